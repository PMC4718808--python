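"""Simulation studies validating the analysis chain against ground truth.

Each function runs a self-contained experiment on synthetic sessions and
returns the measured quantities: Rayleigh false-positive calibration on
unlocked units, preferred-phase and concentration recovery for von
Mises-locked units, the residual gap left by the spike-thinning rate
correction, the calibration and power of the shuffle-null information test,
recovery of designed performance-category proportions, and the power of the
two-factor repeated-measures ANOVA to detect a correct-trial-specific late
amplitude rise. All randomness derives from a single seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from .bands import DEFAULT_BANDS
from .phase import (categorize_unit, rate_corrected_magnitude, rayleigh_test,
                    resultant_vector)
from .session import POKE_DURATION
from .signal import analytic_transform, bandpass_filter, binned_amplitude
from .stats import rm_anova_two_factor
from .information import shuffle_significance
from .synth import (FLAT_GAIN, LATE_RISE_GAIN, BandComponent, Locking,
                    ScenarioConfig, UnitSpec, generate_session)

ALL_COMPONENTS = tuple(BandComponent(DEFAULT_BANDS[n])
                       for n in ("theta", "beta", "low_gamma", "high_gamma"))


def _child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible 31-bit child seeds from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def _pooled_poke_phases(spikes: np.ndarray, trace, trials,
                        outcome: str | None = None) -> np.ndarray:
    """Phases of all spikes inside qualifying pokes (vectorized pooled
    equivalent of extract_spike_phases for large unit populations)."""
    tr = trials if outcome is None else trials[trials["outcome"] == outcome]
    onsets = tr["onset"].to_numpy(float)
    idx = np.searchsorted(onsets, spikes, side="right") - 1
    ok = idx >= 0
    ok[ok] &= spikes[ok] < onsets[idx[ok]] + POKE_DURATION
    return trace.phase_at(spikes[ok])


def _band_traces(session, names=("theta", "beta", "low_gamma", "high_gamma")):
    return {n: analytic_transform(
        bandpass_filter(session.lfp, DEFAULT_BANDS[n], session.fs),
        DEFAULT_BANDS[n], session.fs) for n in names}


def rayleigh_calibration(n_units: int = 500, n_sessions: int = 5,
                         alpha: float = 0.05, seed: int = 0
                         ) -> dict[str, float]:
    """Fraction of unlocked Poisson units called significant per band.

    Should sit at the nominal alpha; units are spread over several LFP
    realizations so calibration does not hinge on one carrier draw.
    """
    per_session = n_units // n_sessions
    hits = {name: 0 for name in DEFAULT_BANDS}
    for s, child in enumerate(_child_seeds(seed, n_sessions)):
        cfg = ScenarioConfig(
            band_components=ALL_COMPONENTS,
            units=tuple(UnitSpec(f"u{i}", "interneuron", 10.0)
                        for i in range(per_session)),
            n_trials=96, block_size=24, p_correct=0.8, trial_spacing=3.0,
            first_onset=2.0, seed=child)
        sess = generate_session(cfg)
        traces = _band_traces(sess)
        for name, trace in traces.items():
            for st in sess.spikes.values():
                ph = _pooled_poke_phases(st, trace, sess.trials)
                hits[name] += rayleigh_test(ph)[2] < alpha
    return {name: h / (per_session * n_sessions) for name, h in hits.items()}


def phase_recovery(kappas=(0.5, 1.0, 2.0), n_per_kappa: int = 50,
                   preferred: float = np.pi / 2, seed: int = 0) -> dict:
    """Recover preferred phase and locking strength of beta-locked units.

    Returns the mean resultant length per kappa, the per-unit absolute
    preferred-phase errors (degrees) at the highest kappa, and one-sided
    Mann-Whitney p-values for R increasing between consecutive kappas.
    """
    units = tuple(
        UnitSpec(f"k{ki}_r{r}", "interneuron", 10.0,
                 (Locking("beta", kappa, preferred),))
        for ki, kappa in enumerate(kappas) for r in range(n_per_kappa))
    cfg = ScenarioConfig(band_components=ALL_COMPONENTS, units=units,
                         n_trials=96, block_size=24, p_correct=0.8,
                         trial_spacing=3.0, first_onset=2.0,
                         seed=_child_seeds(seed, 1)[0])
    sess = generate_session(cfg)
    trace = _band_traces(sess, ("beta",))["beta"]
    R = {k: [] for k in range(len(kappas))}
    errors_deg = []
    n_spikes_top = []
    top = len(kappas) - 1
    for uid, st in sess.spikes.items():
        ki = int(uid[1:].split("_")[0])
        ph = _pooled_poke_phases(st, trace, sess.trials)
        r, ang = resultant_vector(ph)
        R[ki].append(r)
        if ki == top:
            err = np.degrees(np.angle(np.exp(1j * (ang - preferred))))
            errors_deg.append(abs(err))
            n_spikes_top.append(len(ph))
    mono_p = [float(sstats.mannwhitneyu(R[i], R[i + 1],
                                        alternative="less").pvalue)
              for i in range(len(kappas) - 1)]
    return {"kappas": list(kappas),
            "mean_R": [float(np.mean(R[i])) for i in range(len(kappas))],
            "phase_errors_deg": errors_deg,
            "n_spikes_top": n_spikes_top,
            "monotonic_pvalues": mono_p}


def rate_correction_gap(n_reps: int = 50, rate_hi: float = 20.0,
                        rate_lo: float = 10.0, kappa: float = 1.0,
                        k_thin: int = 50, seed: int = 0) -> dict:
    """Residual correct/incorrect magnitude gap for equally locked units
    whose firing rate differs by outcome.

    Each replicate splices a high-rate unit's correct-poke spikes with a
    low-rate unit's incorrect-poke spikes (same kappa, same carrier), so the
    only correct/incorrect asymmetry is the firing rate the thinning
    correction must remove. Returns the mean absolute corrected gap.
    """
    band = DEFAULT_BANDS["beta"]
    gaps = []
    for child in _child_seeds(seed, n_reps):
        cfg = ScenarioConfig(
            band_components=(BandComponent(band),),
            units=(UnitSpec("hi", "interneuron", rate_hi,
                            (Locking("beta", kappa, 0.0),), refractory=0.0),
                   UnitSpec("lo", "interneuron", rate_lo,
                            (Locking("beta", kappa, 0.0),), refractory=0.0)),
            n_trials=48, block_size=24, p_correct=0.5, trial_spacing=3.0,
            first_onset=2.0, seed=child)
        sess = generate_session(cfg)
        corr = sess.trials[sess.trials["outcome"] == "correct"]
        inc = sess.trials[sess.trials["outcome"] == "incorrect"]
        keep_hi = np.zeros(len(sess.spikes["hi"]), bool)
        for on in corr["onset"]:
            keep_hi |= ((sess.spikes["hi"] >= on)
                        & (sess.spikes["hi"] < on + POKE_DURATION))
        keep_lo = np.zeros(len(sess.spikes["lo"]), bool)
        for on in inc["onset"]:
            keep_lo |= ((sess.spikes["lo"] >= on)
                        & (sess.spikes["lo"] < on + POKE_DURATION))
        spliced = np.sort(np.concatenate([sess.spikes["hi"][keep_hi],
                                          sess.spikes["lo"][keep_lo]]))
        mc, mi = rate_corrected_magnitude(
            spliced, sess.lfp, sess.fs, sess.trials, band,
            min_spikes=25, k_thin=k_thin,
            rng=np.random.default_rng(child))
        gaps.append(mc - mi)
    gaps = np.asarray(gaps)
    return {"mean_abs_gap": float(np.abs(gaps.mean())),
            "mean_gap": float(gaps.mean()),
            "gap_sd": float(gaps.std(ddof=1))}


def information_calibration(n_reps: int = 200, n_shuffles: int = 200,
                            tuning_factor: float = 4.0, seed: int = 0
                            ) -> dict:
    """False-positive and detection rates of the shuffle-null information
    test on untuned vs position-tuned (one port at ``tuning_factor`` x rate)
    units, one replicate session each."""
    flags_untuned, flags_tuned = [], []
    for child in _child_seeds(seed, n_reps):
        cfg = ScenarioConfig(
            band_components=(), noise_sd=0.0,
            units=(UnitSpec("flat", "interneuron", 6.0),
                   UnitSpec("tuned", "interneuron", 6.0,
                            tuning={"position": {2: tuning_factor}})),
            n_trials=96, block_size=24, p_correct=0.8, trial_spacing=2.5,
            first_onset=2.0, seed=child)
        sess = generate_session(cfg)
        rng = np.random.default_rng(child)
        _, _, sig_flat = shuffle_significance(
            sess.spikes["flat"], sess.trials, "position", "whole_poke",
            n_shuffles, rng)
        _, _, sig_tuned = shuffle_significance(
            sess.spikes["tuned"], sess.trials, "position", "whole_poke",
            n_shuffles, rng)
        flags_untuned.append(sig_flat)
        flags_tuned.append(sig_tuned)
    return {"untuned_rate": float(np.mean(flags_untuned)),
            "tuned_rate": float(np.mean(flags_tuned)),
            "n_reps": n_reps}


def category_recovery(n_units: int = 60, frac_correct_only: float = 0.7,
                      kappa: float = 1.5, alpha: float = 0.05,
                      seed: int = 0) -> dict:
    """Recover designed performance-category proportions on an
    outcome-dependent population (a fraction locked to beta during correct
    trials only, the rest during all trials)."""
    n_corr_only = int(round(frac_correct_only * n_units))
    units = tuple(
        UnitSpec(f"u{i}", "interneuron", 12.0,
                 (Locking("beta", kappa, 0.0,
                          "correct" if i < n_corr_only else "both"),))
        for i in range(n_units))
    cfg = ScenarioConfig(band_components=ALL_COMPONENTS, units=units,
                         n_trials=96, block_size=24, p_correct=0.5,
                         trial_spacing=3.0, first_onset=2.0,
                         seed=_child_seeds(seed, 1)[0])
    sess = generate_session(cfg)
    trace = _band_traces(sess, ("beta",))["beta"]
    cats = []
    for st in sess.spikes.values():
        ps = {}
        for outc in ("correct", "incorrect"):
            ph = _pooled_poke_phases(st, trace, sess.trials, outc)
            ps[outc] = rayleigh_test(ph)[2] if len(ph) >= 25 else None
        cats.append(categorize_unit(ps["correct"], ps["incorrect"], alpha))
    cats = np.asarray(cats)
    return {"n_units": n_units,
            "designed_correct_only": frac_correct_only,
            "observed_correct_only": float(np.mean(cats == "correct_only")),
            "observed_all_trials": float(np.mean(cats == "all_trials")),
            "observed_incorrect_only": float(
                np.mean(cats == "incorrect_only"))}


def interaction_power(n_reps: int = 50, n_sessions: int = 8,
                      alpha: float = 0.05, seed: int = 0) -> dict:
    """Power of the two-factor RM-ANOVA (six time bins x outcome) to detect
    the correct-trial-specific late low-gamma amplitude rise."""
    band = DEFAULT_BANDS["low_gamma"]
    comp = BandComponent(band, gain_correct=LATE_RISE_GAIN,
                         gain_incorrect=FLAT_GAIN)
    detections = 0
    rep_seeds = _child_seeds(seed, n_reps)
    for rep in range(n_reps):
        data = np.empty((n_sessions, 6, 2))
        for s, child in enumerate(_child_seeds(rep_seeds[rep], n_sessions)):
            cfg = ScenarioConfig(
                band_components=(comp,), units=(), n_trials=24,
                block_size=24, p_correct=0.5, trial_spacing=3.0,
                first_onset=2.0, seed=child)
            sess = generate_session(cfg)
            trace = _band_traces(sess, ("low_gamma",))["low_gamma"]
            mat = binned_amplitude(trace, sess.trials)
            corr = (sess.trials["outcome"] == "correct").to_numpy()
            data[s, :, 0] = mat[corr].mean(axis=0)
            data[s, :, 1] = mat[~corr].mean(axis=0)
        out = rm_anova_two_factor(data)
        detections += out["AxB"]["p"] < alpha
    return {"detection_rate": detections / n_reps, "n_reps": n_reps}
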