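"""Spike-phase coherence per unit, band and trial type.

Two complementary estimators mirror the dual machinery of the analysis:

* Hilbert-phase statistics: every spike inside a qualifying 1.5 s poke is
  assigned the instantaneous phase of the band-filtered LFP; the Rayleigh
  test on those phases decides *significance* (p < alpha) and hence the
  performance category of the unit (Correct Trials Only / Incorrect Trials
  Only / All Trials / none).

* Multitaper spike-field coherency at the band's center frequency supplies
  the *magnitude* and phase of coherence used for correct-vs-incorrect
  comparisons. Taper count per band is K = clamp(floor(2*T*W - 1), 3, 15)
  with T = 1.5 s and W the in-band half-bandwidth (theta 8, beta 14, low and
  high gamma 15 tapers), maximizing tapers while keeping spectral
  concentration inside the band.

Because coherence estimates are biased by spike count, correct/incorrect
magnitude comparisons are rate-corrected by explicit spike thinning: the
higher-count condition is randomly subsampled to the lower count and the
magnitude averaged over repeated draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .bands import BAND_ORDER, BandSpec
from .session import POKE_DURATION, Session
from .signal import AnalyticTrace, analytic_transform, bandpass_filter

log = logging.getLogger("spikerhythm")

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_SPIKES = 25
DEFAULT_K_THIN = 100
MIN_TAPERS, MAX_TAPERS = 3, 15


# ---------------------------------------------------------------- phases

def extract_spike_phases(spike_times: np.ndarray, trace: AnalyticTrace,
                         trials: pd.DataFrame,
                         outcome: str | None = None) -> pd.DataFrame:
    """One row per spike falling in a qualifying poke window.

    Windows are half-open ``[onset, onset + 1.5 s)``. Returns columns
    ``trial, outcome, time, phase``; empty DataFrame if nothing qualifies.
    """
    st = np.asarray(spike_times, float)
    tr = trials if outcome is None else trials[trials["outcome"] == outcome]
    rows = []
    for t in tr.itertuples():
        lo, hi = t.onset, t.onset + POKE_DURATION
        sel = st[(st >= lo) & (st < hi)]
        if len(sel):
            rows.append(pd.DataFrame({
                "trial": t.trial, "outcome": t.outcome, "time": sel,
                "phase": trace.phase_at(sel)}))
    if not rows:
        return pd.DataFrame(columns=["trial", "outcome", "time", "phase"])
    return pd.concat(rows, ignore_index=True)


def resultant_vector(phases: np.ndarray) -> tuple[float, float]:
    """Mean resultant length R in [0, 1] and mean angle of unit phasors."""
    phases = np.asarray(phases, float)
    if len(phases) == 0:
        raise ValueError("resultant_vector needs at least one phase")
    z = np.mean(np.exp(1j * phases))
    return float(np.abs(z)), float(np.angle(z))


def rayleigh_test(phases: np.ndarray,
                  min_n: int | None = None) -> tuple[float, float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(R, z, p)`` with ``z = n R^2`` and the small-sample-corrected
    approximation ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` where
    ``Rn = n R``.
    """
    phases = np.asarray(phases, float)
    n = len(phases)
    if min_n is not None and n < min_n:
        raise ValueError(f"need at least {min_n} spikes, got {n}")
    if n == 0:
        raise ValueError("rayleigh_test needs at least one phase")
    R, _ = resultant_vector(phases)
    Rn = n * R
    z = n * R * R
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - Rn * Rn)) - (1.0 + 2.0 * n))
    return float(R), float(z), float(min(p, 1.0))


# ------------------------------------------------------ multitaper SFC

def taper_count(band: BandSpec, T: float = POKE_DURATION) -> int:
    """K = clamp(floor(2*T*W - 1), 3, 15) with W the in-band half-bandwidth."""
    return int(np.clip(int(np.floor(2.0 * T * band.half_bandwidth - 1.0)),
                       MIN_TAPERS, MAX_TAPERS))


@dataclass
class _SfcArrays:
    """Precomputed tapered transforms for fast (re)evaluation of coherency.

    The LFP side is fixed; the spike side can be re-evaluated under any
    subsampling mask (used by the thinning rate correction).
    """

    J_lfp: np.ndarray        # (n_trials, K) complex
    spike_trial: np.ndarray  # (n_spikes,) trial row index
    spike_phasor: np.ndarray  # (n_spikes, K) complex h_k(t_s) e^{-i 2pi fc t_s}
    H: np.ndarray            # (K,) complex taper transform at fc
    n_samples: int
    n_trials: int

    @property
    def n_spikes(self) -> int:
        return len(self.spike_trial)

    def coherency(self, mask: np.ndarray | None = None) -> complex:
        if mask is None:
            mask = np.ones(self.n_spikes, bool)
        K = self.J_lfp.shape[1]
        J_spk = np.zeros((self.n_trials, K), complex)
        np.add.at(J_spk, self.spike_trial[mask], self.spike_phasor[mask])
        counts = np.bincount(self.spike_trial[mask], minlength=self.n_trials)
        J_spk -= (counts / self.n_samples)[:, None] * self.H[None, :]
        # conj on the spike side so the coherency phase matches the Hilbert
        # convention (spike at the LFP peak -> phase 0, peak lead positive)
        Sxy = np.sum(np.conj(J_spk) * self.J_lfp)
        Sxx = np.sum(np.abs(self.J_lfp) ** 2)
        Syy = np.sum(np.abs(J_spk) ** 2)
        if Sxx == 0 or Syy == 0:
            raise ValueError("degenerate spectra in coherency computation")
        return complex(Sxy / np.sqrt(Sxx * Syy))

    def per_trial_magnitude(self) -> np.ndarray:
        K = self.J_lfp.shape[1]
        J_spk = np.zeros((self.n_trials, K), complex)
        np.add.at(J_spk, self.spike_trial, self.spike_phasor)
        counts = np.bincount(self.spike_trial, minlength=self.n_trials)
        J_spk -= (counts / self.n_samples)[:, None] * self.H[None, :]
        Sxy = np.sum(np.conj(J_spk) * self.J_lfp, axis=1)
        Sxx = np.sum(np.abs(self.J_lfp) ** 2, axis=1)
        Syy = np.sum(np.abs(J_spk) ** 2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.abs(Sxy) / np.sqrt(Sxx * Syy)


def _prepare_sfc(spike_times: np.ndarray, lfp: np.ndarray, fs: float,
                 trials: pd.DataFrame, band: BandSpec) -> _SfcArrays:
    st = np.asarray(spike_times, float)
    n = int(round(POKE_DURATION * fs))
    K = taper_count(band)
    NW = POKE_DURATION * band.half_bandwidth
    tapers = dpss(n, NW, K)                       # (K, n)
    t_rel = np.arange(n) / fs
    e = np.exp(-2j * np.pi * band.f_center * t_rel)
    H = tapers @ e                                # (K,)
    onsets = trials["onset"].to_numpy(float)
    J_lfp = np.empty((len(onsets), K), complex)
    spike_trial, spike_phasor = [], []
    for r, onset in enumerate(onsets):
        i0 = int(round(onset * fs))
        if i0 < 0 or i0 + n > len(lfp):
            raise ValueError("trial epoch exceeds the recording")
        seg = lfp[i0:i0 + n]
        seg = seg - seg.mean()
        J_lfp[r] = tapers @ (seg * e)
        sel = st[(st >= onset) & (st < onset + POKE_DURATION)] - onset
        if len(sel):
            idx = np.clip(np.round(sel * fs).astype(int), 0, n - 1)
            ph = tapers[:, idx].T * np.exp(
                -2j * np.pi * band.f_center * sel)[:, None]
            spike_trial.append(np.full(len(sel), r))
            spike_phasor.append(ph)
    if spike_trial:
        spike_trial = np.concatenate(spike_trial)
        spike_phasor = np.concatenate(spike_phasor)
    else:
        spike_trial = np.empty(0, int)
        spike_phasor = np.empty((0, K), complex)
    return _SfcArrays(J_lfp, spike_trial, spike_phasor, H, n, len(onsets))


def multitaper_sfc(spike_times: np.ndarray, lfp: np.ndarray, fs: float,
                   trials: pd.DataFrame, band: BandSpec,
                   outcome: str | None = None,
                   min_spikes: int = 1) -> tuple[float, float, int]:
    """Spike-field coherency at ``band.f_center`` pooled over qualifying
    trials; returns ``(magnitude, phase, n_spikes)``."""
    tr = trials if outcome is None else trials[trials["outcome"] == outcome]
    if len(tr) == 0:
        raise ValueError("no qualifying trials")
    arr = _prepare_sfc(spike_times, lfp, fs, tr, band)
    if arr.n_spikes < max(min_spikes, 1):
        raise ValueError(f"too few spikes ({arr.n_spikes} < {min_spikes})")
    c = arr.coherency()
    return float(np.abs(c)), float(np.angle(c)), arr.n_spikes


def per_trial_sfc_magnitude(spike_times: np.ndarray, lfp: np.ndarray,
                            fs: float, trials: pd.DataFrame, band: BandSpec,
                            outcome: str | None = "correct") -> np.ndarray:
    """Coherency magnitude per trial (NaN for spikeless trials)."""
    tr = trials if outcome is None else trials[trials["outcome"] == outcome]
    if len(tr) == 0:
        raise ValueError("no qualifying trials")
    return _prepare_sfc(spike_times, lfp, fs, tr, band).per_trial_magnitude()


def rate_corrected_magnitude(spike_times: np.ndarray, lfp: np.ndarray,
                             fs: float, trials: pd.DataFrame, band: BandSpec,
                             min_spikes: int = DEFAULT_MIN_SPIKES,
                             k_thin: int = DEFAULT_K_THIN,
                             rng: np.random.Generator | None = None
                             ) -> tuple[float, float]:
    """Correct/incorrect coherency magnitudes corrected for spike-count
    imbalance by thinning.

    The higher-count condition is randomly subsampled to the lower count and
    its magnitude averaged over ``k_thin`` draws; the lower-count condition
    is untouched. With equal counts both magnitudes are the plain estimates.
    """
    rng = np.random.default_rng() if rng is None else rng
    arrs = {}
    for outc in ("correct", "incorrect"):
        tr = trials[trials["outcome"] == outc]
        if len(tr) == 0:
            raise ValueError(f"no {outc} trials")
        arrs[outc] = _prepare_sfc(spike_times, lfp, fs, tr, band)
        if arrs[outc].n_spikes < min_spikes:
            raise ValueError(f"too few {outc} spikes "
                             f"({arrs[outc].n_spikes} < {min_spikes})")
    n_c, n_i = arrs["correct"].n_spikes, arrs["incorrect"].n_spikes
    target = min(n_c, n_i)
    mags = {}
    for outc, arr in arrs.items():
        if arr.n_spikes == target:
            mags[outc] = float(np.abs(arr.coherency()))
        else:
            draws = np.empty(k_thin)
            for k in range(k_thin):
                keep = rng.choice(arr.n_spikes, size=target, replace=False)
                mask = np.zeros(arr.n_spikes, bool)
                mask[keep] = True
                draws[k] = np.abs(arr.coherency(mask))
            mags[outc] = float(draws.mean())
    return mags["correct"], mags["incorrect"]


# ------------------------------------------------- categories & profiles

def categorize_unit(p_correct: float | None, p_incorrect: float | None,
                    alpha: float = DEFAULT_ALPHA) -> str:
    """Performance category from the two Rayleigh p-values.

    An undefined p-value (too few spikes) is treated as non-significant.
    """
    sc = p_correct is not None and p_correct < alpha
    si = p_incorrect is not None and p_incorrect < alpha
    if sc and si:
        return "all_trials"
    if sc:
        return "correct_only"
    if si:
        return "incorrect_only"
    return "none"


def combination_profile(significance: dict[str, bool]) -> frozenset[str]:
    """Subset of bands with significant coherence for one unit/trial type."""
    missing = set(BAND_ORDER) - set(significance)
    if missing:
        raise ValueError(f"all four bands must be evaluated; missing {missing}")
    return frozenset(b for b in BAND_ORDER if significance[b])


def all_combinations() -> list[frozenset[str]]:
    """The 15 non-empty band subsets in canonical order."""
    out = []
    for k in range(1, 5):
        out.extend(frozenset(c) for c in combinations(BAND_ORDER, k))
    return out


def combination_histogram(profiles: list[frozenset[str]]) -> pd.Series:
    """Population counts over the 15 non-empty subsets (empty profiles are
    excluded, matching the 15-way categorization)."""
    combos = all_combinations()
    labels = ["+".join(b for b in BAND_ORDER if b in c) for c in combos]
    counts = pd.Series(0, index=labels, dtype=int)
    for p in profiles:
        if p:
            counts["+".join(b for b in BAND_ORDER if b in p)] += 1
    return counts


def trialwise_coherence_correlation(
        per_trial_mags: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Product-moment correlation across trials for each band pair.

    NaN trials (no spikes) are dropped pairwise; constant series give NaN
    (flagged by the caller). Requires >= 3 complete trials per pair.
    """
    out = {}
    names = [b for b in BAND_ORDER if b in per_trial_mags]
    for a, b in combinations(names, 2):
        x, y = np.asarray(per_trial_mags[a]), np.asarray(per_trial_mags[b])
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 usable trials for pair ({a},{b})")
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            out[(a, b)] = float("nan")
        else:
            out[(a, b)] = float(np.corrcoef(xs, ys)[0, 1])
    return out


# ---------------------------------------------------------- per-session

def coherence_table(session: Session, bands: dict[str, BandSpec],
                    alpha: float = DEFAULT_ALPHA,
                    min_spikes: int = DEFAULT_MIN_SPIKES,
                    with_multitaper: bool = True,
                    k_thin: int = DEFAULT_K_THIN,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One CoherenceRecord row per unit x band.

    Columns: unit_id, band, n_spikes_correct/incorrect, R and mean phase per
    trial type, Rayleigh p per trial type (NaN when below ``min_spikes``),
    rate-corrected multitaper magnitudes, and the performance category.
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    traces = {name: analytic_transform(
        bandpass_filter(session.lfp, band, session.fs), band, session.fs)
        for name, band in bands.items()}
    for uid, st in session.spikes.items():
        for name, band in bands.items():
            rec: dict = {"unit_id": uid, "band": name}
            ps = {}
            for outc in ("correct", "incorrect"):
                sample = extract_spike_phases(st, traces[name],
                                              session.trials, outc)
                n = len(sample)
                rec[f"n_spikes_{outc}"] = n
                if n >= min_spikes:
                    R, _, p = rayleigh_test(sample["phase"].to_numpy())
                    _, ang = resultant_vector(sample["phase"].to_numpy())
                    rec[f"R_{outc}"], rec[f"phase_{outc}"] = R, ang
                    rec[f"p_{outc}"] = p
                    ps[outc] = p
                else:
                    log.info("unit %s band %s %s: %d spikes < %d, excluded",
                             uid, name, outc, n, min_spikes)
                    rec[f"R_{outc}"] = rec[f"phase_{outc}"] = np.nan
                    rec[f"p_{outc}"] = np.nan
                    ps[outc] = None
            rec["category"] = categorize_unit(ps["correct"], ps["incorrect"],
                                              alpha)
            rec["mt_mag_correct"] = rec["mt_mag_incorrect"] = np.nan
            if (with_multitaper and ps["correct"] is not None
                    and ps["incorrect"] is not None):
                try:
                    mc, mi = rate_corrected_magnitude(
                        st, session.lfp, session.fs, session.trials, band,
                        min_spikes=min_spikes, k_thin=k_thin, rng=rng)
                    rec["mt_mag_correct"], rec["mt_mag_incorrect"] = mc, mi
                except ValueError:
                    pass
            rows.append(rec)
    return pd.DataFrame(rows)
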