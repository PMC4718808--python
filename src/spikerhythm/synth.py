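"""Synthetic session generator with known ground truth.

Generates sessions with the statistical structure the downstream analyses
assume: a 96-trial session in 24-trial blocks (2 contexts x 4 odors x
4 ports), 1.5 s nose pokes with odor onset at +250 ms, band-limited LFP
components whose amplitude follows trial-epoch (and optionally
outcome-dependent) gain profiles, plus white + 1/f noise. Units fire as
inhomogeneous Poisson processes whose intensity is von Mises-modulated by
the *true* carrier phase of chosen bands,

    lambda(t) = base_rate * tuning(trial) * prod_b exp(kappa_b cos(phi_b(t)
                - mu_b)) / I0(kappa_b),

so the mean rate is preserved (the modulation factor has unit mean over a
uniform phase) and the generative locking strength kappa is the ground
truth against which phase-recovery is tested. Band carriers have a slowly
wandering instantaneous frequency (Ornstein-Uhlenbeck around the band
center, clipped to the band) rather than being pure sinusoids, so filters
and multitaper estimates are exercised realistically.

Task structure (mirrors the behavioral design): each block presents one
odor pair; within a block, the first odor of the pair is rewarded at ports
1-2 (side 1) and the second at ports 3-4 (side 2); the second context
reverses the contingencies. Correct trials therefore cover 8 odor-position
combinations per context half, with odors A and C (and B and D) value
matched.

Randomness: one master seed spawns child streams in a fixed order (trial
table, band carriers, noise, then one per unit), so adding a unit never
perturbs the LFP or the trial table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import i0

from .bands import DEFAULT_BANDS, BandSpec
from .session import ODOR_DELAY, POKE_DURATION, Session, write_session

FLAT_GAIN: tuple[tuple[float, float], ...] = ((-0.5, 1.0), (1.5, 1.0))
# Correct-trial-specific late rise in amplitude over the poke (emulates the
# low-gamma dynamic): flat until mid-poke, then ramping up by 60%.
LATE_RISE_GAIN: tuple[tuple[float, float], ...] = (
    (-0.5, 1.0), (0.5, 1.0), (1.5, 1.6))


@dataclass(frozen=True)
class BandComponent:
    """One band-limited LFP component.

    ``gain_correct`` / ``gain_incorrect`` are piecewise-linear amplitude gain
    profiles over time relative to poke onset (s); outside poke epochs the
    gain is 1.
    """

    band: BandSpec
    base_amplitude: float = 1.0
    gain_correct: tuple[tuple[float, float], ...] = FLAT_GAIN
    gain_incorrect: tuple[tuple[float, float], ...] = FLAT_GAIN
    freq_sd: float | None = None     # Hz; default = band width / 8
    freq_tau: float = 0.5            # s; OU time constant of the carrier


@dataclass(frozen=True)
class Locking:
    """von Mises phase locking of a unit to one band carrier."""

    band_name: str
    kappa: float
    preferred_phase: float
    applies_to: str = "both"   # correct | incorrect | both

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not (-np.pi < self.preferred_phase <= np.pi):
            raise ValueError("preferred_phase must lie in (-pi, pi]")
        if self.applies_to not in ("correct", "incorrect", "both"):
            raise ValueError(f"bad applies_to: {self.applies_to}")


@dataclass(frozen=True)
class UnitSpec:
    """Generative description of one unit.

    ``tuning`` maps a task dimension to rate multipliers, e.g.
    ``{"position": {2: 4.0}}`` or ``{"odor_position": {("A", 1): 3.0}}``;
    unlisted conditions have multiplier 1.
    """

    unit_id: str
    cell_class: str = "interneuron"
    base_rate: float = 10.0
    locking: tuple[Locking, ...] = ()
    tuning: dict | None = None
    refractory: float = 0.002

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if self.cell_class == "interneuron" and self.base_rate < 5.0:
            raise ValueError("interneuron base_rate must be >= 5 Hz")
        if self.cell_class == "principal" and self.base_rate >= 3.0:
            raise ValueError("principal base_rate must be < 3 Hz")


@dataclass
class ScenarioConfig:
    """Full description of one synthetic session."""

    band_components: tuple[BandComponent, ...] = ()
    units: tuple[UnitSpec, ...] = ()
    lfp_sampling_rate: float = 1000.0
    n_trials: int = 96
    block_size: int = 24
    p_correct: float = 0.8
    trial_spacing: float = 4.5      # s between consecutive poke onsets
    first_onset: float = 3.0        # s
    session_duration: float | None = None
    noise_sd: float = 0.5           # total broadband noise s.d. (a.u.)
    pink_fraction: float = 0.5      # share of noise variance that is 1/f
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials % self.block_size != 0:
            raise ValueError("n_trials must be divisible by block_size")
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must lie in [0, 1]")
        if not 0.0 <= self.pink_fraction <= 1.0:
            raise ValueError("pink_fraction must lie in [0, 1]")
        band_names = {c.band.name for c in self.band_components}
        for u in self.units:
            for lk in u.locking:
                if lk.band_name not in band_names:
                    raise ValueError(
                        f"unit {u.unit_id} locks to undefined band "
                        f"{lk.band_name!r}")

    @property
    def duration(self) -> float:
        if self.session_duration is not None:
            return self.session_duration
        return (self.first_onset + (self.n_trials - 1) * self.trial_spacing
                + POKE_DURATION + 2.0)


ODOR_PAIRS = (("A", "B"), ("C", "D"))


def build_trial_table(config: ScenarioConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Counterbalanced trial table: positions (and outcomes) balanced within
    each block, context switching at the session midpoint, odor determined by
    block pair, side and reward contingency."""
    n_blocks = config.n_trials // config.block_size
    rows = []
    trial = 0
    for b in range(n_blocks):
        context = 1 if b < (n_blocks + 1) // 2 else 2
        pair = ODOR_PAIRS[b % len(ODOR_PAIRS)]
        bs = config.block_size
        n_corr = int(round(config.p_correct * bs))
        # positions exactly balanced over the block (up to rounding), correct
        # outcomes spread across positions by largest remainder, so every
        # odor-position combination appears equally often up to rounding
        pos = np.resize([1, 2, 3, 4], bs)
        outcomes = np.empty(bs, object)
        quota = {p: int(np.floor(n_corr * np.sum(pos == p) / bs))
                 for p in (1, 2, 3, 4)}
        remainder = n_corr - sum(quota.values())
        for p in rng.permutation([1, 2, 3, 4])[:remainder]:
            quota[p] += 1
        for p in (1, 2, 3, 4):
            idx = rng.permutation(np.flatnonzero(pos == p))
            outcomes[idx[:quota[p]]] = "correct"
            outcomes[idx[quota[p]:]] = "incorrect"
        order = rng.permutation(bs)
        pos, outcomes = pos[order], outcomes[order]
        for k in range(bs):
            side = 1 if pos[k] <= 2 else 2
            if context == 1:
                rewarded = pair[0] if side == 1 else pair[1]
                unrewarded = pair[1] if side == 1 else pair[0]
            else:
                rewarded = pair[1] if side == 1 else pair[0]
                unrewarded = pair[0] if side == 1 else pair[1]
            odor = rewarded if outcomes[k] == "correct" else unrewarded
            onset = config.first_onset + trial * config.trial_spacing
            rows.append((trial, onset, outcomes[k], odor, int(pos[k]),
                         context, b))
            trial += 1
    return pd.DataFrame(rows, columns=["trial", "onset", "outcome", "odor",
                                       "position", "context", "block"])


def _ou_carrier_phase(n: int, fs: float, comp: BandComponent,
                      rng: np.random.Generator) -> np.ndarray:
    """Phase of a carrier whose instantaneous frequency is an OU process
    around the band center, clipped to stay inside the band."""
    band = comp.band
    sd = comp.freq_sd if comp.freq_sd is not None else (band.f_hi - band.f_lo) / 8
    dt = 1.0 / fs
    a = np.exp(-dt / comp.freq_tau)
    s = sd * np.sqrt(1.0 - a * a)
    dev = sps.lfilter([1.0], [1.0, -a], s * rng.standard_normal(n))
    f_inst = np.clip(band.f_center + dev, band.f_lo + 0.25, band.f_hi - 0.25)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    return phase0 + 2.0 * np.pi * np.cumsum(f_inst) * dt


def _gain_envelope(n: int, fs: float, comp: BandComponent,
                   trials: pd.DataFrame) -> np.ndarray:
    """Per-sample amplitude envelope: base amplitude scaled by the epoch
    gain profile inside [-0.5, 1.5] s around each poke onset."""
    env = np.full(n, comp.base_amplitude)
    for onset, outcome in zip(trials["onset"], trials["outcome"]):
        prof = comp.gain_correct if outcome == "correct" else comp.gain_incorrect
        ts, gs = zip(*prof)
        i0_ = max(int(round((onset + ts[0]) * fs)), 0)
        i1 = min(int(round((onset + ts[-1]) * fs)), n)
        if i1 <= i0_:
            continue
        t_rel = np.arange(i0_, i1) / fs - onset
        env[i0_:i1] = comp.base_amplitude * np.interp(t_rel, ts, gs)
    return env


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f (amplitude ~ f^-1/2 in power) noise via FFT shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n)
    return pink / pink.std()


def _enforce_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Delete spikes closer than the refractory period, keeping the earlier."""
    if refractory <= 0 or len(times) < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def _tuning_multipliers(unit: UnitSpec, trials: pd.DataFrame) -> np.ndarray:
    """Per-trial rate multiplier from the unit's condition tuning."""
    mult = np.ones(len(trials))
    if not unit.tuning:
        return mult
    for dim, table in unit.tuning.items():
        if dim == "position":
            keys = trials["position"].to_numpy()
        elif dim == "odor":
            keys = trials["odor"].to_numpy()
        elif dim == "odor_position":
            keys = list(zip(trials["odor"], trials["position"]))
        else:
            raise ValueError(f"unknown tuning dimension {dim!r}")
        mult *= np.array([table.get(k, 1.0) for k in keys])
    return mult


def _unit_spike_train(unit: UnitSpec, config: ScenarioConfig,
                      trials: pd.DataFrame, phases: dict[str, np.ndarray],
                      rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson spikes by thinning a homogeneous envelope."""
    fs = config.lfp_sampling_rate
    duration = config.duration
    g_max = 1.0
    for lk in unit.locking:
        g_max *= np.exp(lk.kappa) / i0(lk.kappa)
    tun = _tuning_multipliers(unit, trials)
    lam_max = unit.base_rate * g_max * max(1.0, tun.max(initial=1.0))
    n_cand = rng.poisson(lam_max * duration)
    t_cand = np.sort(rng.uniform(0.0, duration, n_cand))

    lam = np.full(n_cand, unit.base_rate)
    onsets = trials["onset"].to_numpy(float)
    idx = np.searchsorted(onsets, t_cand, side="right") - 1
    in_poke = (idx >= 0) & (t_cand < onsets[np.clip(idx, 0, None)]
                            + POKE_DURATION)
    poke_trial = idx[in_poke]
    lam_poke = lam[in_poke] * tun[poke_trial]
    outcomes = trials["outcome"].to_numpy()[poke_trial]
    t_poke = t_cand[in_poke]
    samp = np.clip(np.round(t_poke * fs).astype(int), 0,
                   int(duration * fs) - 1)
    for lk in unit.locking:
        if lk.applies_to == "both":
            sel = np.ones(len(t_poke), bool)
        else:
            sel = outcomes == lk.applies_to
        phi = phases[lk.band_name][samp[sel]]
        factor = np.exp(lk.kappa * np.cos(phi - lk.preferred_phase)) / i0(lk.kappa)
        mod = np.ones(len(t_poke))
        mod[sel] = factor
        lam_poke = lam_poke * mod
    lam[in_poke] = lam_poke
    accept = rng.uniform(0.0, 1.0, n_cand) < lam / lam_max
    return _enforce_refractory(t_cand[accept], unit.refractory)


def _waveform_features(unit: UnitSpec, measured_rate: float,
                       rng: np.random.Generator) -> tuple[float, float]:
    """Draw waveform widths consistent with the unit's cell class."""
    if unit.cell_class == "interneuron":
        return rng.uniform(90, 140), rng.uniform(220, 330)
    return rng.uniform(200, 400), rng.uniform(400, 700)


def generate_session(config: ScenarioConfig,
                     return_truth: bool = False):
    """Generate one session. Identical config + seed gives a bit-identical
    session. With ``return_truth=True`` also returns the per-band carrier
    phase arrays used to drive spiking."""
    fs = config.lfp_sampling_rate
    n = int(round(config.duration * fs))
    ss = np.random.SeedSequence(config.seed)
    k_trials, k_carriers, k_noise, k_units = ss.spawn(4)
    trials = build_trial_table(config, np.random.default_rng(k_trials))
    if len(trials) and trials["onset"].iloc[-1] + POKE_DURATION > config.duration:
        raise ValueError("session_duration too short for the trial schedule")

    lfp = np.zeros(n)
    phases: dict[str, np.ndarray] = {}
    for comp, seq in zip(config.band_components,
                         k_carriers.spawn(max(len(config.band_components), 1))):
        crng = np.random.default_rng(seq)
        phi = _ou_carrier_phase(n, fs, comp, crng)
        phases[comp.band.name] = np.mod(phi + np.pi, 2 * np.pi) - np.pi
        lfp += _gain_envelope(n, fs, comp, trials) * np.cos(phi)
    nrng = np.random.default_rng(k_noise)
    if config.noise_sd > 0:
        w_sd = config.noise_sd * np.sqrt(1.0 - config.pink_fraction)
        p_sd = config.noise_sd * np.sqrt(config.pink_fraction)
        if w_sd > 0:
            lfp += w_sd * nrng.standard_normal(n)
        if p_sd > 0:
            lfp += p_sd * _pink_noise(n, nrng)

    spikes: dict[str, np.ndarray] = {}
    unit_rows = []
    for unit, seq in zip(config.units, k_units.spawn(max(len(config.units), 1))):
        urng = np.random.default_rng(seq)
        st = _unit_spike_train(unit, config, trials, phases, urng)
        spikes[unit.unit_id] = st
        rate = len(st) / config.duration
        hw, pt = _waveform_features(unit, rate, urng)
        unit_rows.append((unit.unit_id, unit.cell_class, rate, hw, pt))
    units = pd.DataFrame(unit_rows, columns=[
        "unit_id", "cell_class", "mean_rate_hz", "half_max_width_us",
        "peak_trough_us"])

    sess = Session(lfp=lfp, fs=fs, trials=trials, spikes=spikes, units=units,
                   meta={"seed": int(config.seed), "synthetic": True})
    if return_truth:
        return sess, phases
    return sess


def default_band_components() -> tuple[BandComponent, ...]:
    """All four rhythms at unit amplitude with flat epoch gain, except a
    correct-trial-specific late low-gamma rise."""
    return tuple(
        BandComponent(DEFAULT_BANDS[name],
                      gain_correct=LATE_RISE_GAIN if name == "low_gamma"
                      else FLAT_GAIN)
        for name in ("theta", "beta", "low_gamma", "high_gamma"))


def _mini_config(units: tuple[UnitSpec, ...],
                 components: tuple[BandComponent, ...],
                 seed: int, p_correct: float = 0.5) -> ScenarioConfig:
    """A <=10 s four-trial session for fixture purposes."""
    return ScenarioConfig(
        band_components=components, units=units, n_trials=4, block_size=4,
        p_correct=p_correct, trial_spacing=2.0, first_onset=1.5,
        session_duration=9.5, seed=seed)


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write five mini-sessions covering the qualitative regimes the
    analyses must distinguish; returns (and writes) a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    flat = tuple(BandComponent(DEFAULT_BANDS[nm])
                 for nm in ("theta", "beta", "low_gamma", "high_gamma"))
    rise = default_band_components()

    def inter(i, locking=(), tuning=None):
        return UnitSpec(f"u{i:02d}", "interneuron", 12.0, locking, tuning)

    scenarios = {
        "null": _mini_config(
            tuple(inter(i) for i in range(20)), flat, seed + 1),
        "single_band": _mini_config(
            tuple(inter(i, (Locking("beta", 2.0, np.pi / 2),)) for i in range(8)),
            flat, seed + 2),
        "all_band": _mini_config(
            tuple(inter(i, tuple(Locking(nm, 1.5, 0.0)
                                 for nm in ("theta", "beta", "low_gamma",
                                            "high_gamma")))
                  for i in range(8)), flat, seed + 3),
        "outcome_dependent": _mini_config(
            tuple(inter(i, (Locking("beta", 3.0, 0.0,
                                    "correct" if i < 14 else "both"),))
                  for i in range(20)), flat, seed + 4),
        "lowgamma_rise": _mini_config(
            tuple(inter(i) for i in range(4)), rise, seed + 5),
    }
    manifest = {"seed": seed, "sessions": {}}
    for name, cfg in scenarios.items():
        sdir = out / name
        write_session(generate_session(cfg), sdir)
        manifest["sessions"][name] = name
    (out / "fixtures.json").write_text(json.dumps(manifest, indent=1))
    return manifest
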