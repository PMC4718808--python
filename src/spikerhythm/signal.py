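"""Band filtering, Hilbert amplitude/phase, trial spectrograms, binned amplitude.

The whole-session LFP is band-pass filtered with a zero-phase (forward and
backward) 3rd-order Butterworth filter and converted to an analytic signal
by the Hilbert transform. Filtering is done once on the full trace and
trial epochs are sliced out afterwards, so per-trial edge artifacts never
touch the analyzed windows. Phase convention: 0 rad at the oscillation
peak, +/-pi at the trough, increasing with time.

Spectrograms are multitaper amplitude estimates (Slepian tapers) over
sliding windows covering [-0.5, 1.5] s around each poke onset, normalized
either by baseline inter-trial amplitude or by the incorrect-trial average,
on a log10 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.signal.windows import dpss

from .bands import BandSpec
from .session import POKE_DURATION

SPECTROGRAM_WINDOW = 0.5   # s
SPECTROGRAM_STEP = 0.05    # s
SPECTROGRAM_NW = 3.0       # time-bandwidth product
SPECTROGRAM_TAPERS = 5
EPOCH_START = -0.5         # s relative to poke onset
EPOCH_END = 1.5
N_AMPLITUDE_BINS = 6       # six 250 ms bins across the 1.5 s poke


@dataclass
class AnalyticTrace:
    """Instantaneous amplitude and phase of one band-filtered LFP.

    ``phase`` lies in (-pi, pi]; ``degenerate`` flags constant input for
    which phase is undefined.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    band: BandSpec
    fs: float
    degenerate: bool = False

    def phase_at(self, times: np.ndarray) -> np.ndarray:
        """Phase at arbitrary times (nearest-sample lookup)."""
        idx = np.clip(np.round(np.asarray(times) * self.fs).astype(int),
                      0, len(self.phase) - 1)
        return self.phase[idx]


def bandpass_filter(lfp: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass; output length = input length."""
    lfp = np.asarray(lfp, float)
    if not np.all(np.isfinite(lfp)):
        raise ValueError("LFP contains non-finite samples")
    nyq = fs / 2.0
    if band.f_hi >= nyq:
        raise ValueError(f"band {band.name} upper edge {band.f_hi} Hz >= "
                         f"Nyquist {nyq} Hz")
    sos = sps.butter(3, [band.f_lo, band.f_hi], btype="bandpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, lfp)


def analytic_transform(filtered: np.ndarray, band: BandSpec,
                       fs: float) -> AnalyticTrace:
    """Amplitude = modulus, phase = angle of the analytic (Hilbert) signal."""
    filtered = np.asarray(filtered, float)
    if np.ptp(filtered) == 0.0:
        # constant input: phase undefined
        return AnalyticTrace(np.abs(filtered), np.zeros_like(filtered),
                             band, fs, degenerate=True)
    analytic = sps.hilbert(filtered)
    return AnalyticTrace(np.abs(analytic), np.angle(analytic), band, fs)


def _multitaper_amplitude(seg: np.ndarray, tapers: np.ndarray) -> np.ndarray:
    """Mean over tapers of |FFT| of one windowed segment -> amplitude per rfft bin."""
    spec = np.fft.rfft(tapers * seg[None, :], axis=1)
    return np.mean(np.abs(spec), axis=0)


def _window_starts(t0: float, t1: float, window: float, step: float) -> np.ndarray:
    n = int(np.floor((t1 - t0 - window) / step)) + 1
    return t0 + step * np.arange(max(n, 0))


def trial_spectrogram(lfp: np.ndarray, fs: float, trials: pd.DataFrame,
                      window: float = SPECTROGRAM_WINDOW,
                      step: float = SPECTROGRAM_STEP,
                      nw: float = SPECTROGRAM_NW,
                      n_tapers: int = SPECTROGRAM_TAPERS,
                      f_max: float = 100.0):
    """Multitaper amplitude spectrogram per trial over [-0.5, 1.5] s.

    Returns ``(specs, times, freqs)`` with ``specs`` of shape
    (n_trials, n_windows, n_freqs); ``times`` are window centers relative to
    poke onset.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    lfp = np.asarray(lfp, float)
    nper = int(round(window * fs))
    tapers = dpss(nper, nw, n_tapers)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    fsel = freqs <= f_max
    starts_rel = _window_starts(EPOCH_START, EPOCH_END, window, step)
    specs = []
    for onset in trials["onset"].to_numpy(float):
        i0s = np.round((onset + starts_rel) * fs).astype(int)
        if i0s.min() < 0 or i0s.max() + nper > len(lfp):
            raise ValueError("trial epoch exceeds the recording")
        rows = [_multitaper_amplitude(lfp[i:i + nper], tapers)[fsel]
                for i in i0s]
        specs.append(rows)
    times = starts_rel + window / 2.0
    return np.asarray(specs), times, freqs[fsel]


def interval_spectra(lfp: np.ndarray, fs: float,
                     intervals: list[tuple[float, float]],
                     window: float = SPECTROGRAM_WINDOW,
                     nw: float = SPECTROGRAM_NW,
                     n_tapers: int = SPECTROGRAM_TAPERS,
                     f_max: float = 100.0):
    """Multitaper amplitude spectra over arbitrary intervals (e.g. the 2.0 s
    baseline inter-trial intervals). Returns (spectra, freqs) with one row per
    fitted window."""
    lfp = np.asarray(lfp, float)
    nper = int(round(window * fs))
    tapers = dpss(nper, nw, n_tapers)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    fsel = freqs <= f_max
    rows = []
    for t0, t1 in intervals:
        for s in _window_starts(t0, t1, window, window):
            i = int(round(s * fs))
            if i < 0 or i + nper > len(lfp):
                raise ValueError("baseline interval exceeds the recording")
            rows.append(_multitaper_amplitude(lfp[i:i + nper], tapers)[fsel])
    if not rows:
        raise ValueError("no baseline windows fit in the given intervals")
    return np.asarray(rows), freqs[fsel]


def normalize_spectrogram(trial_specs: np.ndarray,
                          reference: np.ndarray) -> np.ndarray:
    """Mean over trials, divide by the reference mean amplitude, take log10.

    ``reference`` is either another (n_trials, n_windows, n_freqs) stack on
    the same grid (correct/incorrect contrast) or a (n_windows', n_freqs)
    stack of baseline spectra, in which case the baseline mean per frequency
    is broadcast across time.
    """
    mean_spec = np.asarray(trial_specs).mean(axis=0)
    ref = np.asarray(reference)
    if ref.ndim == 3:
        ref_mean = ref.mean(axis=0)
    elif ref.ndim == 2:
        ref_mean = ref.mean(axis=0)[None, :]
    else:
        raise ValueError("reference must be 2- or 3-dimensional")
    if np.any(ref_mean <= 0):
        raise ValueError("reference amplitude must be strictly positive")
    return np.log10(mean_spec / ref_mean)


def binned_amplitude(trace: AnalyticTrace, trials: pd.DataFrame,
                     n_bins: int = N_AMPLITUDE_BINS) -> np.ndarray:
    """Mean instantaneous amplitude in consecutive 250 ms bins of each poke.

    Returns an (n_trials, n_bins) matrix.
    """
    fs = trace.fs
    bin_len = POKE_DURATION / n_bins
    nper = int(round(bin_len * fs))
    out = np.empty((len(trials), n_bins))
    for r, onset in enumerate(trials["onset"].to_numpy(float)):
        i0 = int(round(onset * fs))
        if i0 < 0 or i0 + n_bins * nper > len(trace.amplitude):
            raise ValueError("poke window exceeds the recording")
        seg = trace.amplitude[i0:i0 + n_bins * nper]
        out[r] = seg.reshape(n_bins, nper).mean(axis=1)
    return out
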