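"""Interneuron / principal-cell classification from rate and waveform features.

Interneurons are fast-firing narrow-waveform cells: mean rate >= 5 Hz, width
at half-max < 150 us, and peak-to-trough width < 350 us. Principal cells
fire below 3 Hz with broader waveforms. Cells in the 3-5 Hz gap, or with a
mixed rate/waveform profile, are left unclassified and excluded from the
population analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INTERNEURON_MIN_RATE = 5.0       # Hz
PRINCIPAL_MAX_RATE = 3.0         # Hz
INTERNEURON_MAX_HALFWIDTH = 150.0   # us
INTERNEURON_MAX_PEAK_TROUGH = 350.0  # us


@dataclass(frozen=True)
class WaveformFeatures:
    """Per-unit mean firing rate (Hz) and waveform widths (microseconds)."""

    mean_rate_hz: float
    half_max_width_us: float
    peak_trough_us: float

    def __post_init__(self) -> None:
        vals = (self.mean_rate_hz, self.half_max_width_us, self.peak_trough_us)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError(f"waveform features must be finite and >= 0: {vals}")
        if not (self.half_max_width_us < 2000 and self.peak_trough_us < 2000):
            raise ValueError("waveform widths implausibly large (>= 2000 us)")


def classify_unit(features: WaveformFeatures) -> str:
    """Classify one unit as ``interneuron``, ``principal`` or ``unclassified``."""
    narrow = (features.half_max_width_us < INTERNEURON_MAX_HALFWIDTH
              and features.peak_trough_us < INTERNEURON_MAX_PEAK_TROUGH)
    if features.mean_rate_hz >= INTERNEURON_MIN_RATE and narrow:
        return "interneuron"
    if features.mean_rate_hz < PRINCIPAL_MAX_RATE and not narrow:
        return "principal"
    return "unclassified"


def classify_units(units: pd.DataFrame) -> pd.DataFrame:
    """Add/overwrite a ``cell_class`` column on a unit feature table.

    Expects columns ``mean_rate_hz``, ``half_max_width_us``, ``peak_trough_us``.
    """
    out = units.copy()
    out["cell_class"] = [
        classify_unit(WaveformFeatures(r.mean_rate_hz, r.half_max_width_us,
                                       r.peak_trough_us))
        for r in out.itertuples()
    ]
    return out
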