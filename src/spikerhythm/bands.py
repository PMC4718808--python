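"""Frequency-band definitions for the four CA1 rhythms of interest.

The analyses in this package revolve around four rhythms that are prominent
in the CA1 local field potential while a rat samples an odor: theta
(4-12 Hz), beta (15-35 Hz), low gamma (35-55 Hz) and high gamma (65-90 Hz).
Coherency magnitudes are read out at a nominal center frequency within each
band (7, 20, 45 and 75 Hz respectively).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with a nominal center frequency.

    Attributes
    ----------
    name : str
        Band label (e.g. ``"theta"``).
    f_lo, f_hi : float
        Band edges in Hz, ``0 < f_lo < f_hi``.
    f_center : float
        Frequency (Hz) at which coherency is reported; must lie inside
        the band.
    """

    name: str
    f_lo: float
    f_hi: float
    f_center: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_center < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_center < f_hi, "
                f"got ({self.f_lo}, {self.f_center}, {self.f_hi})"
            )

    @property
    def half_bandwidth(self) -> float:
        """Largest half-bandwidth around f_center that stays in band (Hz)."""
        return min(self.f_center - self.f_lo, self.f_hi - self.f_center)


THETA = BandSpec("theta", 4.0, 12.0, 7.0)
BETA = BandSpec("beta", 15.0, 35.0, 20.0)
LOW_GAMMA = BandSpec("low_gamma", 35.0, 55.0, 45.0)
HIGH_GAMMA = BandSpec("high_gamma", 65.0, 90.0, 75.0)

DEFAULT_BANDS: dict[str, BandSpec] = {
    b.name: b for b in (THETA, BETA, LOW_GAMMA, HIGH_GAMMA)
}

BAND_ORDER = ("theta", "beta", "low_gamma", "high_gamma")


def band_pairs(names: tuple[str, ...] = BAND_ORDER) -> list[tuple[str, str]]:
    """The six unordered band pairs, in canonical order."""
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out.append((a, b))
    return out
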