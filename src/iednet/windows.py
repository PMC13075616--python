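"""Canonical frequency bands and band-adaptive analysis windows.

Each band is analysed in a window long enough to hold five cycles of its
lowest frequency (5 s for delta 1-4 Hz, down to 0.385 s for beta
13-30 Hz).  Because the interest is in what follows a discharge, the
window is shifted so the spike peak sits at 3/8 of its length, and a
Tukey (tapered-cosine, r = 0.25) taper is used so the flat plateau
covers the peak.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import windows as spwin

__all__ = ["BandSpec", "AnalysisWindow", "BANDS", "build_window",
           "PEAK_FRACTION", "N_CYCLES"]

N_CYCLES = 5
PEAK_FRACTION = 3.0 / 8.0
TUKEY_RATIO = 0.25


@dataclasses.dataclass(frozen=True)
class BandSpec:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"invalid band {self.name}: [{self.f_low}, {self.f_high}]")


BANDS = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclasses.dataclass(frozen=True)
class AnalysisWindow:
    """Band-dependent tapered analysis window.

    ``n_samples = round(fs * 5 / f_low)``; the event peak is placed at
    ``peak_index = round(3/8 * n_samples)``; ``taper`` is the Tukey
    coefficient vector applied multiplicatively at epoch extraction.
    """

    band: BandSpec
    fs: float
    n_samples: int
    peak_index: int
    taper: np.ndarray

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def pre(self) -> float:
        """Seconds of signal before the event peak."""
        return self.peak_index / self.fs

    @property
    def post(self) -> float:
        return (self.n_samples - self.peak_index) / self.fs


def build_window(band: BandSpec, fs: float,
                 tukey_ratio: float = TUKEY_RATIO) -> AnalysisWindow:
    """Build the adaptive window for ``band`` at sampling rate ``fs``."""
    if fs <= 2 * band.f_high:
        raise ValueError(f"fs={fs} too low for band up to {band.f_high} Hz")
    n = _round_half_up(fs * N_CYCLES / band.f_low)
    peak = _round_half_up(PEAK_FRACTION * n)
    taper = spwin.tukey(n, tukey_ratio)
    return AnalysisWindow(band=band, fs=fs, n_samples=n, peak_index=peak,
                          taper=taper)
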