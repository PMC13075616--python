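"""Band-averaged power spectral density and spectral phase locking.

Operates on epochs extracted with the band's adaptive Tukey window: per
trial the tapered slice is Fourier transformed; power is normalized by
the taper energy (periodogram density convention, uV^2/Hz), averaged
across trials and then across the FFT bins whose centers fall in
``[f_low, f_high)`` (half-open so shared band edges at 4, 8 and 13 Hz
are not double counted).  Spectral ITC takes the per-bin mean unit
phasor magnitude across trials before band averaging.  Channel-level
values aggregate to ROI values by the arithmetic mean over the channels
sampling each ROI.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .io import ChannelMap
from .windows import BandSpec

__all__ = ["band_psd", "band_itc", "aggregate_units_to_roi"]


def _band_bins(epochs: EpochSet, band: BandSpec) -> tuple[np.ndarray, np.ndarray]:
    if epochs.window is None or epochs.window.band != band:
        raise ValueError("epochs were not extracted with this band's window")
    n = epochs.data.shape[2]
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.fs)
    sel = (freqs >= band.f_low) & (freqs < band.f_high)
    if not sel.any():
        raise ValueError("no FFT bin falls inside the band")
    return freqs, sel


def band_psd(epochs: EpochSet, band: BandSpec) -> pd.Series:
    """Per-channel band-averaged PSD (uV^2/Hz), trials then bins averaged."""
    _, sel = _band_bins(epochs, band)
    X = np.fft.rfft(epochs.data, axis=2)
    u = epochs.fs * np.sum(epochs.window.taper ** 2)
    psd = 2.0 * np.abs(X) ** 2 / u               # one-sided density
    value = psd[:, :, sel].mean(axis=0).mean(axis=1)
    return pd.Series(value, index=epochs.channel_labels, name=band.name)


def band_itc(epochs: EpochSet, band: BandSpec) -> pd.Series:
    """Per-channel band-averaged spectral inter-trial coherence in [0, 1]."""
    if epochs.n_trials < 2:
        raise ValueError("spectral ITC needs at least two trials")
    _, sel = _band_bins(epochs, band)
    X = np.fft.rfft(epochs.data, axis=2)[:, :, sel]
    phasors = X / np.maximum(np.abs(X), 1e-300)
    value = np.abs(phasors.mean(axis=0)).mean(axis=1)
    return pd.Series(value, index=epochs.channel_labels, name=band.name)


def aggregate_units_to_roi(values: pd.Series, cmap: ChannelMap) -> pd.Series:
    """Average channel values into ROI values (unmapped channels excluded).

    ROIs with no mapped channel are absent from the output; an
    all-unmapped input yields an empty series with a warning.
    """
    if len(cmap.table) == 0:
        raise ValueError("empty channel map")
    roi_of = dict(zip(cmap.table["label"], cmap.table["roi"]))
    mapped = {ch: roi_of[ch] for ch in values.index if ch in roi_of}
    if not mapped:
        warnings.warn("no channel could be mapped to an ROI", stacklevel=2)
        return pd.Series(dtype=float)
    frame = pd.DataFrame({"roi": pd.Series(mapped), "value": values[list(mapped)]})
    return frame.groupby("roi")["value"].mean().rename(values.name)
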