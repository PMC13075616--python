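"""Weighted phase lag index (wPLI) connectivity per frequency band.

The wPLI weights each trial's contribution to phase synchrony by the
magnitude of the imaginary cross-spectrum,

    wPLI_ij(f) = | sum_k Im S_k,ij(f) | / sum_k | Im S_k,ij(f) |,

so that zero-lag (instantaneously mixed) components, whose
cross-spectrum is real, cannot produce spurious coupling - the property
that makes it robust to volume conduction and source-leakage.  The
estimator runs across trials per FFT bin of the band-tapered epochs and
averages over in-band bins; when no imaginary cross-spectral mass exists
the value is defined as 0.  The non-debiased form is used (recorded in
the matrix metadata).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .io import ChannelMap
from .windows import BandSpec

__all__ = ["ConnectivityMatrix", "trial_cross_spectra", "wpli",
           "aggregate_pairs_to_roi"]


@dataclasses.dataclass
class ConnectivityMatrix:
    """Symmetric unit x unit matrix of band wPLI values in [0, 1].

    The diagonal and unmeasured pairs are NaN.
    """

    labels: list[str]
    band: str
    condition: str
    W: np.ndarray
    estimator: str = "wpli (non-debiased, across trials)"

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(W, W.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        finite = W[np.isfinite(W)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("wPLI values must lie in [0, 1]")
        self.W = W

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (unit_a, unit_b, band, condition, wpli)."""
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({"unit_a": self.labels[i], "unit_b": self.labels[j],
                             "band": self.band, "condition": self.condition,
                             "wpli": self.W[i, j]})
        return pd.DataFrame(rows)


def trial_cross_spectra(epochs: EpochSet, band: BandSpec) -> np.ndarray:
    """Per-trial, per-in-band-bin cross-spectra.

    Returns a complex array of shape (n_trials, n_bins, n_ch, n_ch) with
    ``S_k,ij(f) = X_k,i(f) conj(X_k,j(f))``.
    """
    if epochs.n_trials < 2:
        raise ValueError("cross-spectral estimation needs at least two trials")
    if epochs.window is None or epochs.window.band != band:
        raise ValueError("epochs were not extracted with this band's window")
    n = epochs.data.shape[2]
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.fs)
    sel = (freqs >= band.f_low) & (freqs < band.f_high)
    X = np.fft.rfft(epochs.data, axis=2)[:, :, sel]     # (k, ch, f)
    return np.einsum("kif,kjf->kfij", X, np.conj(X))


def wpli(cross_spectra: np.ndarray,
         labels: list[str] | None = None,
         band: str = "", condition: str = "") -> ConnectivityMatrix:
    """Band wPLI from trial cross-spectra (mean over in-band bins)."""
    imag = np.imag(cross_spectra)                        # (k, f, i, j)
    num = np.abs(imag.sum(axis=0))
    den = np.abs(imag).sum(axis=0)
    # denominator-zero convention: no imaginary cross-spectral mass means
    # no detectable lagged synchrony; "zero" is relative to the total
    # cross-spectral magnitude so float round-off of an exactly real
    # cross-spectrum does not masquerade as synchrony
    tol = 1e-9 * np.abs(cross_spectra).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_bin = np.where(den > tol, num / np.maximum(den, 1e-300), 0.0)
    W = per_bin.mean(axis=0)
    W = 0.5 * (W + W.T)  # remove float asymmetry
    np.fill_diagonal(W, np.nan)
    if labels is None:
        labels = [f"ch{i}" for i in range(W.shape[0])]
    return ConnectivityMatrix(labels, band, condition, W)


def aggregate_pairs_to_roi(cm: ConnectivityMatrix,
                           cmap: ChannelMap) -> ConnectivityMatrix:
    """Average channel-pair wPLI into ROI-pair wPLI.

    Entry (A, B), A != B, is the mean of ``W_ij`` over all channel pairs
    with i sampling A and j sampling B; within-ROI channel pairs are not
    used; ROI pairs with no sampled channel pair stay NaN.
    """
    roi_of = dict(zip(cmap.table["label"], cmap.table["roi"]))
    members: dict[str, list[int]] = {}
    for i, lab in enumerate(cm.labels):
        roi = roi_of.get(lab)
        if roi is not None:
            members.setdefault(roi, []).append(i)
    rois = sorted(members)
    if len(rois) < 2:
        raise ValueError("channel map covers fewer than two ROIs")
    n = len(rois)
    out = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(a + 1, n):
            block = cm.W[np.ix_(members[rois[a]], members[rois[b]])]
            vals = block[np.isfinite(block)]
            if vals.size:
                out[a, b] = out[b, a] = vals.mean()
    return ConnectivityMatrix(rois, cm.band, cm.condition, out,
                              estimator=cm.estimator + " -> ROI mean")
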