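"""Linear inverse operator and ROI time-course summarization.

Head-model construction is consumed, not computed: an
:class:`InverseOperator` bundles a noise covariance (estimated from
quiet epochs, used for prewhitening), a sensors -> sources kernel built
for whitened data, and the source -> ROI membership.  For synthetic
cohorts the kernel is the ridge-regularized pseudo-inverse of the
generator's own mixing matrix.

Each ROI's representative time course is the first temporal singular
vector of its member-source stack, scaled by the singular value, with
the sign fixed (once per patient, not per trial) so it correlates
non-negatively with the ROI-mean series.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .epochs import EpochSet

__all__ = ["InverseOperator", "estimate_covariance", "whitener_from_cov",
           "build_ridge_inverse", "roi_timecourses"]


@dataclasses.dataclass
class InverseOperator:
    kernel: np.ndarray            # (n_sources, n_sensors), acts on whitened data
    whitener: np.ndarray          # (n_sensors, n_sensors)
    source_rois: list[str]        # ROI membership per source row
    noise_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kernel.shape[0] != len(self.source_rois):
            raise ValueError("kernel rows must match source_rois")
        if self.kernel.shape[1] != self.whitener.shape[0]:
            raise ValueError("kernel/whitener sensor dimensions differ")


def estimate_covariance(epochs: EpochSet) -> np.ndarray:
    """Sensor covariance pooled over trials and samples."""
    x = epochs.data  # (k, ch, t)
    x = x - x.mean(axis=2, keepdims=True)
    n = x.shape[0] * x.shape[2]
    return np.einsum("kit,kjt->ij", x, x) / n


def whitener_from_cov(cov: np.ndarray, rank_tol: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root of a covariance matrix."""
    vals, vecs = np.linalg.eigh(cov)
    keep = vals > rank_tol * vals.max()
    inv_sqrt = np.zeros_like(vals)
    inv_sqrt[keep] = 1.0 / np.sqrt(vals[keep])
    return (vecs * inv_sqrt) @ vecs.T


def build_ridge_inverse(forward: np.ndarray, cov: np.ndarray,
                        source_rois: list[str],
                        ridge: float = 0.1) -> InverseOperator:
    """Ridge pseudo-inverse of a forward (sources -> sensors) matrix.

    The forward matrix ``forward`` has shape (n_sensors, n_sources).
    The leadfield is prewhitened with ``cov``; the ridge parameter is
    scaled by the trace-normalized whitened Gram matrix.
    """
    W = whitener_from_cov(cov)
    A = W @ forward                                   # whitened leadfield
    gram = A @ A.T
    lam = ridge * np.trace(gram) / gram.shape[0]
    kernel = A.T @ np.linalg.inv(gram + lam * np.eye(gram.shape[0]))
    return InverseOperator(kernel=kernel, whitener=W,
                           source_rois=list(source_rois), noise_cov=cov)


def _roi_series(stack: np.ndarray, n_trials: int) -> np.ndarray:
    """First temporal singular vector (times singular value) per trial.

    ``stack`` is (n_members, n_trials * n_samples): the SVD runs per
    trial on the member x sample block; a single-member ROI reduces to
    the member series itself.
    """
    n_samp = stack.shape[1] // n_trials
    out = np.empty((n_trials, n_samp))
    for k in range(n_trials):
        block = stack[:, k * n_samp:(k + 1) * n_samp]
        if block.shape[0] == 1:
            out[k] = block[0]
            continue
        u, s, vt = np.linalg.svd(block, full_matrices=False)
        out[k] = s[0] * vt[0]
    return out


def roi_timecourses(scalp_epochs: EpochSet, inv: InverseOperator) -> EpochSet:
    """Project sensor epochs to sources and summarize per ROI.

    Returns an :class:`EpochSet` whose "channels" are ROI labels.  The
    sign of each ROI series is chosen per patient (pooled across trials)
    so that its correlation with the ROI-mean source series is >= 0.
    """
    x = scalp_epochs.data                               # (k, ch, t)
    if x.shape[1] != inv.kernel.shape[1]:
        raise ValueError("sensor count does not match the inverse operator")
    k, _, t = x.shape
    flat = x.transpose(1, 0, 2).reshape(x.shape[1], k * t)
    sources = inv.kernel @ (inv.whitener @ flat)        # (n_src, k*t)

    rois = sorted(set(inv.source_rois))
    out = np.empty((k, len(rois), t))
    for r, roi in enumerate(rois):
        rows = [i for i, lab in enumerate(inv.source_rois) if lab == roi]
        if not rows:
            raise ValueError(f"ROI {roi} has no member source")
        stack = sources[rows]
        series = _roi_series(stack, k)                  # (k, t)
        mean_series = stack.mean(axis=0).reshape(k, t)
        corr = float((series * mean_series).sum())
        if corr < 0:
            series = -series
        out[:, r, :] = series
    return EpochSet(scalp_epochs.condition, out, scalp_epochs.fs, rois,
                    scalp_epochs.marker_index, scalp_epochs.event_times,
                    scalp_epochs.window)
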