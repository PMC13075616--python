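"""Epoch extraction: band-adaptive tapered epochs and fixed wavelet epochs.

Two epoch flavours are used downstream.  Band analyses (power, spectral
phase locking, connectivity) slice the recording with the band's
adaptive Tukey window so the marker falls at 3/8 of the window.
Time-frequency analyses use longer untapered spans (-2..+3 s around an
IED peak, +-2.5 s around a quiet-period marker); the wavelet's cone of
influence handles the edges there.  Condition imbalance is removed by a
seeded uniform subsample down to the smaller trial count.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .events import EventList
from .io import Recording
from .windows import AnalysisWindow

__all__ = ["EpochSet", "extract_epochs", "extract_tf_epochs",
           "balanced_epochs", "TF_SPAN_IED", "TF_SPAN_NO_IED"]

TF_SPAN_IED = (-2.0, 3.0)      # seconds around the iEEG IED peak
TF_SPAN_NO_IED = (-2.5, 2.5)   # seconds around a no-IED marker


@dataclasses.dataclass
class EpochSet:
    """Condition-labelled trials: array (n_trials, n_channels, n_samples)."""

    condition: str
    data: np.ndarray
    fs: float
    channel_labels: list[str]
    marker_index: int                       # sample of the event within a trial
    event_times: np.ndarray                 # onset of each kept trial (s)
    window: AnalysisWindow | None = None    # None for fixed TF spans

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Trial time axis in seconds relative to the marker."""
        return (np.arange(self.data.shape[2]) - self.marker_index) / self.fs

    def channel(self, label: str) -> "EpochSet":
        i = self.channel_labels.index(label)
        return EpochSet(self.condition, self.data[:, [i], :], self.fs,
                        [label], self.marker_index, self.event_times,
                        self.window)

    def save(self, path) -> None:
        """Serialize to an HDF5 container (window taper not stored)."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data)
            fh.create_dataset("event_times", data=self.event_times)
            fh.attrs["condition"] = self.condition
            fh.attrs["fs"] = self.fs
            fh.attrs["marker_index"] = self.marker_index
            fh.attrs["channel_labels"] = self.channel_labels

    @classmethod
    def load(cls, path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(str(fh.attrs["condition"]), fh["data"][()],
                       float(fh.attrs["fs"]),
                       [str(c) for c in fh.attrs["channel_labels"]],
                       int(fh.attrs["marker_index"]),
                       fh["event_times"][()])


def _slice_trials(rec: Recording, onsets: np.ndarray, pre_samples: int,
                  n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Slice trials with the marker at ``pre_samples``; drop out-of-bounds."""
    starts = np.round(onsets * rec.fs).astype(int) - pre_samples
    keep = (starts >= 0) & (starts + n_samples <= rec.n_samples)
    trials = np.stack([rec.data[:, s:s + n_samples] for s in starts[keep]]) \
        if keep.any() else np.empty((0, rec.data.shape[0], n_samples))
    return trials, onsets[keep]


def extract_epochs(rec: Recording, events: EventList, window: AnalysisWindow,
                   condition: str, n_keep: int | None = None,
                   seed: int | None = None) -> EpochSet:
    """Extract tapered band epochs for one condition.

    Each trial is sliced so the marker sample sits at the window's peak
    index and multiplied by the Tukey taper.  Trials crossing recording
    edges are dropped; if more than ``n_keep`` survive, a seeded uniform
    subsample of exactly ``n_keep`` (in temporal order) is returned.
    """
    onsets = events.times(condition).to_numpy()
    trials, kept = _slice_trials(rec, onsets, window.peak_index,
                                 window.n_samples)
    if trials.shape[0] == 0:
        raise ValueError(f"no surviving {condition} epochs")
    if n_keep is not None and trials.shape[0] > n_keep:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(trials.shape[0], size=n_keep, replace=False))
        trials, kept = trials[idx], kept[idx]
    trials = trials * window.taper
    return EpochSet(condition, trials, rec.fs, rec.labels,
                    window.peak_index, kept, window)


def extract_tf_epochs(rec: Recording, events: EventList, condition: str,
                      n_keep: int | None = None,
                      seed: int | None = None) -> EpochSet:
    """Extract fixed, untapered spans for wavelet analysis.

    IED trials span -2..+3 s around the marker; no-IED trials span
    -2.5..+2.5 s.  Both are 5 s long, so maps of the two conditions
    share a time-axis length (their marker indices differ).
    """
    span = TF_SPAN_IED if condition == "IED" else TF_SPAN_NO_IED
    pre = int(round(-span[0] * rec.fs))
    n = int(round((span[1] - span[0]) * rec.fs))
    onsets = events.times(condition).to_numpy()
    trials, kept = _slice_trials(rec, onsets, pre, n)
    if trials.shape[0] == 0:
        raise ValueError(f"no surviving {condition} epochs")
    if n_keep is not None and trials.shape[0] > n_keep:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(trials.shape[0], size=n_keep, replace=False))
        trials, kept = trials[idx], kept[idx]
    return EpochSet(condition, trials, rec.fs, rec.labels, pre, kept, None)


def balanced_epochs(rec: Recording, events: EventList,
                    window: AnalysisWindow | None, seed: int,
                    tf: bool = False) -> tuple[EpochSet, EpochSet]:
    """Equal-count IED / no-IED epoch pair.

    Both conditions are first extracted without subsampling (so edge
    drops are accounted for), then the larger set is subsampled to the
    smaller count with ``seed``.  Balancing never discards below the
    minimum of the surviving counts.
    """
    if tf:
        first = {c: extract_tf_epochs(rec, events, c) for c in ("IED", "no_IED")}
    else:
        assert window is not None
        first = {c: extract_epochs(rec, events, window, c)
                 for c in ("IED", "no_IED")}
    n_keep = min(e.n_trials for e in first.values())
    out = []
    for c in ("IED", "no_IED"):
        if tf:
            out.append(extract_tf_epochs(rec, events, c, n_keep, seed))
        else:
            out.append(extract_epochs(rec, events, window, c, n_keep, seed))
    return out[0], out[1]
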