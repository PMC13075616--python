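"""Recording container and EDF input/output.

Signals are carried as a channels x samples float array in microvolts,
together with a per-channel annotation table (modality, depth-electrode
shaft/contact, gray-matter flag, ROI label).  Files are exchanged as
plain EDF (16-bit); reading goes through :func:`mne.io.read_raw_edf`,
writing through a small built-in EDF writer with per-channel auto-scaled
physical ranges.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Recording", "ChannelMap", "read_recording", "write_recording",
           "read_channel_map", "write_channel_map"]

_MODALITIES = ("scalp", "intracranial")
_REFERENCE_STATES = ("raw", "common_average", "bipolar")


@dataclasses.dataclass
class Recording:
    """Labelled multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : pandas.DataFrame
        One row per channel with at least a ``label`` and ``modality``
        column; intracranial channels may carry ``shaft`` (str),
        ``contact`` (int), ``gray_matter`` (bool) and ``roi`` (str).
    reference_state : {"raw", "common_average", "bipolar"}
    """

    data: np.ndarray
    fs: float
    channels: pd.DataFrame
    reference_state: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.reference_state not in _REFERENCE_STATES:
            raise ValueError(f"unknown reference_state {self.reference_state!r}")
        if len(self.channels) == 0:
            raise ValueError("empty channel list")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel table and data row count differ")
        labels = list(self.channels["label"])
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate channel labels")
        bad = set(self.channels["modality"]) - set(_MODALITIES)
        if bad:
            raise ValueError(f"unknown modalities {bad}")
        self.channels = self.channels.reset_index(drop=True)

    # -- convenience -------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return list(self.channels["label"])

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Sub-recording restricted to ``labels`` (in the given order)."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        rows = [index[lab] for lab in labels]
        return Recording(self.data[rows], self.fs,
                         self.channels.iloc[rows].reset_index(drop=True),
                         self.reference_state)

    def copy_with(self, data: np.ndarray | None = None,
                  fs: float | None = None,
                  channels: pd.DataFrame | None = None,
                  reference_state: str | None = None) -> "Recording":
        return Recording(self.data if data is None else data,
                         self.fs if fs is None else fs,
                         self.channels.copy() if channels is None else channels,
                         self.reference_state if reference_state is None else reference_state)


@dataclasses.dataclass
class ChannelMap:
    """Channel label -> (ROI, hemisphere, gray matter, shaft, contact) table."""

    table: pd.DataFrame  # columns: label, roi, hemisphere, gray_matter, shaft, contact

    def __post_init__(self) -> None:
        required = {"label", "roi"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"channel map missing columns {missing}")
        if self.table["label"].duplicated().any():
            raise ValueError("duplicate labels in channel map")
        self.table = self.table.reset_index(drop=True)

    def roi_of(self, label: str) -> str | None:
        hit = self.table.loc[self.table["label"] == label, "roi"]
        return None if hit.empty else hit.iloc[0]

    def channels_in(self, roi: str) -> list[str]:
        return list(self.table.loc[self.table["roi"] == roi, "label"])


# ---------------------------------------------------------------------------
# EDF writing (16-bit, one data record per second)
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    text = str(value)[:width]
    return text.ljust(width).encode("ascii")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` as a plain EDF file.

    The physical range is auto-scaled per channel so that the 16-bit
    quantization step adapts to the actual signal amplitude.  Data are
    stored in one-second records; a trailing partial second is
    zero-padded (synthetic cohorts use whole-second durations).
    """
    path = Path(path)
    n_ch, n_samp = rec.data.shape
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = rec.data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    # avoid degenerate ranges on flat channels
    flat = pmax - pmin < 1e-9
    pmax[flat] += 1.0
    pmin[flat] -= 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field(now.strftime("%d.%m.%y"), 8),
        _edf_field(now.strftime("%H.%M.%S"), 8),
        _edf_field(str(256 * (1 + n_ch)), 8),
        _edf_field("", 44),
        _edf_field(str(n_rec), 8),
        _edf_field("1", 8),
        _edf_field(str(n_ch), 4),
    ])
    labels = [_edf_field(lab, 16) for lab in rec.labels]
    sig_header = b"".join(
        [b"".join(labels)]
        + [b"".join(_edf_field("", 80) for _ in range(n_ch))]      # transducer
        + [b"".join(_edf_field("uV", 8) for _ in range(n_ch))]     # dimension
        + [b"".join(_edf_field(f"{v:.6g}", 8) for v in pmin)]
        + [b"".join(_edf_field(f"{v:.6g}", 8) for v in pmax)]
        + [b"".join(_edf_field(str(dmin), 8) for _ in range(n_ch))]
        + [b"".join(_edf_field(str(dmax), 8) for _ in range(n_ch))]
        + [b"".join(_edf_field("", 80) for _ in range(n_ch))]      # prefiltering
        + [b"".join(_edf_field(str(fs), 8) for _ in range(n_ch))]
        + [b"".join(_edf_field("", 32) for _ in range(n_ch))]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())
    return path


def read_recording(path: str | Path,
                   channels: pd.DataFrame | None = None,
                   bad_channels: Sequence[str] = ()) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts).

    Parameters
    ----------
    channels : optional channel annotation table to attach (matched and
        reordered by label); by default all channels are annotated with
        modality "scalp".
    bad_channels : labels to drop on read (the pipeline has no bad-channel
        interpolation; listed channels are simply excluded).
    """
    import mne

    raw = mne.io.read_raw_edf(Path(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels in EDF file")
    data = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned EDF
    fs = float(raw.info["sfreq"])
    keep = [i for i, lab in enumerate(labels) if lab not in set(bad_channels)]
    if not keep:
        raise ValueError("no channels left after dropping bad channels")
    labels = [labels[i] for i in keep]
    data = data[keep]
    if channels is None:
        table = pd.DataFrame({"label": labels, "modality": "scalp"})
    else:
        table = (channels.set_index("label").loc[labels].reset_index())
    return Recording(data, fs, table)


def write_channel_map(cmap: ChannelMap, path: str | Path) -> Path:
    path = Path(path)
    cmap.table.to_csv(path, sep="\t", index=False)
    return path


def read_channel_map(path: str | Path) -> ChannelMap:
    return ChannelMap(pd.read_csv(path, sep="\t"))
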