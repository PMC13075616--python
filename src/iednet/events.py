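"""Event lists: expert-marked condition markers and detector output."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

__all__ = ["EventList", "CONDITIONS"]

CONDITIONS = ("IED", "no_IED")


@dataclasses.dataclass
class EventList:
    """Marked events for one recording session.

    ``markers`` has one row per expert-marked epoch center with columns
    ``onset_s`` (seconds, ascending), ``condition`` ("IED" or "no_IED")
    and ``label`` (source ROI for IED markers, "" otherwise).
    ``detections`` optionally carries automated detector output with
    columns ``time_s`` and ``channel_label`` for rate analyses.
    """

    markers: pd.DataFrame
    detections: pd.DataFrame | None = None
    duration: float | None = None

    def __post_init__(self) -> None:
        m = self.markers
        if not {"onset_s", "condition"} <= set(m.columns):
            raise ValueError("markers need onset_s and condition columns")
        if not m["onset_s"].is_monotonic_increasing:
            raise ValueError("marker times must be sorted ascending")
        bad = set(m["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {bad}")
        if self.duration is not None:
            if (m["onset_s"] < 0).any() or (m["onset_s"] > self.duration).any():
                raise ValueError("marker outside the recording")
        self.markers = m.reset_index(drop=True)

    def times(self, condition: str) -> pd.Series:
        return self.markers.loc[self.markers["condition"] == condition,
                                "onset_s"].reset_index(drop=True)

    def counts(self) -> dict[str, int]:
        return {c: int((self.markers["condition"] == c).sum())
                for c in CONDITIONS}

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.markers.to_csv(path, sep="\t", index=False)
        if self.detections is not None:
            self.detections.to_csv(path.with_suffix(".detections.tsv"),
                                   sep="\t", index=False)
        return path

    @classmethod
    def read(cls, path: str | Path, duration: float | None = None) -> "EventList":
        path = Path(path)
        markers = pd.read_csv(path, sep="\t")
        det_path = path.with_suffix(".detections.tsv")
        det = pd.read_csv(det_path, sep="\t") if det_path.exists() else None
        return cls(markers, det, duration)
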