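"""Packaged cortical + medial temporal parcellation and hemisphere swapping.

The atlas is the Desikan-Killiany cortical parcellation (34 labels per
hemisphere) extended with hippocampus and amygdala and stripped of
non-cortical deep structures (basal ganglia, thalamus, brainstem,
cerebellum), giving 72 regions.  Because discharges may originate from
either hemisphere, group analyses relabel hemispheres per patient so
"ipsi" always denotes the discharge side: for a left-sided patient every
left/right label pair is exchanged, for a right-sided patient the
mapping is the identity.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

__all__ = ["load_atlas", "hemisphere_swap_label", "hemisphere_swap_labels",
           "hemisphere_swap_matrix", "to_ipsi_contra"]

_HEMIS = {"lh", "rh"}


def load_atlas() -> pd.DataFrame:
    """Packaged 72-ROI table: columns label, roi, hemisphere, cortical."""
    ref = importlib.resources.files("iednet.data") / "desikan_killiany_72.tsv"
    table = pd.read_csv(ref, sep="\t")
    if len(table) != 72 or table["label"].duplicated().any():
        raise RuntimeError("packaged atlas table is corrupted")
    if set(table["hemisphere"]) != _HEMIS:
        raise RuntimeError("atlas labels missing hemisphere tags")
    return table


def hemisphere_swap_label(label: str, ied_side: str) -> str:
    """Map a "roi_lh"/"roi_rh" label to "roi_ipsi"/"roi_contra".

    ``ied_side`` is the hemisphere generating the selected discharges;
    applying the induced lh<->rh exchange twice is the identity.
    """
    if ied_side not in ("left", "right"):
        raise ValueError("ied_side must be 'left' or 'right'")
    base, _, hemi = label.rpartition("_")
    if hemi not in _HEMIS:
        raise ValueError(f"label {label!r} has no hemisphere suffix")
    ipsi_hemi = "lh" if ied_side == "left" else "rh"
    return f"{base}_ipsi" if hemi == ipsi_hemi else f"{base}_contra"


def hemisphere_swap_labels(labels: list[str], ied_side: str) -> list[str]:
    return [hemisphere_swap_label(lab, ied_side) for lab in labels]


def to_ipsi_contra(label_ic: str, ied_side: str) -> str:
    """Inverse mapping: "roi_ipsi"/"roi_contra" to "roi_lh"/"roi_rh"."""
    if ied_side not in ("left", "right"):
        raise ValueError("ied_side must be 'left' or 'right'")
    base, _, tag = label_ic.rpartition("_")
    if tag not in ("ipsi", "contra"):
        raise ValueError(f"label {label_ic!r} has no ipsi/contra suffix")
    ipsi_hemi = "lh" if ied_side == "left" else "rh"
    other = "rh" if ipsi_hemi == "lh" else "lh"
    return f"{base}_{ipsi_hemi}" if tag == "ipsi" else f"{base}_{other}"


def hemisphere_swap_matrix(W: np.ndarray, labels: list[str],
                           ied_side: str) -> tuple[np.ndarray, list[str]]:
    """Relabel a connectivity matrix into ipsi/contra space.

    A pure permutation/relabelling: the multiset of entries is
    preserved.  Output rows/columns are sorted by the new labels.
    """
    new = hemisphere_swap_labels(labels, ied_side)
    order = np.argsort(new)
    return W[np.ix_(order, order)], [new[i] for i in order]
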