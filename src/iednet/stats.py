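"""Group statistics: cluster-based permutation tests, Wilcoxon, FDR.

Time-frequency contrasts across patients use a paired cluster-based
permutation test: a one-sided paired t-statistic per pixel, clusters of
4-connected suprathreshold pixels, cluster mass = summed t, and a null
distribution of the maximum cluster mass over sign flips of the
per-patient difference maps.  For n <= 20 patients all 2^n sign
assignments are enumerated (512 for nine patients), identity included,
so the smallest attainable p is 1/2^n and p-values are deterministic.

Scalar band/ROI/network measures use one-sided Wilcoxon signed-rank
tests (exact distribution for n <= 25) with Benjamini-Hochberg FDR
control across the comparison family.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = ["ClusterTestResult", "cluster_permutation", "n_sign_flips",
           "wilcoxon_one_sided", "fdr_bh", "group_test_table"]

MAX_EXHAUSTIVE = 20
_STRUCTURE = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def n_sign_flips(n_patients: int) -> int:
    """Number of sign assignments enumerated for a paired design."""
    if n_patients > MAX_EXHAUSTIVE:
        raise ValueError("exhaustive enumeration capped at 2^20")
    return 2 ** n_patients


@dataclasses.dataclass
class Cluster:
    mask: np.ndarray      # boolean (n_freqs, n_times)
    mass: float           # summed t inside the cluster
    p: float


@dataclasses.dataclass
class ClusterTestResult:
    t_obs: np.ndarray
    clusters: list[Cluster]
    null_max_mass: np.ndarray
    alpha_form: float
    alpha_cluster: float
    side: str
    n_permutations: int

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha_cluster]

    def report(self, coi_mask: np.ndarray | None = None) -> list[dict]:
        """JSON-ready cluster summaries (optionally with COI overlap)."""
        out = []
        for c in self.clusters:
            entry = {"mass": float(c.mass), "p": float(c.p),
                     "n_pixels": int(c.mask.sum()),
                     "significant": bool(c.p < self.alpha_cluster)}
            if coi_mask is not None:
                entry["coi_overlap"] = float(
                    (c.mask & coi_mask).sum() / max(c.mask.sum(), 1))
            out.append(entry)
        return out


def _t_maps(diffs_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired t maps for many sign assignments at once.

    ``diffs_flat`` is (n_patients, n_pixels); ``signs`` is (n_perm,
    n_patients) of +-1.  Sum of squares is sign-invariant, so only the
    mean changes per permutation.
    """
    n = diffs_flat.shape[0]
    mean = signs @ diffs_flat / n
    ss = (diffs_flat ** 2).sum(axis=0)
    var = (ss[None, :] - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def _max_cluster_mass(t_map: np.ndarray, t_crit: float) -> float:
    labels, n_lab = ndimage.label(t_map > t_crit, structure=_STRUCTURE)
    if n_lab == 0:
        return 0.0
    masses = ndimage.sum_labels(t_map, labels, index=np.arange(1, n_lab + 1))
    return float(masses.max())


def cluster_permutation(maps_cond1: np.ndarray, maps_cond2: np.ndarray,
                        alpha_form: float, alpha_cluster: float,
                        side: str = "greater",
                        seed: int | None = None,
                        n_random: int = 1024) -> ClusterTestResult:
    """Paired cluster-based permutation test on per-patient TF maps.

    ``maps_cond1/2`` are (n_patients, n_freqs, n_times) and share axes.
    ``side="greater"`` tests cond1 > cond2 (positive clusters);
    ``side="less"`` negates the differences first.
    """
    a = np.asarray(maps_cond1, dtype=float)
    b = np.asarray(maps_cond2, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("condition maps must share (n_patients, nf, nt) shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least two patients")
    diffs = a - b
    if side == "less":
        diffs = -diffs
    elif side != "greater":
        raise ValueError("side must be 'greater' or 'less'")
    shape = diffs.shape[1:]
    flat = diffs.reshape(n, -1)

    if n <= MAX_EXHAUSTIVE:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_random, n))
        signs[0] = 1.0  # identity included for validity
    n_perm = signs.shape[0]
    t_crit = sstats.t.ppf(1 - alpha_form, df=n - 1)
    t_all = _t_maps(flat, signs)

    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _max_cluster_mass(t_all[k].reshape(shape), t_crit)

    # observed map taken from the identity row of the same batched
    # computation, so null[identity] >= every observed mass holds exactly
    identity = int(np.nonzero((signs == 1.0).all(axis=1))[0][0])
    t_obs = t_all[identity].reshape(shape)
    labels, n_lab = ndimage.label(t_obs > t_crit, structure=_STRUCTURE)
    clusters = []
    if n_lab:
        # same summation routine as the null pass, so the identity
        # permutation compares float-exactly against every observed mass
        masses = ndimage.sum_labels(t_obs, labels,
                                    index=np.arange(1, n_lab + 1))
        for lab, mass in enumerate(masses, start=1):
            p = float((null >= mass).mean())
            clusters.append(Cluster(mask=labels == lab, mass=float(mass), p=p))
    clusters.sort(key=lambda c: c.p)
    return ClusterTestResult(t_obs, clusters, null, alpha_form,
                             alpha_cluster, side, n_perm)


def wilcoxon_one_sided(values_cond1: np.ndarray,
                       values_cond2: np.ndarray) -> tuple[float, float]:
    """One-sided paired Wilcoxon signed-rank test (cond1 > cond2).

    Returns (median difference, p).  Exact distribution for n <= 25
    without ties; raises on all-zero differences.
    """
    d = np.asarray(values_cond1, dtype=float) - np.asarray(values_cond2, dtype=float)
    if d.size < 5:
        raise ValueError("need at least five pairs")
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all-zero differences")
    method = "exact" if nz.size <= 25 else "approx"
    res = sstats.wilcoxon(nz, alternative="greater", method=method)
    return float(np.median(d)), float(res.pvalue)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, significance flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def group_test_table(values: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Wilcoxon + FDR over a family of (unit, band) measures.

    ``values`` must have columns ``unit``, ``band``, ``patient``,
    ``IED``, ``no_IED``; the FDR family is the whole table.  Returns
    rows (unit, band, median_diff, p, p_adj, significant).
    """
    rows = []
    for (unit, band), grp in values.groupby(["unit", "band"], sort=False):
        try:
            med, p = wilcoxon_one_sided(grp["IED"].to_numpy(),
                                        grp["no_IED"].to_numpy())
        except ValueError:
            med, p = 0.0, np.nan
        rows.append({"unit": unit, "band": band, "median_diff": med, "p": p})
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    p_adj = np.full(len(table), np.nan)
    sig = np.zeros(len(table), dtype=bool)
    if ok.any():
        p_adj[ok], sig[ok] = fdr_bh(table.loc[ok, "p"].to_numpy(), q)
    table["p_adj"] = p_adj
    table["significant"] = sig
    return table
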