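"""End-to-end analysis: preprocessing to group statistics.

For each patient the pipeline (1) decimates both modalities to 200 Hz,
band-passes 1-35 Hz, re-references (common average for scalp, bipolar
for depth electrodes), (2) reconstructs ROI time courses from scalp
epochs through the supplied linear inverse operator (prewhitened with a
covariance estimated from the no-IED epochs), (3) computes spike-locked
Morse-wavelet ERSP/ITC maps for the marked medial temporal unit in both
modalities, (4) computes band power, spectral ITC, wPLI connectivity
and weighted network metrics for hdEEG(ROI), iEEG(channel) and
iEEG(ROI) levels with equal-count condition epochs, and (5) runs the
group statistics: cluster-based permutation tests on the
time-frequency maps and one-sided Wilcoxon signed-rank tests with BH-FDR
correction for scalar measures.  Intracranial ROI tests are gated to
regions sampled in at least five patients.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .atlas import hemisphere_swap_label, load_atlas
from .connectivity import (ConnectivityMatrix, aggregate_pairs_to_roi,
                           trial_cross_spectra, wpli)
from .epochs import EpochSet, balanced_epochs
from .events import EventList
from .io import ChannelMap, Recording
from .inverse import (InverseOperator, build_ridge_inverse,
                      estimate_covariance, roi_timecourses)
from .network import network_metrics
from .preprocess import bandpass, bipolar, common_average, downsample
from .spectral import aggregate_units_to_roi, band_itc, band_psd
from .stats import cluster_permutation, group_test_table, wilcoxon_one_sided, fdr_bh
from .synth import SyntheticConfig, patient_bundle, PatientData
from .timefreq import baseline_power, ersp, itc
from .windows import BANDS, AnalysisWindow, build_window

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "rates_and_iz",
           "write_results"]

LEVELS = ("hdEEG_ROI", "iEEG_channel", "iEEG_ROI")


@dataclasses.dataclass
class RunConfig:
    """Pipeline parameters: inputs, bands, alphas, seeds, gates."""

    synth: SyntheticConfig
    fs_analysis: float = 200.0
    band_edges: tuple[float, float] = (1.0, 35.0)
    bands: tuple = BANDS
    alpha_ersp_form: float = 0.0005
    alpha_ersp_cluster: float = 0.001
    alpha_itc_form: float = 0.05
    alpha_itc_cluster: float = 0.05
    q_fdr: float = 0.05
    min_patients_per_roi: int = 5
    tf_time_decim: int = 10
    ridge: float = 0.1
    seed: int = 0


@dataclasses.dataclass
class PipelineResult:
    band_table: pd.DataFrame          # patient, level, unit, band, condition, measure, value
    global_table: pd.DataFrame        # patient, level, band, condition, integration, segregation
    roi_tests: pd.DataFrame           # level, measure, unit, band, median_diff, p, p_adj, significant
    network_tests: pd.DataFrame       # level, measure, band, median_diff, p, p_adj, significant
    cluster_results: dict             # (modality, kind) -> ClusterTestResult
    cluster_report: dict              # JSON-ready summaries
    rates: pd.DataFrame               # patient, unit, roi, rate_per_min, normalized, in_iz
    increase_counts: pd.DataFrame     # level, measure, band, n_increase, n_patients
    roi_patient_counts: pd.Series     # iEEG sampling count per ROI
    connectivity: dict                # (patient, level, band, condition) -> ConnectivityMatrix
    run_log: dict


# ---------------------------------------------------------------------------
# IED rates / irritative zone
# ---------------------------------------------------------------------------

def rates_and_iz(events: EventList, window: AnalysisWindow,
                 cmap: ChannelMap) -> pd.DataFrame:
    """Detector IED rates inside the marker-centred analysis windows.

    Rate = detections falling in the union of per-marker windows divided
    by the total windowed time (per minute); normalized by the
    per-patient maximum; a unit joins the irritative zone when its rate
    exceeds 1/10 of that maximum.
    """
    if events.detections is None or len(events.detections) == 0:
        raise ValueError("no detector events")
    marks = events.times("IED").to_numpy()
    if marks.size == 0:
        raise ValueError("no marked IEDs to centre windows on")
    intervals = sorted((m - window.pre, m + window.post) for m in marks)
    merged: list[list[float]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    total_min = sum(hi - lo for lo, hi in merged) / 60.0
    if total_min <= 0:
        raise ValueError("zero total window time")

    det = events.detections
    in_any = np.zeros(len(det), dtype=bool)
    for lo, hi in merged:
        in_any |= (det["time_s"] >= lo) & (det["time_s"] <= hi)
    counts = det.loc[in_any, "channel_label"].value_counts()

    units = list(cmap.table["label"])
    rate = pd.Series([counts.get(u, 0) / total_min for u in units],
                     index=units, name="rate_per_min")
    maximum = rate.max()
    if maximum == 0:
        raise ValueError("no detection falls inside any analysis window")
    out = pd.DataFrame({"unit": units, "rate_per_min": rate.values})
    out["roi"] = [cmap.roi_of(u) for u in units]
    out["normalized"] = out["rate_per_min"] / maximum
    out["in_iz"] = out["rate_per_min"] > maximum / 10.0
    return out


# ---------------------------------------------------------------------------
# per-patient processing
# ---------------------------------------------------------------------------

def _preprocess(rec: Recording, run: RunConfig, kind: str) -> Recording:
    rec = downsample(rec, run.fs_analysis)
    rec = bandpass(rec, *run.band_edges)
    return common_average(rec) if kind == "scalp" else bipolar(rec)


def _swap_channel_rois(rec: Recording, side: str) -> Recording:
    """Relabel bipolar-pair ROI annotations into ipsi/contra space."""
    tab = rec.channels.copy()
    tab["roi_ic"] = [hemisphere_swap_label(r, side) if isinstance(r, str) and r
                     else "" for r in tab["roi"]]
    return rec.copy_with(channels=tab)


def _build_inverse(mixing: np.ndarray, scalp_proc: Recording,
                   tf_no_ied: EpochSet, source_rois: Sequence[str],
                   ridge: float) -> InverseOperator:
    """Inverse from the generator's effective mixing, CAR-corrected."""
    n_sens = scalp_proc.data.shape[0]
    car = np.eye(n_sens) - np.ones((n_sens, n_sens)) / n_sens
    forward = car @ mixing.T                      # sensors x sources
    cov = estimate_covariance(tf_no_ied)
    return build_ridge_inverse(forward, cov, list(source_rois), ridge)


@dataclasses.dataclass
class _PatientStage:
    index: int
    tf_maps: dict            # (modality, kind) -> np.ndarray (nf, nt)
    coi_halfwidth: np.ndarray
    tf_freqs: np.ndarray
    tf_times: np.ndarray
    band_rows: list
    global_rows: list
    conn: dict               # (level, band, condition) -> ConnectivityMatrix
    rates: pd.DataFrame
    sampled_rois: list


def _analyse_patient(p: PatientData, run: RunConfig, index: int) -> _PatientStage:
    ieeg = _swap_channel_rois(_preprocess(p.ieeg, run, "ieeg"), p.ied_side)
    scalp = _preprocess(p.scalp, run, "scalp")
    events = p.events
    ied_label = run.synth.ied_source_label

    hip_rows = ieeg.channels.index[ieeg.channels["roi_ic"] == ied_label]
    if len(hip_rows) == 0:
        raise RuntimeError(f"stage tf: no intracranial channel samples {ied_label}")
    hip_channel = ieeg.channels.loc[hip_rows[0], "label"]

    # --- time-frequency stage -------------------------------------------
    tf_ied_i, tf_no_i = balanced_epochs(ieeg, events, None, run.seed, tf=True)
    tf_ied_s, tf_no_s = balanced_epochs(scalp, events, None, run.seed, tf=True)
    inv = _build_inverse(p.mixing, scalp, tf_no_s,
                         run.synth.source_roi_labels, run.ridge)
    roi_tf = {c: roi_timecourses(e, inv)
              for c, e in (("IED", tf_ied_s), ("no_IED", tf_no_s))}

    tf_maps, coi, freqs, times = {}, None, None, None
    for modality, pairs in (
            ("iEEG", {"IED": tf_ied_i.channel(hip_channel),
                      "no_IED": tf_no_i.channel(hip_channel)}),
            ("hdEEG", {c: e.channel(ied_label) for c, e in roi_tf.items()})):
        base = baseline_power(pairs["no_IED"])
        for cond, ep in pairs.items():
            m_ersp = ersp(ep, base).decimate_time(run.tf_time_decim)
            m_itc = itc(ep).decimate_time(run.tf_time_decim)
            tf_maps[(modality, "ersp", cond)] = m_ersp.values
            tf_maps[(modality, "itc", cond)] = m_itc.values
            if cond == "IED":
                coi, freqs, times = (m_ersp.coi_halfwidth, m_ersp.freqs,
                                     m_ersp.times)

    # --- band stage -------------------------------------------------------
    band_rows, global_rows, conn = [], [], {}
    roi_map_ieeg = ChannelMap(pd.DataFrame({
        "label": ieeg.channels["label"],
        "roi": ieeg.channels["roi_ic"]}))
    for band in run.bands:
        win = build_window(band, run.fs_analysis)
        ied_i, no_i = balanced_epochs(ieeg, events, win, run.seed)
        ied_s, no_s = balanced_epochs(scalp, events, win, run.seed)
        eps = {"IED": {"iEEG": ied_i, "hd": roi_timecourses(ied_s, inv)},
               "no_IED": {"iEEG": no_i, "hd": roi_timecourses(no_s, inv)}}
        for cond, by_mod in eps.items():
            # spectral values
            for level, ep, agg in (("iEEG_channel", by_mod["iEEG"], False),
                                   ("hdEEG_ROI", by_mod["hd"], False)):
                power = band_psd(ep, band)
                locked = band_itc(ep, band)
                if level == "iEEG_channel":
                    roi_power = aggregate_units_to_roi(power, roi_map_ieeg)
                    roi_locked = aggregate_units_to_roi(locked, roi_map_ieeg)
                    for unit in roi_power.index:
                        band_rows.append((index, "iEEG_ROI", unit, band.name,
                                          cond, "power", roi_power[unit]))
                        band_rows.append((index, "iEEG_ROI", unit, band.name,
                                          cond, "itc", roi_locked[unit]))
                for unit in power.index:
                    band_rows.append((index, level, unit, band.name, cond,
                                      "power", power[unit]))
                    band_rows.append((index, level, unit, band.name, cond,
                                      "itc", locked[unit]))
            # connectivity + networks
            mats = {}
            cs = trial_cross_spectra(by_mod["iEEG"], band)
            mats["iEEG_channel"] = wpli(cs, by_mod["iEEG"].channel_labels,
                                        band.name, cond)
            mats["iEEG_ROI"] = aggregate_pairs_to_roi(mats["iEEG_channel"],
                                                      roi_map_ieeg)
            cs_hd = trial_cross_spectra(by_mod["hd"], band)
            mats["hdEEG_ROI"] = wpli(cs_hd, by_mod["hd"].channel_labels,
                                     band.name, cond)
            for level, cm in mats.items():
                conn[(level, band.name, cond)] = cm
                nm = network_metrics(cm.W, cm.labels)
                for unit, c, ne in zip(nm.labels, nm.clustering,
                                       nm.nodal_efficiency):
                    band_rows.append((index, level, unit, band.name, cond,
                                      "clustering", c))
                    band_rows.append((index, level, unit, band.name, cond,
                                      "nodal_efficiency", ne))
                global_rows.append((index, level, band.name, cond,
                                    nm.global_efficiency, nm.mean_clustering))

    # --- detector rates ---------------------------------------------------
    delta_win = build_window(run.bands[0], run.fs_analysis)
    cmap_contacts = ChannelMap(pd.DataFrame({
        "label": p.channel_map.table["label"],
        "roi": [hemisphere_swap_label(r, p.ied_side) if isinstance(r, str) and r
                else "" for r in p.channel_map.table["roi"]]}))
    rates = rates_and_iz(events, delta_win, cmap_contacts)
    rates.insert(0, "patient", index)

    return _PatientStage(index, tf_maps, coi, freqs, times, band_rows,
                         global_rows, conn, rates, p.sampled_rois)


# ---------------------------------------------------------------------------
# group level
# ---------------------------------------------------------------------------

def _pivot_conditions(table: pd.DataFrame, measure: str,
                      level: str) -> pd.DataFrame:
    sub = table[(table["measure"] == measure) & (table["level"] == level)]
    wide = sub.pivot_table(index=["unit", "band", "patient"],
                           columns="condition", values="value").reset_index()
    return wide.dropna(subset=["IED", "no_IED"])


def run_pipeline(run: RunConfig) -> PipelineResult:
    """Run the full analysis on a (synthetic) cohort; deterministic."""
    cfg = run.synth
    stages = []
    for i in range(cfg.n_patients):
        try:
            stages.append(_analyse_patient(patient_bundle(cfg, i), run, i))
        except Exception as err:  # noqa: BLE001 - stage-tagged abort
            raise RuntimeError(f"patient {i}: {err}") from err

    band_table = pd.DataFrame(
        [r for s in stages for r in s.band_rows],
        columns=["patient", "level", "unit", "band", "condition", "measure",
                 "value"])
    global_table = pd.DataFrame(
        [r for s in stages for r in s.global_rows],
        columns=["patient", "level", "band", "condition", "integration",
                 "segregation"])
    rates = pd.concat([s.rates for s in stages], ignore_index=True)

    # iEEG ROI sampling gate
    counts = pd.Series(
        pd.concat([pd.Series(sorted(set(s.sampled_rois))) for s in stages],
                  ignore_index=True).value_counts(), name="n_patients")
    gated = set(counts[counts >= run.min_patients_per_roi].index)

    # --- cluster-based permutation tests on TF maps ----------------------
    cluster_results, cluster_report = {}, {}
    alphas = {"ersp": (run.alpha_ersp_form, run.alpha_ersp_cluster),
              "itc": (run.alpha_itc_form, run.alpha_itc_cluster)}
    coi_mask = None
    if stages:
        s0 = stages[0]
        edge = np.minimum(s0.tf_times - s0.tf_times[0],
                          s0.tf_times[-1] - s0.tf_times)
        coi_mask = edge[None, :] >= s0.coi_halfwidth[:, None]
    for modality in ("iEEG", "hdEEG"):
        for kind in ("ersp", "itc"):
            a = np.stack([s.tf_maps[(modality, kind, "IED")] for s in stages])
            b = np.stack([s.tf_maps[(modality, kind, "no_IED")] for s in stages])
            form, clus = alphas[kind]
            res = cluster_permutation(a, b, form, clus, side="greater",
                                      seed=run.seed)
            cluster_results[(modality, kind)] = res
            cluster_report[f"{modality}_{kind}"] = res.report(coi_mask)

    # --- scalar group tests ----------------------------------------------
    roi_tests = []
    for level in ("hdEEG_ROI", "iEEG_ROI"):
        for measure in ("power", "itc", "clustering", "nodal_efficiency"):
            wide = _pivot_conditions(band_table, measure, level)
            if level == "iEEG_ROI":
                wide = wide[wide["unit"].isin(gated)]
            if wide.empty:
                continue
            tab = group_test_table(wide, run.q_fdr)
            tab.insert(0, "measure", measure)
            tab.insert(0, "level", level)
            roi_tests.append(tab)
    roi_tests = pd.concat(roi_tests, ignore_index=True)

    network_tests, counts_rows = [], []
    for level in LEVELS:
        sub = global_table[global_table["level"] == level]
        for measure in ("integration", "segregation"):
            wide = sub.pivot_table(index=["band", "patient"],
                                   columns="condition",
                                   values=measure).reset_index()
            rows = []
            for band, grp in wide.groupby("band", sort=False):
                med, pval = wilcoxon_one_sided(grp["IED"].to_numpy(),
                                               grp["no_IED"].to_numpy())
                rows.append({"level": level, "measure": measure, "band": band,
                             "median_diff": med, "p": pval})
                n_inc = int((grp["IED"] > grp["no_IED"]).sum())
                counts_rows.append({"level": level, "measure": measure,
                                    "band": band, "n_increase": n_inc,
                                    "n_patients": len(grp)})
            fam = pd.DataFrame(rows)
            fam["p_adj"], fam["significant"] = fdr_bh(fam["p"].to_numpy(),
                                                      run.q_fdr)
            network_tests.append(fam)
    network_tests = pd.concat(network_tests, ignore_index=True)
    increase_counts = pd.DataFrame(counts_rows)

    connectivity = {(s.index, level, band, cond): cm
                    for s in stages
                    for (level, band, cond), cm in s.conn.items()}
    run_log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "n_patients": cfg.n_patients,
        "seed_pipeline": run.seed,
        "seed_cohort": cfg.seed,
        "bands": [b.name for b in run.bands],
        "alphas": alphas,
        "q_fdr": run.q_fdr,
        "ieeg_roi_gate": sorted(gated),
        "decisions": [
            "ERSP baseline: per-patient mean no-IED power per frequency",
            "wPLI estimator: non-debiased, across trials",
            "clustering: Onnela weighted form on unthresholded matrices",
            "ROI series: per-epoch first singular vector, patient-level sign",
            "epoch balancing seed recorded in seed_pipeline",
        ],
    }
    return PipelineResult(band_table, global_table, roi_tests, network_tests,
                          cluster_results, cluster_report, rates,
                          increase_counts, counts, connectivity, run_log)


def write_results(result: PipelineResult, outdir: str | Path) -> Path:
    """Write the tabular results bundle as TSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.band_table.to_csv(outdir / "band_table.tsv", sep="\t", index=False)
    result.global_table.to_csv(outdir / "network_global.tsv", sep="\t",
                               index=False)
    result.roi_tests.to_csv(outdir / "roi_tests.tsv", sep="\t", index=False)
    result.network_tests.to_csv(outdir / "network_tests.tsv", sep="\t",
                                index=False)
    result.rates.to_csv(outdir / "ied_rates.tsv", sep="\t", index=False)
    result.increase_counts.to_csv(outdir / "increase_counts.tsv", sep="\t",
                                  index=False)
    conn_frames = [cm.to_frame().assign(patient=pat, level=level)
                   for (pat, level, band, cond), cm in result.connectivity.items()]
    if conn_frames:
        pd.concat(conn_frames, ignore_index=True).to_csv(
            outdir / "connectivity.tsv", sep="\t", index=False)
    (outdir / "cluster_report.json").write_text(
        json.dumps(result.cluster_report, indent=1))
    with open(outdir / "run_log.jsonl", "w") as fh:
        fh.write(json.dumps(result.run_log) + "\n")
    return outdir
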