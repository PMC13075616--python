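"""Atlas, hemisphere swapping, inverse summarization, rates, pipeline."""

import numpy as np
import pandas as pd
import pytest

from iednet.atlas import (hemisphere_swap_label, hemisphere_swap_matrix,
                          load_atlas, to_ipsi_contra)
from iednet.epochs import EpochSet, extract_tf_epochs
from iednet.events import EventList
from iednet.io import ChannelMap
from iednet.inverse import (InverseOperator, build_ridge_inverse,
                            estimate_covariance, roi_timecourses,
                            whitener_from_cov)
from iednet.pipeline import RunConfig, rates_and_iz, run_pipeline
from iednet.preprocess import bandpass, common_average, downsample
from iednet.synth import SyntheticConfig, ied_template
from iednet.windows import BANDS, build_window


class TestAtlas:
    def test_seventy_two_unique_regions(self):
        atlas = load_atlas()
        assert len(atlas) == 72
        assert atlas["label"].is_unique
        assert set(atlas["hemisphere"]) == {"lh", "rh"}

    def test_medial_temporal_structures_present_bilaterally(self):
        rois = set(load_atlas()["label"])
        for struct in ("hippocampus", "amygdala"):
            assert {f"{struct}_lh", f"{struct}_rh"} <= rois

    def test_non_cortical_deep_structures_removed(self):
        names = " ".join(load_atlas()["roi"])
        for excluded in ("thalamus", "brainstem", "cerebellum", "caudate",
                         "putamen", "pallidum"):
            assert excluded not in names


class TestHemisphereSwap:
    def test_right_sided_patient_right_labels_are_ipsi(self):
        assert hemisphere_swap_label("hippocampus_rh", "right") == \
            "hippocampus_ipsi"
        assert hemisphere_swap_label("hippocampus_lh", "right") == \
            "hippocampus_contra"

    def test_left_sided_patient_swaps(self):
        assert hemisphere_swap_label("hippocampus_lh", "left") == \
            "hippocampus_ipsi"

    def test_involution_through_both_spaces(self):
        for side in ("left", "right"):
            for label in ("fusiform_lh", "insula_rh"):
                ic = hemisphere_swap_label(label, side)
                assert to_ipsi_contra(ic, side) == label

    def test_matrix_swap_preserves_entry_multiset(self, rng):
        labels = ["a_lh", "a_rh", "b_lh", "b_rh"]
        W = rng.uniform(size=(4, 4))
        W = (W + W.T) / 2
        swapped, new_labels = hemisphere_swap_matrix(W, labels, "left")
        assert sorted(new_labels) == new_labels
        assert np.allclose(np.sort(W, axis=None),
                           np.sort(swapped, axis=None))

    def test_unpaired_label_rejected(self):
        with pytest.raises(ValueError):
            hemisphere_swap_label("vertex", "left")


class TestRoiTimecourses:
    @staticmethod
    def identity_operator(rois):
        n = len(rois)
        return InverseOperator(kernel=np.eye(n), whitener=np.eye(n),
                               source_rois=list(rois))

    def test_rank_one_roi_recovers_true_series(self, rng):
        t = np.linspace(0, 1, 200)
        s = np.sin(2 * np.pi * 3 * t)
        data = np.stack([s, 2 * s, rng.standard_normal(200)])[None]
        ep = EpochSet("IED", data, 200.0, ["x", "y", "z"], 100, np.zeros(1))
        out = roi_timecourses(ep, self.identity_operator(["A", "A", "B"]))
        rec = out.data[0, out.channel_labels.index("A")]
        r = np.corrcoef(rec, s)[0, 1]
        assert abs(r) > 0.999
        assert r > 0                 # sign fixed against the ROI mean

    def test_identity_covariance_whitening_is_noop(self):
        assert np.allclose(whitener_from_cov(np.eye(5)), np.eye(5))

    def test_covariance_estimate_recovers_sensor_covariance(self, rng):
        L = np.array([[1.0, 0.0], [0.7, 0.5]])
        x = (L @ rng.standard_normal((2, 20000)))[None]
        ep = EpochSet("IED", x, 200.0, ["a", "b"], 0, np.zeros(1))
        assert np.allclose(estimate_covariance(ep), L @ L.T, atol=0.1)

    def test_synthetic_hippocampal_series_matches_template(self, small_cfg,
                                                           patient0):
        scalp = common_average(bandpass(downsample(patient0.scalp, 200.0)))
        ev = patient0.events
        tf_no = extract_tf_epochs(scalp, ev, "no_IED")
        tf_ied = extract_tf_epochs(scalp, ev, "IED")
        n_sens = scalp.data.shape[0]
        car = np.eye(n_sens) - np.ones((n_sens, n_sens)) / n_sens
        inv = build_ridge_inverse(car @ patient0.mixing.T,
                                  estimate_covariance(tf_no),
                                  list(small_cfg.source_roi_labels))
        roi = roi_timecourses(tf_ied, inv)
        series = roi.data[:, roi.channel_labels.index("hippocampus_ipsi"), :]
        avg = series.mean(axis=0)
        tpl, peak = ied_template(small_cfg.ied_waveform, 200.0)
        start = roi.marker_index - peak
        window = avg[start:start + tpl.size]
        r = np.corrcoef(window, tpl)[0, 1]
        assert r > 0.5

    def test_sensor_mismatch_rejected(self, rng):
        ep = EpochSet("IED", rng.standard_normal((2, 3, 50)), 200.0,
                      ["a", "b", "c"], 10, np.zeros(2))
        with pytest.raises(ValueError):
            roi_timecourses(ep, self.identity_operator(["A", "B"]))


class TestRatesAndIz:
    @staticmethod
    def build(counts):
        """Markers spaced 10 s apart; per-unit detection counts inside."""
        marks = [20.0, 30.0, 40.0, 50.0]
        markers = pd.DataFrame({"onset_s": marks, "condition": "IED",
                                "label": "hippocampus_ipsi"})
        det = []
        for unit, c in counts.items():
            for k in range(c):
                det.append({"time_s": marks[k % 4] + 0.2 + 0.001 * k,
                            "channel_label": unit})
        det = pd.DataFrame(det).sort_values("time_s")
        events = EventList(markers, det)
        cmap = ChannelMap(pd.DataFrame({"label": list(counts),
                                        "roi": list(counts)}))
        win = build_window(BANDS[0], 200.0)
        return rates_and_iz(events, win, cmap)

    def test_normalized_rates_and_tenth_rule(self):
        out = self.build({"A": 20, "B": 4, "C": 1}).set_index("unit")
        assert out.loc["A", "normalized"] == 1.0
        assert out.loc["B", "normalized"] == pytest.approx(0.2)
        assert out.loc["C", "normalized"] == pytest.approx(0.05)
        assert list(out["in_iz"]) == [True, True, False]

    def test_single_active_unit_is_irritative_zone(self):
        out = self.build({"A": 5}).set_index("unit")
        assert out.loc["A", "normalized"] == 1.0 and out.loc["A", "in_iz"]

    def test_max_rate_unit_always_flagged(self):
        out = self.build({"A": 7, "B": 7, "C": 2})
        top = out.loc[out["normalized"] == 1.0, "in_iz"]
        assert top.all()

    def test_detections_outside_windows_ignored(self):
        markers = pd.DataFrame({"onset_s": [20.0], "condition": ["IED"],
                                "label": ["x"]})
        det = pd.DataFrame({"time_s": [5.0, 20.1], "channel_label": ["A", "A"]})
        cmap = ChannelMap(pd.DataFrame({"label": ["A"], "roi": ["A"]}))
        win = build_window(BANDS[0], 200.0)
        out = rates_and_iz(EventList(markers, det), win, cmap)
        assert out["rate_per_min"].iloc[0] == pytest.approx(1 / (5 / 60))


class TestPipeline:
    MINI = dict(n_patients=5, n_epochs_per_condition=8, fs_raw=400.0,
                duration=120.0, n_scalp_channels=12, seed=21)

    def test_rerun_is_deterministic_and_gate_applies(self):
        run = RunConfig(synth=SyntheticConfig(**self.MINI), seed=4)
        a = run_pipeline(run)
        b = run_pipeline(run)
        pd.testing.assert_frame_equal(a.band_table, b.band_table)
        pd.testing.assert_frame_equal(a.network_tests, b.network_tests)
        assert a.cluster_report == b.cluster_report
        # intracranial ROI tests restricted to regions sampled in >= 5
        gated = set(a.roi_tests.loc[a.roi_tests.level == "iEEG_ROI", "unit"])
        counts = a.roi_patient_counts
        assert gated <= set(counts[counts >= run.min_patients_per_roi].index)
        assert a.run_log["n_patients"] == 5

    def test_default_cohort_gate_is_twelve_core_regions(self):
        cfg = SyntheticConfig()
        sampled = [cfg.sampled_rois(i) for i in range(cfg.n_patients)]
        counts = pd.Series([r for s in sampled for r in s]).value_counts()
        gate = set(counts[counts >= 5].index)
        assert gate == set(cfg.source_roi_labels[:12])
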