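"""Synthetic cohort generator: determinism, scalp-negativity, truth."""

import numpy as np
import pytest
from scipy import signal as spsignal

from iednet.events import EventList
from iednet.io import read_recording
from iednet.synth import (CouplingSpec, IEDWaveform, SyntheticConfig,
                          default_config, generate_patient, ground_truth,
                          ied_template, null_config, patient_bundle,
                          small_config, write_cohort)

import pandas as pd


def marker_samples(p, cfg, condition="IED"):
    t = p.events.times(condition).to_numpy()
    return np.round(t * cfg.fs_raw).astype(int)


def quiet_mask(p, cfg, pad_s=3.0):
    mask = np.ones(p.ieeg.n_samples, dtype=bool)
    pad = int(pad_s * cfg.fs_raw)
    for i in marker_samples(p, cfg):
        mask[max(0, i - pad):i + pad] = False
    return mask


def hip_deep_channel(p):
    tab = p.ieeg.channels
    row = tab[(tab["roi"].astype(str).str.startswith("hippocampus"))
              & (tab["contact"] == 1)].index[0]
    return int(row)


class TestEvents:
    def test_counts_sorted_and_in_bounds(self, small_cfg, patient0):
        counts = patient0.events.counts()
        assert counts["IED"] == counts["no_IED"] == \
            small_cfg.n_epochs_per_condition
        onsets = patient0.events.markers["onset_s"].to_numpy()
        assert np.all(np.diff(onsets) >= 5.5)        # minimum epoch spacing
        assert onsets[0] >= 0 and onsets[-1] <= small_cfg.duration

    def test_duration_too_short_rejected(self):
        cfg = small_config(duration=50.0)
        with pytest.raises(ValueError, match="too short"):
            patient_bundle(cfg, 0)

    def test_unsorted_markers_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            EventList(pd.DataFrame({"onset_s": [2.0, 1.0],
                                    "condition": ["IED", "IED"]}))


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_cfg, patient0):
        again = patient_bundle(small_cfg, 0)
        assert np.array_equal(patient0.ieeg.data, again.ieeg.data)
        assert np.array_equal(patient0.scalp.data, again.scalp.data)
        pd.testing.assert_frame_equal(patient0.events.markers,
                                      again.events.markers)

    def test_patients_differ(self, small_cfg, patient0):
        other = patient_bundle(small_cfg, 1)
        assert not np.array_equal(patient0.ieeg.data[0, :1000],
                                  other.ieeg.data[0, :1000])

    def test_generate_patient_tuple_matches_bundle(self, small_cfg, patient0):
        ieeg, scalp, events = generate_patient(small_cfg, 0)
        assert np.array_equal(ieeg.data, patient0.ieeg.data)
        assert np.array_equal(scalp.data, patient0.scalp.data)
        pd.testing.assert_frame_equal(events.markers,
                                      patient0.events.markers)


class TestScalpNegativity:
    def test_averaged_template_below_scalp_noise_floor(self, small_cfg,
                                                       patient0):
        idx = marker_samples(patient0, small_cfg)
        template = np.stack([patient0.scalp.data[:, i] for i in idx]).mean(0)
        sd = patient0.scalp.data.std(axis=1)
        assert np.all(np.abs(template) < sd)

    def test_intracranial_deflection_dominates_local_noise(self, small_cfg,
                                                           patient0):
        ch = hip_deep_channel(patient0)
        x = patient0.ieeg.data[ch]
        idx = marker_samples(patient0, small_cfg)
        local_sd = x[quiet_mask(patient0, small_cfg)].std()
        assert x[idx].mean() > 5 * local_sd

    def test_transient_absent_in_quiet_condition(self, small_cfg, patient0):
        ch = hip_deep_channel(patient0)
        x = patient0.ieeg.data[ch]
        idx = marker_samples(patient0, small_cfg, "no_IED")
        local_sd = x[quiet_mask(patient0, small_cfg)].std()
        assert abs(np.stack([x[i] for i in idx]).mean()) < local_sd

    def test_null_cohort_has_no_transient(self):
        cfg = null_config(n_epochs_per_condition=20, fs_raw=400.0,
                          duration=300.0, n_scalp_channels=16, seed=3)
        p = patient_bundle(cfg, 0)
        ch = hip_deep_channel(p)
        idx = marker_samples(p, cfg)
        assert abs(p.ieeg.data[ch, idx].mean()) < 1.0


class TestSpectralStructure:
    def test_background_slope_matches_noise_exponent(self, background_cfg):
        p = patient_bundle(background_cfg, 0)
        f, P = spsignal.welch(p.ieeg.data[0], fs=background_cfg.fs_raw,
                              nperseg=8192)
        sel = (f >= 2) & (f <= 30)
        slope = np.polyfit(np.log(f[sel]), np.log(P[sel]), 1)[0]
        assert slope == pytest.approx(-background_cfg.noise_exponent,
                                      abs=0.3)

    def test_programmed_lag_recovered_from_cross_spectrum(self):
        lag, band = 0.9, "theta"
        cfg = SyntheticConfig(
            n_patients=1, n_epochs_per_condition=50, fs_raw=400.0,
            duration=620.0, n_scalp_channels=8,
            source_roi_labels=("hippocampus_ipsi", "amygdala_ipsi"),
            coupling_spec=(CouplingSpec("hippocampus_ipsi", "amygdala_ipsi",
                                        band, lag, 1.0, 1.0),),
            sync_spec=(), seed=11, local_noise_sd=0.0, reference_sd=0.0)
        p = patient_bundle(cfg, 0)
        a = p.ieeg.data[0]            # hippocampal deep contact
        b = p.ieeg.data[3]            # amygdala deep contact
        # scipy's csd(x, y) returns conj(X) * Y, so the lag of b behind a
        # appears with a negative sign; undo it
        f, Pab = spsignal.csd(a, b, fs=cfg.fs_raw, nperseg=4096)
        center = np.sqrt(4 * 8)      # theta band centre
        phase = -np.angle(Pab[np.argmin(np.abs(f - center))])
        assert abs(np.angle(np.exp(1j * (phase - lag)))) < 0.2


class TestIedTemplate:
    def test_peak_amplitude_and_position(self):
        wave = IEDWaveform()
        tpl, peak = ied_template(wave, 1000.0)
        assert tpl[peak] == pytest.approx(wave.spike_amplitude)
        assert abs(tpl).max() == pytest.approx(wave.spike_amplitude)

    def test_zero_amplitude_template_is_flat(self):
        tpl, _ = ied_template(IEDWaveform(spike_amplitude=0.0,
                                          slow_wave_amplitude=0.0), 500.0)
        assert np.allclose(tpl, 0.0)


class TestGroundTruth:
    def test_pairwise_rows_and_sync_expansion(self):
        cfg = default_config()
        truth = ground_truth(cfg)
        pw = truth[truth.mechanism == "pairwise"]
        assert len(pw) == len(cfg.coupling_spec)
        gs = truth[truth.mechanism == "global_sync"]
        n = len(cfg.source_roi_labels)
        assert len(gs) == len(cfg.sync_spec) * n * (n - 1) // 2

    def test_null_cohort_gains_equal(self):
        truth = ground_truth(null_config())
        assert (truth["gain_no_ied"] == truth["gain_ied"]).all()

    def test_zero_lag_pairs_flagged_invisible(self):
        cfg = default_config(coupling_spec=(
            CouplingSpec("hippocampus_ipsi", "amygdala_ipsi", "theta",
                         np.pi, 0.3, 0.6),), sync_spec=())
        truth = ground_truth(cfg)
        assert "wPLI-invisible" in truth["note"].iloc[0]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec("a", "b", "theta", 4.0, 0.1, 0.2)   # lag out of range
        with pytest.raises(ValueError):
            CouplingSpec("a", "b", "gamma", 0.5, 0.1, 0.2)   # unknown band
        with pytest.raises(ValueError):
            default_config(scalp_negative_margin=1.2)


class TestCohortExport:
    def test_roundtrip_through_edf_and_tsv(self, tmp_path):
        cfg = SyntheticConfig(
            n_patients=1, n_epochs_per_condition=3, fs_raw=400.0,
            duration=45.0, n_scalp_channels=4,
            source_roi_labels=("hippocampus_ipsi", "amygdala_ipsi"),
            coupling_spec=(), sync_spec=(), seed=2)
        out = write_cohort(cfg, tmp_path)
        pdir = out / "patient00"
        assert (out / "ground_truth.tsv").exists()
        assert (out / "config.json").exists()
        back = read_recording(pdir / "ieeg.edf")
        orig = patient_bundle(cfg, 0).ieeg
        assert back.labels == orig.labels
        step = (orig.data.max(axis=1) - orig.data.min(axis=1)) / 65535
        assert np.all(np.abs(back.data[:, :orig.n_samples] - orig.data)
                      <= step[:, None] + 1e-9)
        ev = EventList.read(pdir / "events.tsv", duration=cfg.duration)
        assert ev.counts()["IED"] == 3
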