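"""Weighted phase lag index: limits, null behaviour, ROI aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as spsignal
from scipy.stats import spearmanr

from iednet.connectivity import (aggregate_pairs_to_roi, trial_cross_spectra,
                                 wpli, ConnectivityMatrix)
from iednet.epochs import EpochSet
from iednet.io import ChannelMap
from iednet.windows import BANDS, build_window

FS = 200.0
ALPHA = BANDS[2]


def epochs(trials, labels=None):
    win = build_window(ALPHA, FS)
    trials = np.asarray(trials, dtype=float) * win.taper
    labels = labels or [f"c{i}" for i in range(trials.shape[1])]
    return EpochSet("IED", trials, FS, labels, win.peak_index,
                    np.zeros(trials.shape[0]), win)


def lagged_pair_trials(n_trials, lag, rng, f0=10.0, noise=0.0):
    win = build_window(ALPHA, FS)
    t = np.arange(win.n_samples) / FS
    out = []
    for _ in range(n_trials):
        ph = rng.uniform(0, 2 * np.pi)
        a = np.sin(2 * np.pi * f0 * t + ph)
        b = np.sin(2 * np.pi * f0 * t + ph - lag)
        pair = np.stack([a, b])
        if noise:
            pair = pair + noise * rng.standard_normal(pair.shape)
        out.append(pair)
    return np.array(out)


class TestCrossSpectra:
    def test_self_cross_spectrum_is_real(self, rng):
        ep = epochs(rng.standard_normal((5, 1, 77 * 0 + build_window(
            ALPHA, FS).n_samples)))
        S = trial_cross_spectra(ep, ALPHA)
        assert np.abs(np.imag(S[:, :, 0, 0])).max() == 0.0

    def test_phase_shift_recovered(self, rng):
        lag = 0.8
        ep = epochs(lagged_pair_trials(10, lag, rng))
        S = trial_cross_spectra(ep, ALPHA)
        n = ep.data.shape[2]
        freqs = np.fft.rfftfreq(n, 1 / FS)
        sel = (freqs >= ALPHA.f_low) & (freqs < ALPHA.f_high)
        f0_bin = np.argmin(np.abs(freqs[sel] - 10.0))
        phases = np.angle(S[:, f0_bin, 0, 1])
        err = np.abs(np.angle(np.exp(1j * (phases - lag))))
        assert err.max() < 0.01

    def test_conjugate_symmetry(self, rng):
        ep = epochs(rng.standard_normal(
            (4, 3, build_window(ALPHA, FS).n_samples)))
        S = trial_cross_spectra(ep, ALPHA)
        assert np.allclose(S, np.conj(np.swapaxes(S, 2, 3)))

    def test_single_trial_rejected(self, rng):
        ep = epochs(rng.standard_normal(
            (1, 2, build_window(ALPHA, FS).n_samples)))
        with pytest.raises(ValueError):
            trial_cross_spectra(ep, ALPHA)


class TestWpli:
    def test_zero_lag_scaling_gives_zero(self, rng):
        win = build_window(ALPHA, FS)
        x = rng.standard_normal((30, win.n_samples))
        trials = np.stack([x, 3.0 * x], axis=1)
        W = wpli(trial_cross_spectra(epochs(trials), ALPHA)).W
        assert W[0, 1] == 0.0

    def test_quarter_cycle_lag_saturates_to_one(self, rng):
        ep = epochs(lagged_pair_trials(20, np.pi / 2, rng))
        W = wpli(trial_cross_spectra(ep, ALPHA)).W
        assert W[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_stays_below_null_bound(self, rng):
        win = build_window(ALPHA, FS)
        trials = rng.standard_normal((200, 2, win.n_samples))
        W = wpli(trial_cross_spectra(epochs(trials), ALPHA)).W
        assert W[0, 1] < 0.15

    def test_common_zero_lag_mixing_is_leakage_robust(self, rng):
        win = build_window(ALPHA, FS)
        common = rng.standard_normal((200, win.n_samples))
        a = rng.standard_normal((200, win.n_samples)) + common
        b = rng.standard_normal((200, win.n_samples)) + 0.8 * common
        W = wpli(trial_cross_spectra(epochs(np.stack([a, b], axis=1)),
                                     ALPHA)).W
        assert W[0, 1] < 0.15

    def test_monotone_in_coupling_gain(self, rng):
        # shared band-limited oscillation with fixed 0.9 rad lag, rising
        # gain against unit background noise
        win = build_window(ALPHA, FS)
        sos = spsignal.butter(4, [ALPHA.f_low, ALPHA.f_high],
                              btype="bandpass", fs=FS, output="sos")
        gains = [0.1, 0.25, 0.5, 1.0, 2.0]
        values = []
        for g in gains:
            trials = []
            for _ in range(100):
                s = spsignal.sosfiltfilt(sos,
                                         rng.standard_normal(win.n_samples))
                s /= s.std()
                rot = np.real(spsignal.hilbert(s) * np.exp(-1j * 0.9))
                a = rng.standard_normal(win.n_samples) + g * s
                b = rng.standard_normal(win.n_samples) + g * rot
                trials.append(np.stack([a, b]))
            W = wpli(trial_cross_spectra(epochs(np.array(trials)), ALPHA)).W
            values.append(W[0, 1])
        rho, _ = spearmanr(gains, values)
        assert rho > 0.9

    def test_output_symmetric_and_bounded(self, rng):
        win = build_window(ALPHA, FS)
        trials = rng.standard_normal((20, 5, win.n_samples))
        cm = wpli(trial_cross_spectra(epochs(trials), ALPHA))
        W = cm.W
        assert np.allclose(W, W.T, equal_nan=True)
        off = W[~np.eye(5, dtype=bool)]
        assert off.min() >= 0 and off.max() <= 1
        assert np.isnan(np.diagonal(W)).all()


class TestRoiAggregation:
    @staticmethod
    def cm(labels, W):
        return ConnectivityMatrix(labels, "alpha", "IED", np.asarray(W))

    @staticmethod
    def cmap(mapping):
        return ChannelMap(pd.DataFrame({"label": list(mapping),
                                        "roi": list(mapping.values())}))

    def test_mean_over_cross_roi_channel_pairs(self):
        W = np.array([[np.nan, 0.9, 0.2], [0.9, np.nan, 0.4],
                      [0.2, 0.4, np.nan]])
        out = aggregate_pairs_to_roi(
            self.cm(["a1", "a2", "b1"], W),
            self.cmap({"a1": "A", "a2": "A", "b1": "B"}))
        i, j = out.labels.index("A"), out.labels.index("B")
        assert out.W[i, j] == pytest.approx(0.3)   # mean of 0.2, 0.4

    def test_uncovered_roi_pair_missing(self):
        W = np.full((3, 3), np.nan)
        W[0, 1] = W[1, 0] = 0.5
        out = aggregate_pairs_to_roi(
            self.cm(["a", "b", "c"], W),
            self.cmap({"a": "A", "b": "B", "c": "C"}))
        i, j = out.labels.index("A"), out.labels.index("C")
        assert np.isnan(out.W[i, j])

    def test_single_channel_per_roi_restricts_matrix(self, rng):
        raw = rng.uniform(0.1, 0.9, (3, 3))
        W = (raw + raw.T) / 2
        np.fill_diagonal(W, np.nan)
        out = aggregate_pairs_to_roi(
            self.cm(["x", "y", "z"], W),
            self.cmap({"x": "X", "y": "Y", "z": "Z"}))
        order = [["x", "y", "z"][i] for i in np.argsort(["X", "Y", "Z"])]
        assert np.allclose(out.W[~np.isnan(out.W)], W[~np.isnan(W)])

    def test_fewer_than_two_rois_rejected(self):
        W = np.array([[np.nan, 0.5], [0.5, np.nan]])
        with pytest.raises(ValueError):
            aggregate_pairs_to_roi(self.cm(["a", "b"], W),
                                   self.cmap({"a": "A", "b": "A"}))
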