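"""Generalized Morse wavelet time-frequency analysis: ERSP, ITC, COI.

The transform uses the generalized Morse wavelet with symmetry
``gamma = 3`` and time-bandwidth product ``P^2 = 40`` (``beta =
P^2/gamma``), evaluated in the frequency domain on a log-spaced axis
with 10 voices per octave between 1 and 40 Hz.  Wavelets are one-sided
in frequency (analytic) and normalized to unit energy per scale.

Two trial-averaged maps are derived: the event-related spectral
perturbation (ERSP), ``10*log10(mean_k |W_k|^2 / baseline)`` in dB,
which captures both phase-locked and induced power changes, and the
inter-trial coherence (ITC), ``|mean_k exp(i arg W_k)|`` in [0, 1],
which captures only the phase-locked part.  The cone of influence (COI)
is the e-folding time of each wavelet's temporal envelope; map pixels
closer than that to an epoch edge are flagged, not removed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .epochs import EpochSet

__all__ = ["TFMap", "MorseWavelet", "morse_frequencies", "morse_transform",
           "ersp", "itc", "baseline_power"]

GAMMA = 3.0
TIME_BANDWIDTH = 40.0  # P^2; beta = P^2 / gamma
F_MIN = 1.0
F_MAX = 40.0
VOICES_PER_OCTAVE = 10


def morse_frequencies(f_min: float = F_MIN, f_max: float = F_MAX,
                      voices: int = VOICES_PER_OCTAVE) -> np.ndarray:
    """Log-spaced analysis frequencies, ``voices`` per octave."""
    n_oct = np.log2(f_max / f_min)
    k = np.arange(int(np.floor(n_oct * voices)) + 1)
    return f_min * 2.0 ** (k / voices)


@dataclasses.dataclass
class TFMap:
    """Time-frequency map with cone-of-influence annotation.

    ``values`` is (n_freqs, n_times); ``times`` are seconds relative to
    the marker; ``coi_halfwidth`` gives, per frequency, the temporal
    half-width (s) inside which an epoch edge contaminates the estimate.
    """

    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray
    coi_halfwidth: np.ndarray
    kind: str  # "ersp" (dB) or "itc" (unitless)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.freqs), len(self.times)):
            raise ValueError("values shape mismatch")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def valid_mask(self) -> np.ndarray:
        """Boolean (n_freqs, n_times): True where edges do not intrude."""
        from_left = self.times - self.times[0]
        from_right = self.times[-1] - self.times
        edge = np.minimum(from_left, from_right)
        return edge[None, :] >= self.coi_halfwidth[:, None]

    def decimate_time(self, q: int) -> "TFMap":
        return TFMap(self.freqs, self.times[::q], self.values[:, ::q],
                     self.coi_halfwidth, self.kind)


class MorseWavelet:
    """Frequency-domain Morse filter bank for a fixed trial length."""

    def __init__(self, n_samples: int, fs: float,
                 freqs: np.ndarray | None = None,
                 gamma: float = GAMMA,
                 time_bandwidth: float = TIME_BANDWIDTH):
        self.fs = float(fs)
        self.n = int(n_samples)
        self.freqs = morse_frequencies() if freqs is None else np.asarray(freqs)
        beta = time_bandwidth / gamma
        omega_peak = (beta / gamma) ** (1.0 / gamma)
        omega = 2 * np.pi * np.fft.fftfreq(self.n, d=1.0 / self.fs)
        bank = np.zeros((len(self.freqs), self.n))
        pos = omega > 0
        for i, f in enumerate(self.freqs):
            w = omega[pos] * omega_peak / (2 * np.pi * f)
            h = np.exp(beta * np.log(w) - w ** gamma)
            bank[i, pos] = h
        # unit energy per scale: sum |h(t)|^2 dt = 1
        energy = (bank ** 2).sum(axis=1) / (self.n * self.fs)
        bank /= np.sqrt(energy)[:, None]
        self.bank = bank
        self.coi_halfwidth = self._coi()

    def _coi(self) -> np.ndarray:
        """E-folding time (s) of each wavelet's temporal envelope."""
        out = np.empty(len(self.freqs))
        for i in range(len(self.freqs)):
            h = np.fft.ifft(self.bank[i])
            env = np.abs(h)
            thresh = env[0] / np.e
            # envelope decays away from t=0 (wrapped); first crossing
            below = np.nonzero(env[: self.n // 2] < thresh)[0]
            out[i] = (below[0] if below.size else self.n // 2) / self.fs
        return out

    def transform(self, trials: np.ndarray) -> np.ndarray:
        """Wavelet coefficients, shape (n_trials, n_freqs, n_samples)."""
        trials = np.atleast_2d(np.asarray(trials, dtype=float))
        if trials.shape[1] != self.n:
            raise ValueError("trial length does not match the filter bank")
        X = np.fft.fft(trials, axis=1)
        return np.fft.ifft(X[:, None, :] * self.bank[None, :, :], axis=2)


def _single_channel(epochs: EpochSet) -> np.ndarray:
    if epochs.data.shape[1] != 1:
        raise ValueError("time-frequency maps are per channel; "
                         "pick one channel first (EpochSet.channel)")
    return epochs.data[:, 0, :]


def morse_transform(epochs: EpochSet,
                    freqs: np.ndarray | None = None
                    ) -> tuple[np.ndarray, MorseWavelet]:
    """Coefficients for a single-channel epoch set, plus the bank used."""
    trials = _single_channel(epochs)
    if trials.shape[1] < epochs.fs / F_MIN:
        raise ValueError("trial shorter than one cycle of the lowest frequency")
    bank = MorseWavelet(trials.shape[1], epochs.fs, freqs)
    return bank.transform(trials), bank


def baseline_power(epochs: EpochSet,
                   freqs: np.ndarray | None = None) -> np.ndarray:
    """Per-frequency mean power over all trials and times (ERSP baseline)."""
    W, _ = morse_transform(epochs, freqs)
    return (np.abs(W) ** 2).mean(axis=(0, 2))


def ersp(epochs: EpochSet, baseline: np.ndarray,
         freqs: np.ndarray | None = None) -> TFMap:
    """Event-related spectral perturbation in dB relative to ``baseline``."""
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline power must be strictly positive")
    W, bank = morse_transform(epochs, freqs)
    power = (np.abs(W) ** 2).mean(axis=0)
    values = 10.0 * np.log10(power / baseline[:, None])
    return TFMap(bank.freqs, epochs.times, values, bank.coi_halfwidth, "ersp")


def itc(epochs: EpochSet, freqs: np.ndarray | None = None) -> TFMap:
    """Inter-trial phase coherence, amplitude-invariant, in [0, 1]."""
    if epochs.n_trials < 2:
        raise ValueError("ITC needs at least two trials")
    W, bank = morse_transform(epochs, freqs)
    phases = W / np.maximum(np.abs(W), 1e-300)
    values = np.abs(phases.mean(axis=0))
    return TFMap(bank.freqs, epochs.times, values, bank.coi_halfwidth, "itc")
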