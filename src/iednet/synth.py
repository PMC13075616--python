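"""Synthetic simultaneous scalp + intracranial cohorts with known truth.

Each synthetic "patient" is a set of source time series (1/f-like
background noise per region), pairwise band-limited couplings with a
programmed constant phase lag (implemented by adding a shared
band-passed oscillation to both sources, one copy rotated in phase via
its analytic signal, so the lag is analytically known), and a
spike-and-slow-wave transient injected into a designated medial
temporal source at marked times.  Intracranial channels sample sources
directly through two-contact depth shafts; scalp channels see a
depth-attenuated linear mixture plus sensor noise, with the transient's
mixing row rescaled so its scalp footprint stays below the background
noise floor (scalp-negative).  Coupling gains switch between a no-IED
and an IED level inside windows around the marked discharges, giving the
downstream pipeline a recoverable condition effect.  All randomness
derives from one root seed expanded per patient, so cohorts are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as spsignal

from .atlas import to_ipsi_contra
from .events import EventList
from .io import ChannelMap, Recording, write_channel_map, write_recording
from .windows import BANDS, BandSpec

__all__ = ["IEDWaveform", "CouplingSpec", "SyncSpec", "SyntheticConfig",
           "PatientData",
           "default_config", "null_config", "small_config",
           "generate_patient", "patient_bundle", "ground_truth",
           "write_cohort"]

_BAND_BY_NAME = {b.name: b for b in BANDS}

# Default 16-region source space (ipsi/contra labels).  The first twelve
# are implanted in every synthetic patient and match the regions a
# bilateral temporal + frontal depth implantation typically samples; the
# last four are sampled by only a subset of patients.
DEFAULT_SOURCES = (
    "hippocampus_ipsi", "hippocampus_contra",
    "amygdala_ipsi", "fusiform_ipsi",
    "inferiortemporal_ipsi", "inferiortemporal_contra",
    "middletemporal_ipsi", "middletemporal_contra",
    "lateralorbitofrontal_ipsi", "lateralorbitofrontal_contra",
    "rostralmiddlefrontal_ipsi", "rostralmiddlefrontal_contra",
    "amygdala_contra", "fusiform_contra",
    "insula_ipsi", "superiorfrontal_ipsi",
)
N_CORE_SAMPLED = 12

# Two explicit hippocampus-centred pairwise couplings (known lags, used
# for programmed-lag and synchrony-recovery checks); phase lags avoid 0
# and pi so the coupling is visible to a lag-based synchrony measure.
DEFAULT_COUPLING = (
    ("hippocampus_ipsi", "amygdala_ipsi", "theta", 1.1, 0.4, 1.0),
    ("hippocampus_ipsi", "fusiform_ipsi", "alpha", 0.8, 0.4, 1.0),
)

# Per band, one network-wide oscillatory drive reaching every source
# with a source-specific phase offset, so all source pairs are
# lag-coupled.  Its gain rises inside discharge windows: this is the
# large-scale, frequency-dependent synchronization increase that raises
# both network integration and segregation, rather than a single
# dominant edge (which a max-normalized clustering coefficient would
# penalize).
DEFAULT_SYNC = (
    ("delta", 0.18, 0.25, 0.9),
    ("theta", 0.18, 0.25, 0.9),
    ("alpha", 0.18, 0.25, 0.9),
    ("beta", 0.18, 0.25, 0.9),
)

_DEEP_ROIS = ("hippocampus", "amygdala")


@dataclasses.dataclass(frozen=True)
class IEDWaveform:
    """Spike (difference of Gaussians) followed by a half-cosine slow wave."""
    spike_width_ms: float = 70.0
    spike_amplitude: float = 8.0
    slow_wave_width_ms: float = 300.0
    slow_wave_amplitude: float = 2.5


@dataclasses.dataclass(frozen=True)
class CouplingSpec:
    source_a: str
    source_b: str
    band: str
    phase_lag_rad: float
    gain_no_ied: float
    gain_ied: float

    def __post_init__(self) -> None:
        if self.band not in _BAND_BY_NAME:
            raise ValueError(f"unknown band {self.band!r}")
        if not (-np.pi < self.phase_lag_rad <= np.pi):
            raise ValueError("phase lag must lie in (-pi, pi]")
        if self.gain_no_ied < 0 or self.gain_ied < 0:
            raise ValueError("coupling gains must be >= 0")


@dataclasses.dataclass(frozen=True)
class SyncSpec:
    """Network-wide band-limited drive with per-source phase offsets.

    Source ``m`` (in config order) receives the shared oscillation
    rotated by ``phase_step_rad * m``; the pairwise lag between sources
    m and m' is therefore ``phase_step_rad * (m - m')``.  ``members``
    restricts the drive to a subset of sources (None = all).
    """
    band: str
    phase_step_rad: float = 0.18
    gain_no_ied: float = 0.25
    gain_ied: float = 0.9
    members: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.band not in _BAND_BY_NAME:
            raise ValueError(f"unknown band {self.band!r}")
        if self.gain_no_ied < 0 or self.gain_ied < 0:
            raise ValueError("sync gains must be >= 0")


@dataclasses.dataclass
class SyntheticConfig:
    """Cohort-level generation parameters (see module docstring)."""

    n_patients: int = 9
    n_epochs_per_condition: int = 40
    fs_raw: float = 1000.0
    duration: float = 560.0
    source_roi_labels: tuple[str, ...] = DEFAULT_SOURCES
    ied_source_label: str = "hippocampus_ipsi"
    ied_waveform: IEDWaveform = dataclasses.field(default_factory=IEDWaveform)
    coupling_spec: tuple[CouplingSpec, ...] = tuple(
        CouplingSpec(*row) for row in DEFAULT_COUPLING)
    sync_spec: tuple[SyncSpec, ...] = tuple(
        SyncSpec(*row) for row in DEFAULT_SYNC)
    scalp_mixing: np.ndarray | None = None   # (n_sources, n_scalp) or None
    n_scalp_channels: int = 32
    scalp_negative_margin: float = 0.5
    noise_exponent: float = 1.0
    seed: int = 0
    # secondary amplitudes (source background has unit SD)
    sensor_noise_sd: float = 1.0
    local_noise_sd: float = 0.3
    reference_sd: float = 0.5
    wm_gain: float = 0.25
    mixing_scale: float = 0.35
    depth_attenuation: float = 0.15
    n_core_sampled: int = N_CORE_SAMPLED

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.scalp_negative_margin < 1:
            raise ValueError("scalp_negative_margin must lie in [0, 1)")
        if self.ied_source_label not in self.source_roi_labels:
            raise ValueError("ied_source_label must be one of source_roi_labels")
        names = set(self.source_roi_labels)
        for c in self.coupling_spec:
            if c.source_a not in names or c.source_b not in names:
                raise ValueError(f"coupling references unknown source: {c}")
        for s in self.sync_spec:
            if s.members is not None and not set(s.members) <= names:
                raise ValueError(f"sync drive references unknown source: {s}")

    @property
    def n_sources(self) -> int:
        return len(self.source_roi_labels)

    def sampled_rois(self, patient_index: int) -> list[str]:
        """ROIs implanted in this patient: a fixed core plus extras.

        Extras rotate so that each is sampled by fewer than five of nine
        patients, leaving exactly the core regions eligible for
        group-level intracranial ROI tests.
        """
        core = list(self.source_roi_labels[:self.n_core_sampled])
        extras = [roi for k, roi in
                  enumerate(self.source_roi_labels[self.n_core_sampled:])
                  if (patient_index + k) % 3 == 0]
        return core + extras


def default_config(**overrides) -> SyntheticConfig:
    return SyntheticConfig(**overrides)


def null_config(**overrides) -> SyntheticConfig:
    """Effect switched off: zero transient, equal coupling gains."""
    cfg = SyntheticConfig(**overrides)
    wave = dataclasses.replace(cfg.ied_waveform, spike_amplitude=0.0,
                               slow_wave_amplitude=0.0)
    coupling = tuple(dataclasses.replace(c, gain_ied=c.gain_no_ied)
                     for c in cfg.coupling_spec)
    sync = tuple(dataclasses.replace(s, gain_ied=s.gain_no_ied)
                 for s in cfg.sync_spec)
    return dataclasses.replace(cfg, ied_waveform=wave, coupling_spec=coupling,
                               sync_spec=sync)


def small_config(**overrides) -> SyntheticConfig:
    """Reduced problem size for Monte-Carlo calibration runs."""
    defaults = dict(n_epochs_per_condition=20, fs_raw=400.0, duration=300.0,
                    n_scalp_channels=16)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@dataclasses.dataclass
class PatientData:
    """One synthetic patient: recordings, events, and generation truth."""
    ieeg: Recording
    scalp: Recording
    events: EventList
    channel_map: ChannelMap
    mixing: np.ndarray          # effective (possibly rescaled) mixing used
    ied_side: str
    sampled_rois: list[str]     # ipsi/contra space


def patient_side(patient_index: int) -> str:
    return "right" if patient_index % 2 == 0 else "left"


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _colored_noise(rng: np.random.Generator, n_rows: int, n: int, fs: float,
                   exponent: float) -> np.ndarray:
    """Rows of unit-SD noise with power spectrum ~ 1/f**exponent."""
    white = rng.standard_normal((n_rows, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n, axis=1)
    return x / x.std(axis=1, keepdims=True)


def _band_limited(rng: np.random.Generator, n: int, fs: float,
                  band: BandSpec) -> np.ndarray:
    sos = spsignal.butter(4, [band.f_low, band.f_high], btype="bandpass",
                          fs=fs, output="sos")
    x = spsignal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _phase_rotate(x: np.ndarray, lag: float) -> np.ndarray:
    """Rotate every spectral component of ``x`` by ``-lag`` radians.

    The cross-spectral phase arg(X conj(X_rot)) then equals +lag."""
    return np.real(spsignal.hilbert(x) * np.exp(-1j * lag))


def ied_template(wave: IEDWaveform, fs: float) -> tuple[np.ndarray, int]:
    """Sampled transient and the index of its (spike) peak."""
    sig1 = wave.spike_width_ms / 1000.0 / 6.0
    sig2 = 2.0 * sig1
    t = np.arange(-0.15, 0.45, 1.0 / fs)
    spike = np.exp(-t ** 2 / (2 * sig1 ** 2)) - 0.55 * np.exp(-t ** 2 / (2 * sig2 ** 2))
    if spike.max() > 0:
        spike = spike / spike.max() * wave.spike_amplitude
    slow_t0 = 0.04
    slow_w = wave.slow_wave_width_ms / 1000.0
    in_slow = (t >= slow_t0) & (t <= slow_t0 + slow_w)
    slow = np.zeros_like(t)
    slow[in_slow] = wave.slow_wave_amplitude * np.sin(
        np.pi * (t[in_slow] - slow_t0) / slow_w)
    template = spike + slow
    return template, int(np.argmin(np.abs(t)))


def _place_events(rng: np.random.Generator, cfg: SyntheticConfig) -> pd.DataFrame:
    """Jittered-grid epoch centers with minimum spacing >= 5.5 s."""
    n_slots = 2 * cfg.n_epochs_per_condition
    edge = 3.2          # accommodates the longest pre/post epoch extent
    step, jitter = 6.0, 0.5
    needed = 2 * edge + (n_slots - 1) * step + jitter
    if cfg.duration < needed:
        raise ValueError(
            f"duration {cfg.duration} s too short for {n_slots} epochs "
            f"(needs >= {needed:.1f} s)")
    onsets = edge + step * np.arange(n_slots) + rng.uniform(0, jitter, n_slots)
    conditions = np.array(["IED"] * cfg.n_epochs_per_condition
                          + ["no_IED"] * cfg.n_epochs_per_condition)
    rng.shuffle(conditions)
    return pd.DataFrame({"onset_s": onsets, "condition": conditions})


def _gain_envelope(n: int, fs: float, ied_times: np.ndarray,
                   half_width: float = 2.5, ramp: float = 0.25) -> np.ndarray:
    """0..1 envelope: raised-cosine plateaus around each IED marker."""
    env = np.zeros(n)
    t = np.arange(n) / fs
    for m in ied_times:
        lo, hi = m - half_width, m + half_width
        sel = (t >= lo - ramp) & (t <= hi + ramp)
        tt = t[sel]
        up = np.clip((tt - (lo - ramp)) / ramp, 0, 1)
        down = np.clip(((hi + ramp) - tt) / ramp, 0, 1)
        env[sel] = np.maximum(env[sel], 0.5 * (1 - np.cos(np.pi * up))
                              * 0.5 * (1 - np.cos(np.pi * down)))
    return np.clip(env, 0, 1)


def _default_mixing(cfg: SyntheticConfig) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(10 ** 6,)))
    M = cfg.mixing_scale * rng.standard_normal(
        (cfg.n_sources, cfg.n_scalp_channels))
    for i, roi in enumerate(cfg.source_roi_labels):
        if any(roi.startswith(d) for d in _DEEP_ROIS):
            M[i] *= cfg.depth_attenuation
    return M


def _shaft_code(roi_lr: str) -> str:
    base, _, hemi = roi_lr.rpartition("_")
    return base[:3].upper() + hemi[0]


# ---------------------------------------------------------------------------
# patient generation
# ---------------------------------------------------------------------------

def patient_bundle(cfg: SyntheticConfig, patient_index: int) -> PatientData:
    """Generate one patient (full truth bundle); deterministic in (seed, index)."""
    if patient_index >= cfg.n_patients:
        raise ValueError("patient_index out of range")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(patient_index,)))
    fs = cfg.fs_raw
    n = int(round(cfg.duration * fs))
    side = patient_side(patient_index)
    src_labels = list(cfg.source_roi_labels)

    markers = _place_events(rng, cfg)
    ied_times = markers.loc[markers["condition"] == "IED", "onset_s"].to_numpy()

    # background + pairwise couplings + network-wide sync drives
    sources = _colored_noise(rng, cfg.n_sources, n, fs, cfg.noise_exponent)
    env = _gain_envelope(n, fs, ied_times)
    for c in cfg.coupling_spec:
        shared = _band_limited(rng, n, fs, _BAND_BY_NAME[c.band])
        gain = c.gain_no_ied + (c.gain_ied - c.gain_no_ied) * env
        ia = src_labels.index(c.source_a)
        ib = src_labels.index(c.source_b)
        sources[ia] += gain * shared
        sources[ib] += gain * _phase_rotate(shared, c.phase_lag_rad)
    for s in cfg.sync_spec:
        shared = _band_limited(rng, n, fs, _BAND_BY_NAME[s.band])
        analytic = spsignal.hilbert(shared)
        gain = s.gain_no_ied + (s.gain_ied - s.gain_no_ied) * env
        members = s.members if s.members is not None else cfg.source_roi_labels
        for m, roi in enumerate(members):
            rotated = np.real(analytic * np.exp(-1j * s.phase_step_rad * m))
            sources[src_labels.index(roi)] += gain * rotated

    # transient train in the IED source
    template, peak = ied_template(cfg.ied_waveform, fs)
    train = np.zeros(n)
    for m in ied_times:
        start = int(round(m * fs)) - peak
        stop = start + template.size
        if 0 <= start and stop <= n:
            train[start:stop] += template
    ied_row = src_labels.index(cfg.ied_source_label)
    background = sources.copy()
    sources[ied_row] += train

    # ----- intracranial recording: two-contact shafts per sampled ROI -----
    sampled = cfg.sampled_rois(patient_index)
    reference = cfg.reference_sd * rng.standard_normal(n)
    contact_gains = (1.0, 0.45, cfg.wm_gain)   # deep gray, gray, white matter
    rows, data = [], []
    for roi in sampled:
        roi_lr = to_ipsi_contra(roi, side)
        code = _shaft_code(roi_lr)
        src = sources[src_labels.index(roi)]
        for c, gain in enumerate(contact_gains, start=1):
            gray = c < 3
            data.append(gain * src
                        + cfg.local_noise_sd * rng.standard_normal(n)
                        + reference)
            rows.append({"label": f"{code}{c}", "modality": "intracranial",
                         "shaft": code, "contact": c, "gray_matter": gray,
                         "roi": roi_lr if gray else ""})
    ieeg = Recording(np.asarray(data), fs, pd.DataFrame(rows))

    # ----- scalp recording: depth-attenuated mixing, scalp-negative -----
    M = (cfg.scalp_mixing.copy() if cfg.scalp_mixing is not None
         else _default_mixing(cfg))
    if M.shape[0] != cfg.n_sources:
        raise ValueError("scalp_mixing row count must equal n_sources")
    amp = np.abs(template).max() if template.size else 0.0
    src_var = background.var(axis=1)
    for _ in range(2):  # rescale the IED source row to stay sub-noise-floor
        sd = np.sqrt((M ** 2).T @ src_var + cfg.sensor_noise_sd ** 2)
        footprint = np.abs(M[ied_row]) * amp
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.min(np.where(footprint > 0,
                                  cfg.scalp_negative_margin * sd
                                  / np.maximum(footprint, 1e-300), np.inf))
        if not np.isfinite(rho) or rho >= 1:
            break
        M[ied_row] *= rho
    scalp_data = M.T @ sources + cfg.sensor_noise_sd * rng.standard_normal(
        (M.shape[1], n))
    scalp_rows = pd.DataFrame({
        "label": [f"E{i + 1:02d}" for i in range(M.shape[1])],
        "modality": "scalp"})
    scalp = Recording(scalp_data, fs, scalp_rows)

    # ----- events -----
    markers["label"] = np.where(markers["condition"] == "IED",
                                to_ipsi_contra(cfg.ied_source_label, side), "")
    detections = _detector_events(rng, cfg, ied_times, side, sampled)
    events = EventList(markers, detections, duration=cfg.duration)

    cmap = ChannelMap(pd.DataFrame(rows))
    return PatientData(ieeg=ieeg, scalp=scalp, events=events,
                       channel_map=cmap, mixing=M, ied_side=side,
                       sampled_rois=sampled)


def _detector_events(rng: np.random.Generator, cfg: SyntheticConfig,
                     ied_times: np.ndarray, side: str,
                     sampled: list[str]) -> pd.DataFrame:
    """Automated-detector-style events concentrated in the IED source.

    The marked source fires at every marker (the per-patient maximum
    rate); the amygdala co-fires at ~40% of markers; a frontal region
    shows sporadic sub-threshold activity (~5%), below the 1/10-of-max
    irritative-zone cut.
    """
    rows = []

    def add(roi_ic: str, times: np.ndarray) -> None:
        if roi_ic not in sampled:
            return
        code = _shaft_code(to_ipsi_contra(roi_ic, side))
        for t in times:
            rows.append({"time_s": t, "channel_label": f"{code}1"})

    add(cfg.ied_source_label, ied_times + rng.uniform(-0.05, 0.05, ied_times.size))
    co = rng.random(ied_times.size) < 0.4
    add("amygdala_ipsi", ied_times[co] + rng.uniform(-0.3, 0.3, int(co.sum())))
    sp = rng.random(ied_times.size) < 0.05
    add("lateralorbitofrontal_ipsi",
        ied_times[sp] + rng.uniform(-0.5, 0.5, int(sp.sum())))
    frame = pd.DataFrame(rows, columns=["time_s", "channel_label"])
    return frame.sort_values("time_s").reset_index(drop=True)


def generate_patient(cfg: SyntheticConfig, patient_index: int
                     ) -> tuple[Recording, Recording, EventList]:
    """(intracranial, scalp, events) for one synthetic patient."""
    p = patient_bundle(cfg, patient_index)
    return p.ieeg, p.scalp, p.events


def ground_truth(cfg: SyntheticConfig) -> pd.DataFrame:
    """Programmed couplings per band and source pair, plus visibility notes.

    Pairwise couplings are listed directly; each network-wide sync drive
    is expanded into its implied source-pair rows (lag = phase-step
    difference).  Pairs whose lag has zero sine are flagged as invisible
    to a lagged-synchrony measure.
    """
    rows = []

    def add(a: str, b: str, band: str, lag: float, g0: float, g1: float,
            mechanism: str) -> None:
        invisible = np.isclose(np.sin(lag), 0.0, atol=1e-12)
        rows.append({
            "source_a": a, "source_b": b, "band": band,
            "phase_lag_rad": lag, "gain_no_ied": g0, "gain_ied": g1,
            "mechanism": mechanism,
            "note": "zero-lag: wPLI-invisible by design" if invisible else "",
        })

    for c in cfg.coupling_spec:
        add(c.source_a, c.source_b, c.band, c.phase_lag_rad,
            c.gain_no_ied, c.gain_ied, "pairwise")
    for s in cfg.sync_spec:
        members = s.members if s.members is not None else cfg.source_roi_labels
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                add(members[i], members[j], s.band,
                    s.phase_step_rad * (j - i), s.gain_no_ied, s.gain_ied,
                    "global_sync")
    truth = pd.DataFrame(rows)
    truth.attrs["ied_source"] = cfg.ied_source_label
    return truth


def write_cohort(cfg: SyntheticConfig, outdir: str | Path) -> Path:
    """Export a cohort to disk: EDF signals, TSV events/maps, JSON config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i in range(cfg.n_patients):
        p = patient_bundle(cfg, i)
        pdir = outdir / f"patient{i:02d}"
        pdir.mkdir(exist_ok=True)
        write_recording(p.ieeg, pdir / "ieeg.edf")
        write_recording(p.scalp, pdir / "scalp.edf")
        p.events.write(pdir / "events.tsv")
        write_channel_map(p.channel_map, pdir / "channels.tsv")
        np.savetxt(pdir / "mixing.tsv", p.mixing, delimiter="\t")
        (pdir / "patient.json").write_text(json.dumps(
            {"ied_side": p.ied_side, "sampled_rois": p.sampled_rois}))
    ground_truth(cfg).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["ied_waveform"] = dataclasses.asdict(cfg.ied_waveform)
    cfg_dict["coupling_spec"] = [dataclasses.asdict(c) for c in cfg.coupling_spec]
    cfg_dict["sync_spec"] = [dataclasses.asdict(s) for s in cfg.sync_spec]
    if cfg.scalp_mixing is not None:
        cfg_dict["scalp_mixing"] = np.asarray(cfg.scalp_mixing).tolist()
    (outdir / "config.json").write_text(json.dumps(cfg_dict, indent=1))
    return outdir
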