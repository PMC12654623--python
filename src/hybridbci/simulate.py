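"""Seeded two-session synthetic EEG/EOG protocol simulator.

Emulates the recording protocol of the study design: 15 subjects x
2 sessions (morning, evening) x 5 classes x 10 repetitions of 16 s
four-channel frontal EEG at 256 Hz.  LED-on trials carry a 7 Hz
steady-state visual evoked response (plus a weaker 14 Hz harmonic) and a
class-specific slow ocular deflection while the subject's eyes sweep the
moving target; the LED-off control class carries randomly timed
saccade-like steps instead.  All classes ride on 1/f ("pink") plus white
background noise and occasional blink artefacts.  The evening session
passes through a configurable distribution shift (channel mixing, gain
drift, noise inflation, baseline offset) standing in for electrode
repositioning and diurnal state changes.

Everything is a pure function of (config, subject, session, class,
repetition): identical configurations reproduce identical datasets bit
for bit.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import (
    CHANNELS,
    CLASSES,
    RANDOM_GAZE,
    SESSIONS,
    TRAJECTORY_CLASSES,
    DatasetManifest,
    ManifestEntry,
    Recording,
    save_manifest,
    write_trial_csv,
)


@dataclass
class SessionShift:
    """Evening-session distribution shift.

    mixing_eps
        Scale of the random channel-mixing perturbation ``I + eps*M``
        (electrode repositioning leaks neighbouring sources between
        channels).  Dimensionless; 0 disables mixing.
    gain_drift
        (low, high) bounds of the per-channel multiplicative amplitude
        factor, sampled uniformly per subject.  Models impedance drift,
        which routinely moves scalp amplitudes by tens of percent.
    noise_sd_ratio
        Evening/morning background-noise SD ratio (end-of-day muscle
        tone and restlessness).
    baseline_offset_sd
        SD of a constant per-channel offset in microvolts (largely
        removed again by the high-pass edge of the band-pass filters).
    """

    mixing_eps: float = 0.2
    gain_drift: tuple[float, float] = (0.8, 1.25)
    noise_sd_ratio: float = 1.2
    baseline_offset_sd: float = 1.0

    @classmethod
    def neutral(cls) -> "SessionShift":
        """Identity shift: morning and evening are identically distributed."""
        return cls(mixing_eps=0.0, gain_drift=(1.0, 1.0), noise_sd_ratio=1.0,
                   baseline_offset_sd=0.0)

    def validate(self) -> None:
        if self.mixing_eps < 0:
            raise ValueError("mixing_eps must be >= 0")
        lo, hi = self.gain_drift
        if not (0 < lo <= hi):
            raise ValueError("gain_drift bounds must be positive with low <= high")
        if self.noise_sd_ratio <= 0:
            raise ValueError("noise_sd_ratio must be > 0")
        if self.baseline_offset_sd < 0:
            raise ValueError("baseline_offset_sd must be >= 0")


@dataclass
class SimulationConfig:
    """Full description of a synthetic two-session dataset.

    Amplitudes are in microvolts.  The defaults reproduce the study
    protocol geometry (15 subjects, 10 repetitions, 16 s trials with 3 s
    warning periods, 7 Hz stimulation) with background noise around
    10 uV RMS and ocular deflections an order of magnitude above the
    SSVEP, as is typical for frontal-site recordings.
    """

    n_subjects: int = 15
    classes: tuple[str, ...] = CLASSES
    reps_per_class: int = 10
    fs: float = 256.0
    trial_seconds: float = 16.0
    warning_seconds: float = 3.0
    ssvep_freq: float = 7.0
    ssvep_amp: float = 8.0
    harmonic_amp: float = 1.5
    eog_amp: float = 40.0
    pink_noise_sd: float = 10.0
    white_noise_sd: float = 2.0
    motion_period: float = 2.0
    blink_rate: float = 0.15
    session_shift: SessionShift = field(default_factory=SessionShift)
    seed: int = 0

    def validate(self) -> None:
        n = self.trial_seconds * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_seconds * fs must be an integer sample count")
        if not self.warning_seconds < self.trial_seconds / 2:
            raise ValueError("warning_seconds must be < trial_seconds / 2")
        for name in ("ssvep_amp", "harmonic_amp", "eog_amp", "pink_noise_sd",
                     "white_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects < 1 or self.reps_per_class < 1:
            raise ValueError("n_subjects and reps_per_class must be >= 1")
        if self.motion_period <= 0 or self.ssvep_freq <= 0:
            raise ValueError("motion_period and ssvep_freq must be > 0")
        unknown = set(self.classes) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")
        self.session_shift.validate()

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.fs))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "session_shift" in data and isinstance(data["session_shift"], dict):
            data["session_shift"] = SessionShift(**data["session_shift"])
        if "classes" in data:
            data["classes"] = tuple(data["classes"])
        cfg = cls(**data)
        if isinstance(cfg.session_shift.gain_drift, list):
            cfg.session_shift.gain_drift = tuple(cfg.session_shift.gain_drift)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classes"] = list(self.classes)
        d["session_shift"]["gain_drift"] = list(self.session_shift.gain_drift)
        return d


@dataclass
class SubjectProfile:
    """Deterministic per-subject gains and evening-shift realization."""

    subject_index: int
    subject_id: str
    channel_gains: np.ndarray        # (4,) broadband gain per channel
    ssvep_gain: float                # subject-level SSVEP amplitude multiplier
    ssvep_channel_gains: np.ndarray  # (4,) channel weighting of the SSVEP
    noise_gain: float                # subject-level noise multiplier
    evening_mixing: np.ndarray       # (4, 4) channel mixing matrix
    evening_gains: np.ndarray        # (4,) per-channel gain drift
    evening_baseline: np.ndarray     # (4,) constant offset, microvolts


def subject_id_for(index: int) -> str:
    return f"sub{index + 1:02d}"


def subject_profile(cfg: SimulationConfig, subject_index: int) -> SubjectProfile:
    """Draw the per-subject parameters from a config-seeded stream."""
    if not 0 <= subject_index < cfg.n_subjects:
        raise IndexError(
            f"subject_index {subject_index} out of range [0, {cfg.n_subjects})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1, subject_index]))
    shift = cfg.session_shift
    lo, hi = shift.gain_drift
    mixing = np.eye(4) + shift.mixing_eps * rng.standard_normal((4, 4))
    return SubjectProfile(
        subject_index=subject_index,
        subject_id=subject_id_for(subject_index),
        channel_gains=rng.lognormal(mean=0.0, sigma=0.1, size=4),
        ssvep_gain=float(rng.lognormal(mean=0.0, sigma=0.25)),
        ssvep_channel_gains=rng.lognormal(mean=0.0, sigma=0.15, size=4),
        noise_gain=float(rng.lognormal(mean=0.0, sigma=0.15)),
        evening_mixing=mixing,
        evening_gains=rng.uniform(lo, hi, size=4),
        evening_baseline=shift.baseline_offset_sd * rng.standard_normal(4),
    )


# --------------------------------------------------------------------------
# Deterministic trajectory templates
# --------------------------------------------------------------------------

def trajectory_template(class_label: str, duration: float, fs: float,
                        motion_period: float = 2.0) -> np.ndarray:
    """Smooth periodic 4-channel ocular deflection template, peak amplitude 1.

    Vertical gaze drives Fp1/Fp2 with equal sign; horizontal gaze drives
    F7/F8 with opposite signs.  The two diagonal classes are normalized
    sums of a vertical and a horizontal sweep, differing only in the
    sign of the horizontal component.
    """
    if class_label == RANDOM_GAZE:
        raise ValueError(
            "random_gaze has no deterministic template; it is generated "
            "stochastically by simulate_trial"
        )
    if class_label not in TRAJECTORY_CLASSES:
        raise ValueError(f"unknown trajectory class {class_label!r}")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sweep = np.sin(2 * np.pi * t / motion_period)
    vert = np.zeros((n, 4))
    vert[:, 0] = sweep   # Fp1
    vert[:, 3] = sweep   # Fp2
    horiz = np.zeros((n, 4))
    horiz[:, 1] = sweep  # F7
    horiz[:, 2] = -sweep  # F8
    if class_label == "up_down":
        out = vert
    elif class_label == "right_left":
        out = horiz
    elif class_label == "left_cross":
        out = vert + horiz
    else:  # right_cross
        out = vert - horiz
    peak = np.abs(out).max()
    return out / peak


# --------------------------------------------------------------------------
# Trial synthesis
# --------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, n_ch: int) -> np.ndarray:
    """Unit-SD 1/f noise via spectral shaping of white noise."""
    spec = rng.standard_normal((n // 2 + 1, n_ch)) + 1j * rng.standard_normal(
        (n // 2 + 1, n_ch))
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shape[:, None], n=n, axis=0)
    x /= x.std(axis=0, keepdims=True)
    return x


def _smooth_steps(rng: np.random.Generator, t: np.ndarray, rate: float,
                  edge: float = 0.03) -> np.ndarray:
    """Random saccade-like step waveform: piecewise level changes with
    sigmoidal edges, levels in [-1, 1]."""
    duration = t[-1] - t[0] if len(t) else 0.0
    n_steps = rng.poisson(rate * duration)
    x = np.zeros_like(t)
    level = rng.uniform(-0.5, 0.5)
    x += level
    for t0 in np.sort(rng.uniform(t[0], t[-1], size=n_steps)):
        target = rng.uniform(-1.0, 1.0)
        x += (target - level) * 0.5 * (1 + np.tanh((t - t0) / edge))
        level = target
    return x


def _blinks(rng: np.random.Generator, t: np.ndarray, rate: float) -> np.ndarray:
    """Positive blink-like pulses on all four channels (frontal dominance)."""
    n_blinks = rng.poisson(rate * (t[-1] - t[0]))
    out = np.zeros((len(t), 4))
    for _ in range(n_blinks):
        t0 = rng.uniform(t[0], t[-1])
        width = rng.uniform(0.07, 0.14)  # 0.2-0.4 s total footprint
        amp = rng.uniform(60.0, 120.0)
        pulse = amp * np.exp(-0.5 * ((t - t0) / width) ** 2)
        out[:, 0] += pulse
        out[:, 3] += pulse
        out[:, 1] += 0.4 * pulse
        out[:, 2] += 0.4 * pulse
    return out


def _trial_rng(cfg: SimulationConfig, subject_index: int, session: str,
               class_label: str, repetition: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([
        cfg.seed, 2, subject_index, SESSIONS.index(session),
        CLASSES.index(class_label), repetition,
    ]))


def simulate_trial(cfg: SimulationConfig, profile: SubjectProfile, session: str,
                   class_label: str, repetition: int) -> Recording:
    """Synthesize one 16 s trial, fully determined by its protocol key."""
    cfg.validate()
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}")
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    rng = _trial_rng(cfg, profile.subject_index, session, class_label, repetition)

    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    shift = cfg.session_shift
    evening = session == "evening"
    noise_scale = profile.noise_gain * (shift.noise_sd_ratio if evening else 1.0)

    x = cfg.pink_noise_sd * noise_scale * _pink_noise(rng, n, 4)
    x += cfg.white_noise_sd * noise_scale * rng.standard_normal((n, 4))

    # Central task window: between the two warning periods.
    w0 = int(round(cfg.warning_seconds * cfg.fs))
    w1 = n - w0
    active = slice(w0, w1)
    t_active = t[active]

    led_on = class_label != RANDOM_GAZE
    if led_on:
        phase = rng.uniform(0, 2 * np.pi)
        phase2 = rng.uniform(0, 2 * np.pi)
        ssvep = (cfg.ssvep_amp * np.sin(2 * np.pi * cfg.ssvep_freq * t + phase)
                 + cfg.harmonic_amp * np.sin(4 * np.pi * cfg.ssvep_freq * t + phase2))
        x += profile.ssvep_gain * ssvep[:, None] * profile.ssvep_channel_gains
        template = trajectory_template(class_label, cfg.trial_seconds - 2 *
                                       cfg.warning_seconds, cfg.fs,
                                       cfg.motion_period)
        # Small per-trial amplitude jitter keeps repetitions non-identical.
        x[active] += cfg.eog_amp * rng.uniform(0.85, 1.15) * template
    else:
        v = _smooth_steps(rng, t_active, rate=1.0)
        h = _smooth_steps(rng, t_active, rate=1.0)
        gaze = np.zeros((len(t_active), 4))
        gaze[:, 0] = v
        gaze[:, 3] = v
        gaze[:, 1] = h
        gaze[:, 2] = -h
        x[active] += 0.8 * cfg.eog_amp * gaze

    x += _blinks(rng, t, cfg.blink_rate)
    x *= profile.channel_gains

    if evening:
        x = x @ profile.evening_mixing.T
        x *= profile.evening_gains
        x += profile.evening_baseline

    return Recording(
        subject_id=profile.subject_id,
        session=session,
        class_label=class_label,
        repetition=repetition,
        samples=x,
        fs=cfg.fs,
    )


def iter_trial_keys(cfg: SimulationConfig):
    """Yield (subject_index, session, class_label, repetition) in protocol order."""
    for s in range(cfg.n_subjects):
        for session in SESSIONS:
            for class_label in cfg.classes:
                for rep in range(1, cfg.reps_per_class + 1):
                    yield s, session, class_label, rep


def simulate_recordings(cfg: SimulationConfig):
    """Generate the full dataset in memory, one Recording at a time."""
    cfg.validate()
    profiles = {s: subject_profile(cfg, s) for s in range(cfg.n_subjects)}
    for s, session, class_label, rep in iter_trial_keys(cfg):
        yield simulate_trial(cfg, profiles[s], session, class_label, rep)


def simulate_dataset(cfg: SimulationConfig, out_dir: str | os.PathLike) -> DatasetManifest:
    """Write the full dataset (trial CSVs + manifest.csv) under out_dir."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []
    try:
        for rec in simulate_recordings(cfg):
            fname = (f"{rec.subject_id}_{rec.session}_{rec.class_label}_"
                     f"rep{rec.repetition:02d}.csv")
            write_trial_csv(rec, out_dir / fname)
            entries.append(ManifestEntry(
                path=fname,
                subject_id=rec.subject_id,
                session=rec.session,
                class_label=rec.class_label,
                repetition=rec.repetition,
            ))
    except OSError:
        for e in entries:  # leave no partial dataset behind
            (out_dir / e.path).unlink(missing_ok=True)
        raise
    manifest = DatasetManifest(entries=entries, root=out_dir)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
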