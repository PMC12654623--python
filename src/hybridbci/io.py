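"""Core data model and on-disk formats.

A *trial* is one 16 s recording of four frontal EEG channels (Fp1, F7,
F8, Fp2) at 256 Hz while a subject either followed a moving target with
the 7 Hz LED on (four trajectory classes) or gazed randomly with the LED
off.  Trials are stored one per file in a small self-describing CSV
dialect: ``# key: value`` comment lines carry the metadata, followed by
one header row of channel names and one row per sample (microvolts).
A dataset is described by a manifest CSV listing every trial file with
its (subject, session, class, repetition) key.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Protocol channel montage, in the fixed on-disk column order.
CHANNELS: tuple[str, ...] = ("Fp1", "F7", "F8", "Fp2")

#: Recording sessions (training domain first).
SESSIONS: tuple[str, ...] = ("morning", "evening")

#: The four LED-on trajectory classes followed by the LED-off control class.
TRAJECTORY_CLASSES: tuple[str, ...] = (
    "left_cross",
    "right_cross",
    "right_left",
    "up_down",
)
RANDOM_GAZE = "random_gaze"
CLASSES: tuple[str, ...] = TRAJECTORY_CLASSES + (RANDOM_GAZE,)

#: Protocol constants: sampling rate and untrimmed trial length.
PROTOCOL_FS = 256.0
PROTOCOL_TRIAL_SAMPLES = 4096

MANIFEST_SCHEMA_VERSION = "1"
MANIFEST_COLUMNS = ("path", "subject_id", "session", "class_label", "repetition")


class TrialFormatError(ValueError):
    """Raised when a trial CSV does not conform to the dialect."""


class ManifestError(ValueError):
    """Raised when a dataset manifest fails validation."""


@dataclass
class Recording:
    """One trial: a [n_samples x n_channels] matrix in microvolts plus metadata."""

    subject_id: str
    session: str
    class_label: str
    repetition: int
    samples: np.ndarray
    fs: float = PROTOCOL_FS
    channels: tuple[str, ...] = CHANNELS
    trimmed: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [n_samples x n_channels] matrix")
        self.channels = tuple(self.channels)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.fs

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.subject_id, self.session, self.class_label, self.repetition)


def validate_recording(rec: Recording) -> list[str]:
    """Check a Recording against the protocol invariants.

    Returns a list of human-readable violation messages; an empty list
    means the recording is protocol-conformant.  Validation never raises.
    """
    violations: list[str] = []
    if rec.channels != CHANNELS:
        violations.append(
            f"channel order must be {CHANNELS} in this fixed order, got {rec.channels}"
        )
    if rec.fs != PROTOCOL_FS:
        violations.append(f"sampling rate must be {PROTOCOL_FS:g} Hz, got {rec.fs:g}")
    if rec.samples.shape[1] != len(rec.channels):
        violations.append(
            f"samples have {rec.samples.shape[1]} columns for "
            f"{len(rec.channels)} channel names"
        )
    if not rec.trimmed and rec.n_samples != PROTOCOL_TRIAL_SAMPLES:
        violations.append(
            f"untrimmed trials must have {PROTOCOL_TRIAL_SAMPLES} samples, "
            f"got {rec.n_samples}"
        )
    if rec.session not in SESSIONS:
        violations.append(f"session must be one of {SESSIONS}, got {rec.session!r}")
    if rec.class_label not in CLASSES:
        violations.append(
            f"class_label must be one of {CLASSES}, got {rec.class_label!r}"
        )
    if rec.repetition < 1:
        violations.append(f"repetition must be >= 1, got {rec.repetition}")
    if not np.all(np.isfinite(rec.samples)):
        violations.append("samples contain non-finite values")
    return violations


# --------------------------------------------------------------------------
# Trial CSV dialect
# --------------------------------------------------------------------------

_META_FIELDS = ("subject_id", "session", "class_label", "repetition", "fs", "trimmed")


def write_trial_csv(rec: Recording, path: str | os.PathLike) -> Path:
    """Write a Recording in the trial CSV dialect; deterministic bytes.

    Samples are written with 10 significant digits, enough for a
    round-trip error below 1e-9 microvolts at EEG amplitudes.
    """
    violations = validate_recording(rec)
    # Trimmed/non-protocol recordings are still writable; only structural
    # impossibilities (channel count mismatch) block serialization.
    if rec.samples.shape[1] != len(rec.channels):
        raise TrialFormatError("; ".join(violations))
    path = Path(path)
    buf = _stdio.StringIO()
    buf.write(f"# subject_id: {rec.subject_id}\n")
    buf.write(f"# session: {rec.session}\n")
    buf.write(f"# class_label: {rec.class_label}\n")
    buf.write(f"# repetition: {rec.repetition}\n")
    buf.write(f"# fs: {rec.fs:.10g}\n")
    buf.write(f"# trimmed: {str(rec.trimmed).lower()}\n")
    buf.write(",".join(rec.channels) + "\n")
    np.savetxt(buf, rec.samples, fmt="%.10g", delimiter=",")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_trial_csv(path: str | os.PathLike) -> Recording:
    """Parse a trial CSV file written in the package dialect."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
        frame = pd.read_csv(fh, dtype=str)

    missing = [k for k in _META_FIELDS if k not in meta]
    if missing:
        raise TrialFormatError(f"{path}: missing metadata fields {missing}")

    channels = tuple(c.strip() for c in frame.columns)
    for ch in CHANNELS:
        if ch not in channels:
            raise TrialFormatError(f"{path}: missing channel column {ch!r}")

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise TrialFormatError(
            f"{path}: non-numeric value at data row {row}, column {frame.columns[col]!r}"
        )
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy())[0][0])
        raise TrialFormatError(f"{path}: empty cell at data row {row}")

    return Recording(
        subject_id=meta["subject_id"],
        session=meta["session"],
        class_label=meta["class_label"],
        repetition=int(meta["repetition"]),
        samples=numeric.to_numpy(dtype=float),
        fs=float(meta["fs"]),
        channels=channels,
        trimmed=meta["trimmed"] == "true",
    )


# --------------------------------------------------------------------------
# Dataset manifest
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    path: str
    subject_id: str
    session: str
    class_label: str
    repetition: int

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.subject_id, self.session, self.class_label, self.repetition)


@dataclass
class DatasetManifest:
    """Index of all trial files of a dataset, keyed by the protocol tuple."""

    entries: list[ManifestEntry]
    root: Path = field(default_factory=Path)
    schema_version: str = MANIFEST_SCHEMA_VERSION

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self, check_files: bool = True) -> None:
        seen: set[tuple] = set()
        for e in self.entries:
            if e.key in seen:
                raise ManifestError(f"duplicate manifest key {e.key}")
            seen.add(e.key)
            if check_files and not (self.root / e.path).exists():
                raise ManifestError(f"dangling file reference {e.path!r}")

    def iter_recordings(self):
        """Yield the Recording for every entry, in manifest order."""
        for e in self.entries:
            yield read_trial_csv(self.root / e.path)


def save_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> Path:
    path = Path(path)
    frame = pd.DataFrame([dataclasses.asdict(e) for e in manifest.entries],
                         columns=list(MANIFEST_COLUMNS))
    path.write_text(frame.to_csv(index=False), encoding="utf-8")
    return path


def load_manifest(path: str | os.PathLike, check_files: bool = True) -> DatasetManifest:
    """Load and validate a manifest CSV; trial files resolve next to it."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"repetition": int})
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    entries = [
        ManifestEntry(
            path=str(r.path),
            subject_id=str(r.subject_id),
            session=str(r.session),
            class_label=str(r.class_label),
            repetition=int(r.repetition),
        )
        for r in frame.itertuples(index=False)
    ]
    manifest = DatasetManifest(entries=entries, root=path.parent)
    manifest.validate(check_files=check_files)
    return manifest
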