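"""Stage-2 time-domain features and the shared z-score standardizer.

Each 3 s window contributes, per channel, its mean-square power, its
sum-of-squares energy, and the 21 coefficients of a degree-20
least-squares polynomial fit — 23 features x 4 channels = 92 columns.
The polynomial is fitted on a time axis affinely mapped to [-1, 1]; a
raw degree-20 Vandermonde system on 768 integer sample indices is
numerically singular in double precision, so the coefficients are
defined (and named) in the scaled domain, in descending-power order.

The z-score standardizer learns per-column mean and sample standard
deviation from the training rows only and is applied unchanged to test
rows, so session shifts in scale and offset survive into the
standardized test features — exactly the mismatch the CORAL step is
there to absorb.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CHANNELS

logger = logging.getLogger(__name__)

DEFAULT_POLY_DEGREE = 20


@dataclass
class FeatureTable:
    """Rows = segments, columns = named features, plus row metadata."""

    X: np.ndarray                       # (n_rows, n_features)
    feature_names: list[str]
    labels: np.ndarray                  # class label per row
    session: np.ndarray                 # session tag per row
    subject: np.ndarray                 # subject id per row

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.session = np.asarray(self.session)
        self.subject = np.asarray(self.subject)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError("X shape inconsistent with feature_names")
        for meta in (self.labels, self.session, self.subject):
            if len(meta) != self.X.shape[0]:
                raise ValueError("row metadata length mismatch")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def mask(self, rows: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X[rows], list(self.feature_names),
                            self.labels[rows], self.session[rows],
                            self.subject[rows])

    def select_features(self, names: list[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.X[:, idx], list(names), self.labels,
                            self.session, self.subject)

    def with_X(self, X: np.ndarray) -> "FeatureTable":
        return FeatureTable(X, list(self.feature_names), self.labels,
                            self.session, self.subject)

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if other.feature_names != self.feature_names:
            raise ValueError("feature name mismatch")
        return FeatureTable(
            np.vstack([self.X, other.X]), list(self.feature_names),
            np.concatenate([self.labels, other.labels]),
            np.concatenate([self.session, other.session]),
            np.concatenate([self.subject, other.subject]),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame.insert(0, "subject", self.subject)
        frame.insert(1, "session", self.session)
        frame.insert(2, "label", self.labels)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        meta = ["subject", "session", "label"]
        names = [c for c in frame.columns if c not in meta]
        return cls(frame[names].to_numpy(float), names,
                   frame["label"].to_numpy(), frame["session"].to_numpy(),
                   frame["subject"].to_numpy())


# --------------------------------------------------------------------------
# Per-channel features
# --------------------------------------------------------------------------

def power_energy(x: np.ndarray) -> tuple[float, float]:
    """(mean-square power, sum-of-squares energy) of a 1-D segment."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    energy = float(np.sum(x * x))
    return energy / x.size, energy


def polyfit_coeffs(x: np.ndarray, degree: int = DEFAULT_POLY_DEGREE) -> np.ndarray:
    """Least-squares polynomial coefficients on the [-1, 1] time axis.

    Returns degree + 1 coefficients in descending-power order.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= degree:
        raise ValueError(f"segment length {n} must exceed degree {degree}")
    t = np.linspace(-1.0, 1.0, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coeffs, _, rank, _, _ = np.polyfit(t, x, degree, full=True)
    if rank < degree + 1:
        raise ValueError(f"rank-deficient polynomial fit (rank {rank})")
    return coeffs


def stage2_feature_names(degree: int = DEFAULT_POLY_DEGREE,
                         channels: tuple[str, ...] = CHANNELS) -> list[str]:
    names = []
    for ch in channels:
        names.append(f"{ch}_power")
        names.append(f"{ch}_energy")
        names.extend(f"{ch}_poly_t{p}" for p in range(degree, -1, -1))
    return names


def assemble_stage2_features(segment_sets, degree: int = DEFAULT_POLY_DEGREE,
                             channels: tuple[str, ...] = CHANNELS) -> FeatureTable:
    """Build the stage-2 FeatureTable from stage-2-filtered SegmentSets.

    Per segment and channel (order Fp1, F7, F8, Fp2): power, energy,
    then the degree + 1 polynomial coefficients.  The default degree of
    20 gives 4 x 23 = 92 columns.
    """
    names = stage2_feature_names(degree, channels)
    rows, labels, sessions, subjects = [], [], [], []
    for seg_set in segment_sets:
        subject_id, session, class_label, _rep = seg_set.trial_ref
        for seg in seg_set.segments:
            if seg.shape[1] != len(channels):
                raise ValueError(
                    f"expected {len(channels)} channels, got {seg.shape[1]}"
                )
            row = []
            for c in range(len(channels)):
                p, e = power_energy(seg[:, c])
                row.extend((p, e))
                row.extend(polyfit_coeffs(seg[:, c], degree))
            rows.append(row)
            labels.append(class_label)
            sessions.append(session)
            subjects.append(subject_id)
    X = np.asarray(rows, dtype=float) if rows else np.empty((0, len(names)))
    return FeatureTable(X, names, np.asarray(labels), np.asarray(sessions),
                        np.asarray(subjects))


# --------------------------------------------------------------------------
# Z-score standardizer
# --------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature z-score transform z = (x - mean) / sd, fit on training rows.

    Sample (n-1) standard deviation.  Zero-variance columns get sd
    replaced by 1 (with a logged warning) so the transform never
    divides by zero.
    """

    mean_: np.ndarray
    scale_: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    @classmethod
    def fit(cls, table: FeatureTable) -> "Standardizer":
        if table.n_rows < 2:
            raise ValueError("need >= 2 rows to fit a standardizer")
        mean = table.X.mean(axis=0)
        scale = table.X.std(axis=0, ddof=1)
        degenerate = scale == 0
        if degenerate.any():
            bad = [table.feature_names[i] for i in np.flatnonzero(degenerate)]
            logger.warning("zero-variance columns %s: sd guard set to 1", bad)
            warnings.warn(f"zero-variance columns {bad}: sd guard set to 1",
                          stacklevel=2)
            scale = np.where(degenerate, 1.0, scale)
        return cls(mean_=mean, scale_=scale,
                   feature_names=list(table.feature_names))

    def _check(self, table: FeatureTable) -> None:
        if table.feature_names != self.feature_names:
            raise ValueError("feature names do not match the fitted table")

    def transform(self, table: FeatureTable) -> FeatureTable:
        self._check(table)
        return table.with_X((table.X - self.mean_) / self.scale_)

    def inverse_transform(self, table: FeatureTable) -> FeatureTable:
        self._check(table)
        return table.with_X(table.X * self.scale_ + self.mean_)


def fit_standardizer(train: FeatureTable) -> Standardizer:
    return Standardizer.fit(train)


def apply_standardizer(s: Standardizer, table: FeatureTable) -> FeatureTable:
    return s.transform(table)
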