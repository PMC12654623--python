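"""CORAL (correlation alignment) domain adaptation.

Cross-session drift leaves the standardized evening features with a
different second-moment structure than the morning features the
classifier was trained on.  CORAL removes that mismatch without
touching target labels: source rows are whitened with the source
covariance and recolored with the target covariance,

    A = (Cs + lambda*I)^(-1/2) (Ct + lambda*I)^(1/2),    x -> x A,

after which cov(source A) = Ct + lambda*I - lambda*A'A ~ Ct.  Both
square roots are the symmetric PSD roots from an eigendecomposition
with eigenvalues clamped at zero.  The ridge term keeps the inverse
root well posed when the feature dimension (92) approaches the number
of rows per subject.  On standardized (unit-variance) features a small
ridge suffices; the default is 0.1, i.e. a 10% inflation of every
eigenvalue, which keeps the inverse root stable without washing out
the alignment itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureTable

DEFAULT_LAMBDA = 0.1


@dataclass
class CoralTransform:
    """Fitted whitening-recoloring matrix mapping source rows toward the target."""

    matrix: np.ndarray              # (d, d)
    lam: float
    feature_names: list[str]

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "lam": self.lam,
                "feature_names": list(self.feature_names)}

    @classmethod
    def from_dict(cls, data: dict) -> "CoralTransform":
        return cls(matrix=np.asarray(data["matrix"], dtype=float),
                   lam=float(data["lam"]),
                   feature_names=list(data["feature_names"]))


def _sym_sqrt(c: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Symmetric PSD square root (or inverse root) via eigendecomposition."""
    vals, vecs = np.linalg.eigh(c)
    vals = np.clip(vals, 0.0, None)
    if inverse:
        if np.any(vals <= 0):
            raise np.linalg.LinAlgError(
                "singular covariance: inverse square root undefined (increase lambda)"
            )
        root = 1.0 / np.sqrt(vals)
    else:
        root = np.sqrt(vals)
    return (vecs * root) @ vecs.T


def fit_coral(source: FeatureTable, target: FeatureTable,
              lam: float = DEFAULT_LAMBDA) -> CoralTransform:
    """Estimate the CORAL transform from unlabeled source/target rows.

    Target labels are never read; covariances are estimated with each
    domain centered by its own mean.
    """
    if source.feature_names != target.feature_names:
        raise ValueError("source and target feature columns differ")
    if source.n_rows < 2 or target.n_rows < 2:
        raise ValueError("need >= 2 rows per domain to estimate covariances")
    if not (np.all(np.isfinite(source.X)) and np.all(np.isfinite(target.X))):
        raise ValueError("non-finite feature values")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    d = source.X.shape[1]
    cs = np.cov(source.X, rowvar=False, ddof=1).reshape(d, d)
    ct = np.cov(target.X, rowvar=False, ddof=1).reshape(d, d)
    eye = np.eye(d)
    a = _sym_sqrt(cs + lam * eye, inverse=True) @ _sym_sqrt(ct + lam * eye)
    return CoralTransform(matrix=a, lam=lam,
                          feature_names=list(source.feature_names))


def apply_coral(t: CoralTransform, table: FeatureTable) -> FeatureTable:
    """Right-multiply rows by the fitted matrix; metadata untouched."""
    if table.feature_names != t.feature_names:
        raise ValueError("feature fingerprint does not match the fitted transform")
    return table.with_X(table.X @ t.matrix)
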