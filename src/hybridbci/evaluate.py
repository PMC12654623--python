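"""Classifier contracts, ANOVA feature selection, and evaluation statistics.

Three classifier families mirror the study configuration: bootstrap
aggregating over 100 depth-15 decision trees, a 50-tree random forest
with per-tree random feature subsets, and a one-vs-one SVM whose
kernel, kernel scale, and box constraint are tuned by a 30-evaluation
randomized search under 5-fold cross-validation on training data only.

Metrics follow the convention of per-class accuracy = class recall and
macro-averaged precision/recall/F1 (under balanced test classes macro
recall equals overall accuracy).  The information transfer rate is the
Wolpaw bit rate.  The signed-rank test is exact: its null distribution
is enumerated over all 2^n sign assignments (via the equivalent
generating-function recursion), with no normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

CLASSIFIER_FAMILIES = ("bagging", "random_forest", "svm_ovo")


@dataclass
class ClassifierSpec:
    """Family + hyperparameters; the seed fixes every stochastic choice."""

    family: str = "bagging"
    n_trees: int | None = None
    max_depth: int | None = None
    search_iters: int = 30
    search_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"family must be one of {CLASSIFIER_FAMILIES}")
        if self.n_trees is None:
            self.n_trees = 100 if self.family == "bagging" else 50
        if self.max_depth is None and self.family == "bagging":
            self.max_depth = 15
        if self.n_trees < 1 or self.search_iters < 1:
            raise ValueError("n_trees and search_iters must be positive")


@dataclass
class TrainedModel:
    estimator: object
    feature_names: list[str]
    classes: np.ndarray


@dataclass
class AnovaSelection:
    """Per-feature one-way F statistics with the retained set at level alpha."""

    feature_names: list[str]
    f_statistic: np.ndarray
    p_value: np.ndarray
    alpha: float
    selected: list[str]


@dataclass
class MetricsReport:
    """Per-class and aggregate classification metrics, all in percent."""

    classes: list[str]
    per_class_accuracy: dict[str, float]
    overall_accuracy: float
    precision: float
    recall: float
    f1: float
    itr: float | None = None
    n_repetitions: int = 1
    per_repetition: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "per_class_accuracy": dict(self.per_class_accuracy),
            "overall_accuracy": self.overall_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "itr": self.itr,
            "n_repetitions": self.n_repetitions,
            "per_repetition": list(self.per_repetition),
        }


# --------------------------------------------------------------------------
# Classifiers
# --------------------------------------------------------------------------

def _build_estimator(spec: ClassifierSpec):
    if spec.family == "bagging":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(max_depth=spec.max_depth,
                                             random_state=spec.seed),
            n_estimators=spec.n_trees,
            random_state=spec.seed,
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features="sqrt",
            random_state=spec.seed,
        )
    # One-vs-one margin classifier with randomized hyperparameter search
    # over kernel, kernel scale (gamma), and box constraint (C).
    param_distributions = {
        "kernel": ["linear", "rbf"],
        "C": stats.loguniform(1e-2, 1e3),
        "gamma": stats.loguniform(1e-4, 1e1),
    }
    return RandomizedSearchCV(
        SVC(decision_function_shape="ovo", random_state=spec.seed),
        param_distributions=param_distributions,
        n_iter=spec.search_iters,
        cv=StratifiedKFold(n_splits=spec.search_folds, shuffle=True,
                           random_state=spec.seed),
        random_state=spec.seed,
        n_jobs=1,
    )


def train_classifier(spec: ClassifierSpec, train: FeatureTable) -> TrainedModel:
    if train.n_rows == 0:
        raise ValueError("empty training table")
    if not np.all(np.isfinite(train.X)):
        raise ValueError("non-finite feature values in training table")
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError("training data must contain >= 2 classes")
    est = _build_estimator(spec)
    est.fit(train.X, train.labels)
    return TrainedModel(estimator=est, feature_names=list(train.feature_names),
                        classes=classes)


def predict(model: TrainedModel, test: FeatureTable) -> np.ndarray:
    """Predict one label per row, realigning columns by feature name."""
    if set(test.feature_names) != set(model.feature_names):
        raise ValueError("test feature columns do not match the trained model")
    if test.feature_names != model.feature_names:
        test = test.select_features(model.feature_names)
    return np.asarray(model.estimator.predict(test.X))


# --------------------------------------------------------------------------
# ANOVA F-test feature selection
# --------------------------------------------------------------------------

def anova_select(table: FeatureTable, alpha: float = 0.05) -> AnovaSelection:
    """One-way F test per feature across class groups; retain p < alpha.

    Constant features get F = 0, p = 1 (dropped); features with zero
    within-class variance but distinct class means have infinite F and
    p = 0 (retained).
    """
    classes, inverse = np.unique(table.labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes for ANOVA selection")
    counts = np.bincount(inverse)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 rows for ANOVA selection")
    n, k = table.n_rows, len(classes)
    grand = table.X.mean(axis=0)
    ss_between = np.zeros(table.X.shape[1])
    ss_within = np.zeros(table.X.shape[1])
    for g in range(k):
        rows = table.X[inverse == g]
        mean_g = rows.mean(axis=0)
        ss_between += len(rows) * (mean_g - grand) ** 2
        ss_within += ((rows - mean_g) ** 2).sum(axis=0)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    constant = table.X.max(axis=0) == table.X.min(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    f = np.where(constant, 0.0, f)
    p = np.where(np.isinf(f), 0.0,
                 stats.f.sf(np.where(np.isfinite(f), f, 0.0), k - 1, n - k))
    p = np.where(constant, 1.0, p)
    selected = [name for name, pv in zip(table.feature_names, p) if pv < alpha]
    return AnovaSelection(feature_names=list(table.feature_names),
                          f_statistic=f, p_value=p, alpha=alpha,
                          selected=selected)


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def compute_metrics(truth: np.ndarray, predicted: np.ndarray,
                    classes: list[str]) -> MetricsReport:
    """Per-class accuracy (= recall), overall accuracy, macro P/R/F1, in percent."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    unseen = set(predicted) - set(classes)
    if unseen:
        raise ValueError(f"predicted labels {sorted(unseen)} not in class list")
    unseen_truth = set(truth) - set(classes)
    if unseen_truth:
        raise ValueError(f"true labels {sorted(unseen_truth)} not in class list")

    per_class: dict[str, float] = {}
    precisions, recalls, f1s = [], [], []
    for c in classes:
        is_c = truth == c
        pred_c = predicted == c
        tp = float(np.sum(is_c & pred_c))
        rec = tp / is_c.sum() if is_c.sum() else 0.0
        prec = tp / pred_c.sum() if pred_c.sum() else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        per_class[c] = 100.0 * rec
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return MetricsReport(
        classes=list(classes),
        per_class_accuracy=per_class,
        overall_accuracy=100.0 * float(np.mean(truth == predicted)),
        precision=100.0 * float(np.mean(precisions)),
        recall=100.0 * float(np.mean(recalls)),
        f1=100.0 * float(np.mean(f1s)),
    )


def wolpaw_itr(overall_accuracy: float, n_classes: int,
               selection_seconds: float = 2.5) -> float:
    """Wolpaw bit rate in bits/min.

    B = log2 N + P log2 P + (1 - P) log2((1 - P) / (N - 1)) per
    selection, scaled by 60 / T.  P = 1/N gives 0 by continuity; P = 1
    gives log2 N.
    """
    p, n = float(overall_accuracy), int(n_classes)
    if n < 2:
        raise ValueError("need >= 2 classes")
    if selection_seconds <= 0:
        raise ValueError("selection time must be positive")
    chance = 1.0 / n
    if p < chance - 1e-12 or p > 1 + 1e-12:
        raise ValueError(f"accuracy {p:g} outside [1/N, 1]")
    p = min(p, 1.0)
    bits = np.log2(n)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (n - 1))
    if abs(p - chance) < 1e-12:
        bits = 0.0
    return float(bits * 60.0 / selection_seconds)


# --------------------------------------------------------------------------
# Exact Wilcoxon signed-rank test
# --------------------------------------------------------------------------

def _signed_rank_null(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of W+ over all 2^n sign assignments of the given ranks.

    Ranks may be half-integers (average ranks under ties); internally
    doubled to stay on an integer lattice.  The generating-function
    recursion enumerates the same 2^n assignments without materializing
    them.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    support = np.arange(total + 1) / 2.0
    return support, counts / counts.sum()


def wilcoxon_exact(paired_a, paired_b, alternative: str = "two-sided") -> float:
    """Exact signed-rank p-value for paired samples (n <= 25).

    Zero differences are dropped with a warning (signed-rank
    convention); tied absolute differences receive average ranks.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = a - b
    zeros = d == 0
    if zeros.any():
        warnings.warn(f"dropping {int(zeros.sum())} zero difference(s)",
                      stacklevel=2)
        d = d[~zeros]
    n = len(d)
    if n == 0:
        return 1.0
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    support, pmf = _signed_rank_null(ranks)
    cdf = float(pmf[support <= w_plus + 1e-9].sum())
    sf = float(pmf[support >= w_plus - 1e-9].sum())
    if alternative == "greater":
        return sf
    if alternative == "less":
        return cdf
    return min(1.0, 2.0 * min(cdf, sf))


# --------------------------------------------------------------------------
# Repetition averaging
# --------------------------------------------------------------------------

def repeat_and_average(run, n_repetitions: int = 10,
                       base_seed: int = 0) -> MetricsReport:
    """Average a training/evaluation closure over derived seeds.

    ``run(seed)`` must return a MetricsReport; scalar metrics and the
    per-class accuracies are averaged, and each repetition's values are
    retained.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_repetitions)
    reports = [run(int(s) % (2 ** 31)) for s in seeds]
    classes = reports[0].classes
    per_class = {
        c: float(np.mean([r.per_class_accuracy[c] for r in reports]))
        for c in classes
    }
    itrs = [r.itr for r in reports]
    return MetricsReport(
        classes=list(classes),
        per_class_accuracy=per_class,
        overall_accuracy=float(np.mean([r.overall_accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        itr=None if any(i is None for i in itrs) else float(np.mean(itrs)),
        n_repetitions=n_repetitions,
        per_repetition=[r.to_dict() for r in reports],
    )
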