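"""End-to-end two-stage experiment orchestration.

Stage 1 (activation gate): per subject, the four per-channel band-ratio
features are standardized on the morning session and a binary
classifier separates LED-on from LED-off segments; the trained gate is
applied to every segment of both sessions.

Stage 2 (trajectory decoding): morning LED-on segments whose gate
decision was correct form the training set; evening trajectory
segments that pass the gate form the test set.  Their 92-dimensional
time-domain features are standardized on the training rows, optionally
CORAL-aligned toward the (unlabeled) evening feature distribution,
optionally reduced by one-way ANOVA selection, and classified over the
four trajectory classes.  Evening labels are read only by the metric
computation, never by any fitted component.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .coral import DEFAULT_LAMBDA, apply_coral, fit_coral
from .evaluate import (
    ClassifierSpec,
    MetricsReport,
    anova_select,
    compute_metrics,
    predict,
    repeat_and_average,
    train_classifier,
    wilcoxon_exact,
    wolpaw_itr,
)
from .features import (
    DEFAULT_POLY_DEGREE,
    FeatureTable,
    apply_standardizer,
    assemble_stage2_features,
    fit_standardizer,
)
from .gate import DEFAULT_OVERLAP, DEFAULT_WINDOW_LEN, gate_ratios
from .io import CHANNELS, RANDOM_GAZE, SESSIONS, TRAJECTORY_CLASSES
from .preprocess import (
    DEFAULT_STRIDE_SAMPLES,
    DEFAULT_WINDOW_SECONDS,
    STAGE1_FILTER,
    STAGE2_FILTER,
    FilterSpec,
    bandpass_zero_phase,
    segment_trial,
    trim_warnings,
)
from .simulate import SimulationConfig, simulate_recordings

logger = logging.getLogger(__name__)

LED_ON = "led_on"
LED_OFF = "led_off"
GATE_CLASSES = [LED_ON, LED_OFF]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one experiment run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    stage1_filter: FilterSpec = STAGE1_FILTER
    stage2_filter: FilterSpec = STAGE2_FILTER
    warning_seconds: float = 3.0
    window_seconds: float = DEFAULT_WINDOW_SECONDS
    stride_samples: int = DEFAULT_STRIDE_SAMPLES
    welch_window_len: int = DEFAULT_WINDOW_LEN
    welch_overlap: int = DEFAULT_OVERLAP
    poly_degree: int = DEFAULT_POLY_DEGREE
    classifier: str = "bagging"
    coral: bool = True
    coral_lam: float = DEFAULT_LAMBDA
    standardize_per_session: bool = True
    anova: bool = False
    anova_alpha: float = 0.05
    selection_seconds: float = 2.5
    n_repetitions: int = 10
    gate_bypass: bool = False
    train_on_correct_gate: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        self.stage1_filter.validate(self.sim.fs)
        self.stage2_filter.validate(self.sim.fs)
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if not 0 < self.anova_alpha <= 1:
            raise ValueError("anova_alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "sim" in data:
            data["sim"] = SimulationConfig.from_dict(data["sim"])
        for key in ("stage1_filter", "stage2_filter"):
            if key in data and isinstance(data[key], dict):
                spec = data[key]
                data[key] = FilterSpec(order=int(spec["order"]),
                                       band=tuple(spec["band"]))
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        for key in ("stage1_filter", "stage2_filter"):
            d[key]["band"] = list(d[key]["band"])
        return d


@dataclass
class PipelineData:
    """Per-segment feature tables for both stages, row-aligned."""

    gate_table: FeatureTable     # 4 band-ratio features; labels led_on/led_off
    stage2_table: FeatureTable   # 92 features; labels = protocol class
    window_starts: np.ndarray    # per row
    repetitions: np.ndarray      # per row

    @property
    def n_rows(self) -> int:
        return self.gate_table.n_rows


@dataclass
class Stage1Result:
    per_subject: dict[str, MetricsReport]
    average_accuracy: float
    decisions: np.ndarray        # gate decision per PipelineData row

    def to_dict(self) -> dict:
        return {
            "per_subject": {s: r.to_dict() for s, r in self.per_subject.items()},
            "average_accuracy": self.average_accuracy,
        }


@dataclass
class Stage2Result:
    per_subject: dict[str, MetricsReport]          # evening (test) metrics
    per_subject_morning: dict[str, MetricsReport]  # training-session metrics
    average: MetricsReport
    average_morning: MetricsReport
    anova_selected: dict[str, int]
    wilcoxon_p: float
    # per-subject evening predictions, one array per repetition (not serialized)
    predictions: dict[str, list] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_subject": {s: r.to_dict() for s, r in self.per_subject.items()},
            "per_subject_morning": {
                s: r.to_dict() for s, r in self.per_subject_morning.items()
            },
            "average": self.average.to_dict(),
            "average_morning": self.average_morning.to_dict(),
            "anova_selected": dict(self.anova_selected),
            "wilcoxon_p": self.wilcoxon_p,
        }


# --------------------------------------------------------------------------
# Feature extraction over a dataset
# --------------------------------------------------------------------------

def build_pipeline_data(cfg: PipelineConfig, recordings) -> PipelineData:
    """Trim, segment, filter, and featurize every trial for both stages."""
    cfg.validate()
    fs = cfg.sim.fs
    gate_rows, gate_labels = [], []
    stage2_sets = []
    sessions, subjects, starts, reps = [], [], [], []
    for rec in recordings:
        trimmed = trim_warnings(rec, cfg.warning_seconds)
        seg_set = segment_trial(trimmed, cfg.window_seconds, cfg.stride_samples)
        led = LED_ON if rec.class_label != RANDOM_GAZE else LED_OFF
        for seg in seg_set.segments:
            filtered1 = bandpass_zero_phase(seg, cfg.stage1_filter, fs)
            gate_rows.append(gate_ratios(filtered1, fs, cfg.welch_window_len,
                                         cfg.welch_overlap))
            gate_labels.append(led)
            sessions.append(rec.session)
            subjects.append(rec.subject_id)
            reps.append(rec.repetition)
        starts.extend(seg_set.window_starts)
        filtered2 = np.stack([
            bandpass_zero_phase(seg, cfg.stage2_filter, fs)
            for seg in seg_set.segments
        ])
        stage2_sets.append(dataclasses.replace(seg_set, segments=filtered2))

    gate_table = FeatureTable(
        np.asarray(gate_rows), [f"{ch}_band_ratio" for ch in CHANNELS],
        np.asarray(gate_labels), np.asarray(sessions), np.asarray(subjects),
    )
    stage2_table = assemble_stage2_features(stage2_sets, cfg.poly_degree)
    return PipelineData(
        gate_table=gate_table,
        stage2_table=stage2_table,
        window_starts=np.asarray(starts),
        repetitions=np.asarray(reps),
    )


# --------------------------------------------------------------------------
# Stage 1: activation gate
# --------------------------------------------------------------------------

def run_stage1(cfg: PipelineConfig, data: PipelineData) -> Stage1Result:
    """Train the per-subject gate on morning ratios; decide every segment."""
    table = data.gate_table
    for session in SESSIONS:
        if not np.any(table.session == session):
            raise ValueError(f"dataset contains no {session} session")
    decisions = np.empty(table.n_rows, dtype=object)
    per_subject: dict[str, MetricsReport] = {}
    for subject in sorted(set(table.subject)):
        is_subj = table.subject == subject
        morning = is_subj & (table.session == "morning")
        evening = is_subj & (table.session == "evening")
        train_table = table.mask(morning)
        std = fit_standardizer(train_table)
        spec = ClassifierSpec(family=cfg.classifier, seed=cfg.seed)
        model = train_classifier(spec, apply_standardizer(std, train_table))
        for rows in (morning, evening):
            rows_table = table.mask(rows)
            # Each session is z-scored with its own (label-free) statistics,
            # absorbing session-level amplitude/offset drift before the gate.
            row_std = (fit_standardizer(rows_table)
                       if cfg.standardize_per_session else std)
            decisions[rows] = predict(model, apply_standardizer(row_std, rows_table))
        per_subject[subject] = compute_metrics(
            table.labels[evening], decisions[evening], GATE_CLASSES
        )
    avg = float(np.mean([r.overall_accuracy for r in per_subject.values()]))
    logger.info("stage 1: mean evening gate accuracy %.2f%%", avg)
    return Stage1Result(per_subject=per_subject, average_accuracy=avg,
                        decisions=decisions.astype(str))


# --------------------------------------------------------------------------
# Stage 2: trajectory classification
# --------------------------------------------------------------------------

def _average_reports(reports: list[MetricsReport],
                     classes: list[str]) -> MetricsReport:
    itrs = [r.itr for r in reports]
    return MetricsReport(
        classes=list(classes),
        per_class_accuracy={
            c: float(np.mean([r.per_class_accuracy[c] for r in reports]))
            for c in classes
        },
        overall_accuracy=float(np.mean([r.overall_accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        itr=None if any(i is None for i in itrs) else float(np.mean(itrs)),
        n_repetitions=reports[0].n_repetitions,
    )


def run_stage2(cfg: PipelineConfig, data: PipelineData,
               stage1: Stage1Result) -> Stage2Result:
    """Decode the four trajectories per subject, morning-train / evening-test."""
    table = data.stage2_table
    classes = list(TRAJECTORY_CLASSES)
    is_trajectory = np.isin(table.labels, classes)
    gate_on = stage1.decisions == LED_ON

    per_subject: dict[str, MetricsReport] = {}
    per_subject_morning: dict[str, MetricsReport] = {}
    anova_selected: dict[str, int] = {}
    predictions: dict[str, list] = {}
    for subject in sorted(set(table.subject)):
        is_subj = table.subject == subject
        train_rows = is_subj & (table.session == "morning") & is_trajectory
        if cfg.train_on_correct_gate:
            train_rows &= gate_on
        test_rows = is_subj & (table.session == "evening") & is_trajectory
        if not cfg.gate_bypass:
            test_rows &= gate_on
        if not test_rows.any():
            raise ValueError(
                f"{subject}: no evening segments pass the stage-1 gate; "
                "re-check the gate or run with gate_bypass"
            )
        train_table = table.mask(train_rows)
        test_table = table.mask(test_rows)

        std = fit_standardizer(train_table)
        train_std = apply_standardizer(std, train_table)
        # Per-session z-scoring (the default) removes first-moment and
        # per-feature scale drift; CORAL then aligns what z-scoring cannot:
        # the cross-feature correlation structure.  Test labels are unread.
        test_std = apply_standardizer(
            fit_standardizer(test_table) if cfg.standardize_per_session else std,
            test_table)
        if cfg.coral:
            transform = fit_coral(train_std, test_std, cfg.coral_lam)
            train_std = apply_coral(transform, train_std)
        if cfg.anova:
            selection = anova_select(train_std, cfg.anova_alpha)
            anova_selected[subject] = len(selection.selected)
            train_std = train_std.select_features(selection.selected)
            test_std = test_std.select_features(selection.selected)

        morning_reports: list[MetricsReport] = []
        subject_predictions: list = []

        def run_once(seed: int, _train=train_std, _test=test_std,
                     _morning=morning_reports,
                     _preds=subject_predictions) -> MetricsReport:
            spec = ClassifierSpec(family=cfg.classifier, seed=seed)
            model = train_classifier(spec, _train)
            predicted = predict(model, _test)
            _preds.append(predicted)
            report = compute_metrics(_test.labels, predicted, classes)
            report.itr = wolpaw_itr(report.overall_accuracy / 100.0,
                                    len(classes), cfg.selection_seconds)
            _morning.append(compute_metrics(
                _train.labels, predict(model, _train), classes))
            return report

        per_subject[subject] = repeat_and_average(
            run_once, cfg.n_repetitions, base_seed=cfg.seed)
        per_subject_morning[subject] = _average_reports(morning_reports, classes)
        predictions[subject] = subject_predictions

    average = _average_reports(list(per_subject.values()), classes)
    average.n_repetitions = cfg.n_repetitions
    average_morning = _average_reports(list(per_subject_morning.values()), classes)
    morning_acc = [average_morning.per_class_accuracy[c] for c in classes]
    evening_acc = [average.per_class_accuracy[c] for c in classes]
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        p = wilcoxon_exact(morning_acc, evening_acc)
    logger.info("stage 2: mean evening accuracy %.2f%% (coral=%s)",
                average.overall_accuracy, cfg.coral)
    return Stage2Result(
        per_subject=per_subject,
        per_subject_morning=per_subject_morning,
        average=average,
        average_morning=average_morning,
        anova_selected=anova_selected,
        wilcoxon_p=p,
        predictions=predictions,
    )


# --------------------------------------------------------------------------
# Full experiment
# --------------------------------------------------------------------------

def run_experiment(cfg: PipelineConfig, recordings=None) -> dict:
    """Simulate (unless given data), gate, decode, and report.

    Returns a JSON-serializable report with stage-1 and stage-2
    results under the configured CORAL setting.
    """
    cfg.validate()
    if recordings is None:
        recordings = simulate_recordings(cfg.sim)
    data = build_pipeline_data(cfg, recordings)
    stage1 = run_stage1(cfg, data)
    stage2 = run_stage2(cfg, data, stage1)
    return {
        "config": cfg.to_dict(),
        "stage1": stage1.to_dict(),
        "stage2": stage2.to_dict(),
    }
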