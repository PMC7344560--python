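"""End-to-end orchestration: filter -> window -> features -> model -> report.

One feature-table row per 10 s window: the ten statistical and six gait
features for each knee (32 columns), the window's label and provenance, and
a per-knee quality flag marking windows where too few gait events were
found (their gait features are zeros, never missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, modeling
from .evaluation import ConfusionMatrix, confusion
from .gait_features import GaitDetectorConfig, detect_strikes, gait_features
from .preprocess import DEFAULT_FOLD, FilterSpec, WindowSegment, lowpass_filter, segment_windows
from .signal_io import FEATURE_NAMES, FLAG_COLUMNS, META_COLUMNS, Cohort
from .simulate import VERTICAL_AXIS
from .stat_features import magnitude, stat_features

logger = logging.getLogger(__name__)


@dataclass
class FeaturizeConfig:
    """Everything the featurisation stage can tune."""

    filter_spec: FilterSpec | None = None  # None -> default for the recording fs
    fold: int = DEFAULT_FOLD
    leg_length_m: float = 0.9
    leg_length_by_subject: dict[str, float] = field(default_factory=dict)
    vertical_axis: int = VERTICAL_AXIS
    gait: GaitDetectorConfig = field(default_factory=GaitDetectorConfig)

    def leg_length(self, subject_id: str) -> float:
        return self.leg_length_by_subject.get(subject_id, self.leg_length_m)


def window_features(window: WindowSegment, cfg: FeaturizeConfig) -> dict:
    """The 32 named features (plus flags) for one left/right window pair."""
    row: dict = {
        "subject_id": window.subject_id,
        "course_id": window.course_id,
        "window_index": window.window_index,
        "label": window.label,
    }
    leg = cfg.leg_length(window.subject_id)
    for knee_name, block in (("Left", window.left), ("Right", window.right)):
        mag = magnitude(block)
        stats = stat_features(mag, block)
        events = detect_strikes(mag, window.fs, cfg.gait)
        gait = gait_features(events, block[:, cfg.vertical_axis], window.fs, leg)
        values = stats.as_tuple() + gait.as_tuple()
        names = FEATURE_NAMES[:16] if knee_name == "Left" else FEATURE_NAMES[16:]
        row.update(dict(zip(names, values)))
        row[f"Gait Flag ({knee_name} Knee)"] = int(gait.flagged)
    return row


def featurize_cohort(cohort: Cohort, cfg: FeaturizeConfig | None = None) -> pd.DataFrame:
    """Feature table for a whole cohort: one row per emitted window."""
    cfg = cfg or FeaturizeConfig()
    rows: list[dict] = []
    for subject_id, state in cohort.courses():
        left, right = cohort.knee_pair(subject_id, state)
        spec = cfg.filter_spec or FilterSpec(fs_hz=left.fs)
        left_f = lowpass_filter(left, spec)
        right_f = lowpass_filter(right, spec)
        windows = segment_windows(left_f, right_f, cfg.fold)
        rows.extend(window_features(w, cfg) for w in windows)
        logger.info("%s/%s: %d windows", subject_id, state, len(windows))
    if not rows:
        logger.warning("empty cohort: no windows emitted")
        return pd.DataFrame(columns=list(META_COLUMNS) + list(FEATURE_NAMES) + list(FLAG_COLUMNS))
    return pd.DataFrame(rows)


@dataclass
class SplitResult:
    """Outcome of one train/test evaluation."""

    cm: ConfusionMatrix
    report: evaluation.EvaluationReport
    auc: float | None
    auc_ci: tuple[float, float] | None
    model: modeling.PredictiveModel


def run_split(
    table: pd.DataFrame,
    family: str,
    seed: int = 0,
    mask: pd.Series | None = None,
    use_default_mask: bool = True,
) -> SplitResult:
    """Train on a subject-level 70:30 split and evaluate on the held-out 30%."""
    if mask is None and use_default_mask:
        mask = modeling.load_feature_mask(family)
    train, test = modeling.split_70_30(table, seed=seed)
    modeling.assert_no_subject_leakage(train, test)
    model = modeling.train_classifier(modeling.ClassifierSpec(family), mask, train, seed=seed)
    cm = confusion(test["label"].to_numpy(), model.predict(test))
    report = evaluation.metrics(cm)
    auc = ci = None
    labels = test["label"].to_numpy()
    if len(set(labels)) == 2:
        point, lo, hi = evaluation.roc_auc(model.score(test), labels, seed=seed)
        auc, ci = point, (lo, hi)
    return SplitResult(cm=cm, report=report, auc=auc, auc_ci=ci, model=model)


@dataclass
class LosoResult:
    """Per-subject confusion matrices from leave-one-subject-out CV."""

    per_subject: list[tuple[str, ConfusionMatrix]]
    fold_accuracies: list[float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def pooled(self) -> ConfusionMatrix:
        total = ConfusionMatrix(0, 0, 0, 0)
        for _, cm in self.per_subject:
            total = total + cm
        return total


def run_loso(
    table: pd.DataFrame,
    family: str,
    seed: int = 0,
    mask: pd.Series | None = None,
    use_default_mask: bool = True,
) -> LosoResult:
    """Leave-one-subject-out cross-validation of one classifier family."""
    if mask is None and use_default_mask:
        mask = modeling.load_feature_mask(family)
    per_subject = []
    accuracies = []
    for train, test in modeling.loso_folds(table):
        modeling.assert_no_subject_leakage(train, test)
        sid = str(test["subject_id"].iloc[0])
        model = modeling.train_classifier(
            modeling.ClassifierSpec(family), mask, train, seed=seed
        )
        cm = confusion(test["label"].to_numpy(), model.predict(test))
        per_subject.append((sid, cm))
        accuracies.append((cm.tp + cm.tn) / cm.total)
    return LosoResult(per_subject=per_subject, fold_accuracies=accuracies)


def loso_report(result: LosoResult, table: pd.DataFrame) -> pd.DataFrame:
    """Published-shaped per-subject report (confusion cells, counts, Total)."""
    counts = {}
    for (sid, state), group in table.groupby(["subject_id", "label"]):
        counts[(str(sid), state)] = len(group)
    items = []
    for sid, cm in result.per_subject:
        # report the raw sample counts implied by full windows; callers with
        # access to the cohort should prefer per_subject_report directly.
        items.append((sid, cm, cm.n_on * DEFAULT_FOLD, cm.n_off * DEFAULT_FOLD))
    return evaluation.per_subject_report(items)


@dataclass
class PredictionSummary:
    """Per-window calls plus the course-level majority call."""

    calls: list[str]
    scores: list[float]
    majority: str
    n_windows: int


def predict_course(
    model: modeling.PredictiveModel,
    left,
    right,
    cfg: FeaturizeConfig | None = None,
) -> PredictionSummary:
    """Per-window On/Off calls for one recording pair plus a majority summary.

    A pair too short to emit any window returns an explicit empty summary
    with majority "insufficient data".
    """
    cfg = cfg or FeaturizeConfig()
    spec = cfg.filter_spec or FilterSpec(fs_hz=left.fs)
    windows = segment_windows(lowpass_filter(left, spec), lowpass_filter(right, spec), cfg.fold)
    if not windows:
        return PredictionSummary(calls=[], scores=[], majority="insufficient data", n_windows=0)
    rows = pd.DataFrame([window_features(w, cfg) for w in windows])
    calls = [str(c) for c in model.predict(rows)]
    scores = [float(s) for s in model.score(rows)]
    n_on = sum(c == "on" for c in calls)
    majority = "on" if n_on * 2 >= len(calls) else "off"
    return PredictionSummary(calls=calls, scores=scores, majority=majority, n_windows=len(calls))
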