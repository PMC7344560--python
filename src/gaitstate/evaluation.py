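"""Confusion-matrix bookkeeping and the reported evaluation metrics.

The positive class is "On" (medication effect present) throughout. The
matrix follows the orientation of the published per-subject test table:
``fp`` counts true-On windows called Off and ``fn`` counts true-Off windows
called On, so ``tp + fp`` is the number of true-On windows and ``fn + tn``
the number of true-Off windows. All derived rates are computed from the
cells with exactly that convention; the diagnostic odds ratio applies the
Haldane-Anscombe +0.5 correction to every cell whenever any cell is zero.

The package ships the reference clinical study's per-subject confusion
cells and course lengths (a plain-text copy of its published leave-one-
subject-out test table) for regression checks on the windowing and
summation arithmetic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import window_count

POSITIVE = "on"
NEGATIVE = "off"


class LabelError(ValueError):
    """A label outside {on, off} was encountered."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion cells in the On-positive, published orientation."""

    tp: int  # true On, called On
    fp: int  # true On, called Off
    fn: int  # true Off, called On
    tn: int  # true Off, called Off

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def n_on(self) -> int:
        return self.tp + self.fp

    @property
    def n_off(self) -> int:
        return self.fn + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def confusion(true_labels: Sequence[str], predicted: Sequence[str]) -> ConfusionMatrix:
    """Count the confusion cells of per-window state calls."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted, dtype=object)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    seen = set(t) | set(p)
    if not seen <= {POSITIVE, NEGATIVE}:
        raise LabelError(f"unexpected label values: {sorted(seen - {POSITIVE, NEGATIVE})}")
    return ConfusionMatrix(
        tp=int(np.sum((t == POSITIVE) & (p == POSITIVE))),
        fp=int(np.sum((t == POSITIVE) & (p == NEGATIVE))),
        fn=int(np.sum((t == NEGATIVE) & (p == POSITIVE))),
        tn=int(np.sum((t == NEGATIVE) & (p == NEGATIVE))),
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Rates derived from one confusion matrix."""

    accuracy: float
    avg_recall: float
    avg_precision: float
    avg_f1: float
    specificity: float
    sensitivity: float
    ppv: float
    dor: float
    degenerate: bool = False  # some rate had an empty denominator (reported 0)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def metrics(cm: ConfusionMatrix) -> EvaluationReport:
    """All scalar rates from one confusion matrix.

    Average recall/precision/F1 are macro (unweighted two-class) means.
    Degenerate denominators yield 0 with the report flagged.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    degenerate = False

    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity, d1 = _safe_div(cm.tp, cm.tp + cm.fn)
    specificity, d2 = _safe_div(cm.tn, cm.tn + cm.fp)
    ppv, d3 = _safe_div(cm.tp, cm.tp + cm.fp)

    # per-class recall: correct calls over true-class support
    recall_on, d4 = _safe_div(cm.tp, cm.n_on)
    recall_off, d5 = _safe_div(cm.tn, cm.n_off)
    # per-class precision: correct calls over predicted-class support
    precision_on, d6 = _safe_div(cm.tp, cm.tp + cm.fn)
    precision_off, d7 = _safe_div(cm.tn, cm.tn + cm.fp)

    def f1(p: float, r: float) -> float:
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0

    avg_recall = (recall_on + recall_off) / 2
    avg_precision = (precision_on + precision_off) / 2
    avg_f1 = (f1(precision_on, recall_on) + f1(precision_off, recall_off)) / 2

    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    if min(tp, fp, fn, tn) == 0:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    dor = (tp * tn) / (fp * fn)

    degenerate = any((d1, d2, d3, d4, d5, d6, d7))
    return EvaluationReport(
        accuracy=accuracy,
        avg_recall=avg_recall,
        avg_precision=avg_precision,
        avg_f1=avg_f1,
        specificity=specificity,
        sensitivity=sensitivity,
        ppv=ppv,
        dor=dor,
        degenerate=degenerate,
    )


def roc_auc(
    scores: Sequence[float],
    true_labels: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Rank-based ROC-AUC with a percentile-bootstrap 95% CI.

    AUC is the probability that a random On window outscores a random Off
    window, ties counting one half (Mann-Whitney form). The CI resamples
    windows with replacement ``n_boot`` times at a fixed seed.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lab == POSITIVE else 0 for lab in true_labels])
    if y.min() == y.max():
        raise ValueError("ROC-AUC undefined: both classes must be present")

    def _auc(scores_: np.ndarray, y_: np.ndarray) -> float:
        from scipy.stats import rankdata

        ranks = rankdata(scores_)
        n_pos = int(y_.sum())
        n_neg = len(y_) - n_pos
        u = ranks[y_ == 1].sum() - n_pos * (n_pos + 1) / 2
        return float(u / (n_pos * n_neg))

    point = _auc(s, y)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(s), len(s))
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        boots.append(_auc(s[idx], yb))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, float(lo), float(hi)


REPORT_COLUMNS = (
    "subject_id",
    "tp",
    "fp",
    "fn",
    "tn",
    "on_samples",
    "off_samples",
    "on_windows",
    "off_windows",
)


def per_subject_report(
    results: Iterable[tuple[str, ConfusionMatrix, int, int]]
) -> pd.DataFrame:
    """Assemble the published-shaped per-subject table plus a Total row.

    Each item is (subject_id, confusion matrix, On-course sample count,
    Off-course sample count); window counts are recomputed from the sample
    counts with the fold rule and the Total row is the column-wise sum.
    """
    rows = []
    seen: set[str] = set()
    for sid, cm, n_on_samples, n_off_samples in results:
        if sid in seen:
            raise ValueError(f"duplicate subject in report: {sid!r}")
        seen.add(sid)
        rows.append(
            {
                "subject_id": sid,
                "tp": cm.tp,
                "fp": cm.fp,
                "fn": cm.fn,
                "tn": cm.tn,
                "on_samples": n_on_samples,
                "off_samples": n_off_samples,
                "on_windows": window_count(n_on_samples),
                "off_windows": window_count(n_off_samples),
            }
        )
    if not rows:
        raise ValueError("no per-subject results")
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    total = df.drop(columns="subject_id").sum()
    total["subject_id"] = "Total"
    return pd.concat([df, total.to_frame().T[list(REPORT_COLUMNS)]], ignore_index=True)


def load_reference_subject_table(include_total: bool = False) -> pd.DataFrame:
    """The reference study's published per-subject test table.

    Twenty rows of confusion cells, per-course sample counts and window
    counts, plus (optionally) the Total row exactly as printed. Note the
    printed Total row does not equal the column sums of the printed
    per-subject rows for tp (342 vs 343) and on_windows (373 vs 374); the
    per-subject rows are internally consistent (tp + fp always equals the
    On window count implied by the On sample count, likewise for Off).
    """
    ref = importlib.resources.files("gaitstate.data") / "reference_subject_table.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df["subject_id"] = df["subject_id"].astype(str)
    if not include_total:
        df = df[df["subject_id"] != "Total"].reset_index(drop=True)
        df = df.astype({c: int for c in df.columns if c != "subject_id"})
    return df
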