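"""Confusion bookkeeping, clinical metrics, ROC-AUC and per-subject reports."""

import numpy as np
import pandas as pd
import pytest

from gaitstate.evaluation import (
    ConfusionMatrix,
    LabelError,
    confusion,
    metrics,
    per_subject_report,
    roc_auc,
)


# --- confusion ------------------------------------------------------------

def test_confusion_perfect_and_all_on():
    true = ["on"] * 17 + ["off"] * 16
    cm = confusion(true, true)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (17, 0, 0, 16)
    cm2 = confusion(true, ["on"] * 33)
    assert (cm2.tp, cm2.fp, cm2.fn, cm2.tn) == (17, 0, 16, 0)
    assert cm2.n_on == 17 and cm2.n_off == 16


def test_confusion_rejects_unknown_labels():
    with pytest.raises(LabelError):
        confusion(["on", "off"], ["on", "maybe"])
    with pytest.raises(ValueError):
        confusion(["on"], ["on", "off"])


# --- metrics against a brute-force oracle ---------------------------------

def oracle_metrics(tp, fp, fn, tn):
    """Direct first-principles rates under the On-positive orientation."""
    total = tp + fp + fn + tn
    div = lambda a, b: a / b if b else 0.0
    acc = (tp + tn) / total
    sens = div(tp, tp + fn)
    spec = div(tn, tn + fp)
    ppv = div(tp, tp + fp)
    r_on, r_off = div(tp, tp + fp), div(tn, fn + tn)
    p_on, p_off = div(tp, tp + fn), div(tn, fp + tn)
    f1 = lambda p, r: 2 * p * r / (p + r) if p + r else 0.0
    cells = (tp, fp, fn, tn)
    if 0 in cells:
        tp, fp, fn, tn = (c + 0.5 for c in cells)
    dor = (tp * tn) / (fp * fn)
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "avg_recall": (r_on + r_off) / 2,
        "avg_precision": (p_on + p_off) / 2,
        "avg_f1": (f1(p_on, r_on) + f1(p_off, r_off)) / 2,
        "dor": dor,
    }


def test_metrics_match_bruteforce_on_random_matrices():
    rng = np.random.default_rng(7)
    for _ in range(200):
        tp, fp, fn, tn = (int(v) for v in rng.integers(0, 40, 4))
        if tp + fp + fn + tn == 0:
            continue
        rep = metrics(ConfusionMatrix(tp, fp, fn, tn))
        want = oracle_metrics(tp, fp, fn, tn)
        for key, expected in want.items():
            assert getattr(rep, key) == pytest.approx(expected, rel=1e-12), key


def test_metrics_on_pooled_reference_cells():
    """Summed per-subject cells: accuracy 685/743, sens 0.9268, spec 0.9171."""
    rep = metrics(ConfusionMatrix(342, 31, 27, 343))
    assert rep.accuracy == pytest.approx(685 / 743)
    assert rep.accuracy == pytest.approx(0.9219, abs=5e-4)
    assert rep.sensitivity == pytest.approx(342 / 369)
    assert rep.sensitivity == pytest.approx(0.9268, abs=5e-4)
    assert rep.specificity == pytest.approx(343 / 374)
    assert rep.specificity == pytest.approx(0.9171, abs=5e-4)


def test_dor_haldane_correction():
    rep = metrics(ConfusionMatrix(50, 0, 0, 50))
    assert rep.accuracy == 1.0
    assert rep.dor == pytest.approx((50.5 * 50.5) / 0.25)
    assert rep.dor == pytest.approx(10201.0)


def test_degenerate_matrix_flags():
    rep = metrics(ConfusionMatrix(0, 0, 0, 10))
    assert rep.sensitivity == 0.0
    assert rep.specificity == 1.0
    assert rep.degenerate
    with pytest.raises(ValueError):
        metrics(ConfusionMatrix(0, 0, 0, 0))


# --- ROC-AUC --------------------------------------------------------------

def exhaustive_auc(scores, labels):
    """Pairwise enumeration: P(on outscores off), ties half."""
    on = [s for s, l in zip(scores, labels) if l == "on"]
    off = [s for s, l in zip(scores, labels) if l == "off"]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in on for b in off)
    return wins / (len(on) * len(off))


def test_auc_worked_example():
    scores = [0.9, 0.8, 0.7, 0.85]
    labels = ["on", "on", "off", "off"]
    assert exhaustive_auc(scores, labels) == 0.75  # 3 of 4 concordant pairs
    point, lo, hi = roc_auc(scores, labels, n_boot=200, seed=0)
    assert point == pytest.approx(0.75)
    assert lo <= point <= hi


def test_auc_matches_exhaustive_and_sklearn_on_random_data():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(3)
    scores = rng.uniform(0, 1, 60)
    labels = ["on" if v else "off" for v in rng.integers(0, 2, 60)]
    point, _, _ = roc_auc(scores, labels, n_boot=50, seed=0)
    assert point == pytest.approx(exhaustive_auc(scores, labels), abs=1e-12)
    y = [1 if l == "on" else 0 for l in labels]
    assert point == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def test_auc_extremes_and_errors():
    labels = ["on"] * 10 + ["off"] * 10
    perfect = list(np.linspace(1, 0.6, 10)) + list(np.linspace(0.4, 0, 10))
    point, lo, hi = roc_auc(perfect, labels, n_boot=100, seed=1)
    assert point == 1.0
    rng = np.random.default_rng(12)
    noise, _, _ = roc_auc(rng.uniform(0, 1, 2000), ["on", "off"] * 1000, n_boot=10, seed=0)
    assert noise == pytest.approx(0.5, abs=0.05)
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], ["on", "on"])


# --- per-subject report ---------------------------------------------------

def test_reference_row_identities_hold(reference_table):
    """tp+fp equals the On window count and fn+tn the Off count, row by row."""
    for row in reference_table.itertuples():
        assert row.tp + row.fp == row.on_windows
        assert row.fn + row.tn == row.off_windows


def test_per_subject_report_totals(reference_table):
    items = [
        (row.subject_id, ConfusionMatrix(row.tp, row.fp, row.fn, row.tn),
         row.on_samples, row.off_samples)
        for row in reference_table.itertuples()
    ]
    report = per_subject_report(items)
    assert len(report) == 21
    total = report.iloc[-1]
    assert total["subject_id"] == "Total"
    # Total row is the column sum of the per-subject rows by construction
    body = report.iloc[:-1]
    for col in ("tp", "fp", "fn", "tn", "on_windows", "off_windows"):
        assert total[col] == body[col].sum()
    # window counts recomputed from sample counts match the published rows
    pd.testing.assert_series_equal(
        body["on_windows"].astype(int), reference_table["on_windows"], check_names=False
    )


def test_per_subject_report_single_and_duplicate():
    cm = ConfusionMatrix(15, 2, 1, 15)
    report = per_subject_report([("Subject 1", cm, 5370, 5217)])
    assert report.iloc[0]["on_windows"] == 17
    assert report.iloc[0]["off_windows"] == 16
    with pytest.raises(ValueError, match="duplicate"):
        per_subject_report([("a", cm, 320, 320), ("a", cm, 320, 320)])
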