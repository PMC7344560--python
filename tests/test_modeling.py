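"""Partitioning, feature selection, classifiers and Bayesian optimisation."""

import numpy as np
import pytest
from scipy.stats import norm

import gaitstate as gs
from gaitstate.modeling import (
    ClassifierSpec,
    SearchSpace,
    assert_no_subject_leakage,
    expected_improvement,
    incumbent_curve,
    load_feature_mask,
    loso_folds,
    rfe,
    smbo_optimize,
    split_70_30,
    train_classifier,
)
from gaitstate.signal_io import FEATURE_NAMES

from conftest import synthetic_feature_table


# --- partitioning ---------------------------------------------------------

def test_split_20_subjects_gives_14_6():
    table = synthetic_feature_table(n_subjects=20)
    train, test = split_70_30(table, seed=0)
    assert train["subject_id"].nunique() == 14
    assert test["subject_id"].nunique() == 6
    assert_no_subject_leakage(train, test)


def test_split_determinism_and_boundary():
    table = synthetic_feature_table(n_subjects=20)
    a = split_70_30(table, seed=5)
    b = split_70_30(table, seed=5)
    assert set(a[0]["subject_id"]) == set(b[0]["subject_id"])
    c = split_70_30(table, seed=6)
    assert set(a[0]["subject_id"]) != set(c[0]["subject_id"])

    tiny = synthetic_feature_table(n_subjects=2)
    train, test = split_70_30(tiny, seed=0)
    assert train["subject_id"].nunique() == 1
    assert test["subject_id"].nunique() == 1


def test_loso_folds_partition_the_table():
    table = synthetic_feature_table(n_subjects=20)
    folds = loso_folds(table)
    assert len(folds) == 20
    test_ids = []
    covered = 0
    for train, test in folds:
        assert_no_subject_leakage(train, test)
        assert test["subject_id"].nunique() == 1
        test_ids.append(test["subject_id"].iloc[0])
        covered += len(test)
    assert len(set(test_ids)) == 20
    assert covered == len(table)

    two = synthetic_feature_table(n_subjects=2)
    assert len(loso_folds(two)) == 2


def test_leakage_assertion_fires():
    table = synthetic_feature_table(n_subjects=4)
    with pytest.raises(AssertionError, match="leakage"):
        assert_no_subject_leakage(table, table)


# --- feature masks and RFE ------------------------------------------------

def test_packaged_masks_cover_all_features():
    for family in ("random_forest", "svm", "knn", "naive_bayes"):
        mask = load_feature_mask(family)
        assert list(mask.index) == list(FEATURE_NAMES)
        assert 1 <= mask.sum() <= 32


def test_random_forest_mask_keeps_22_features():
    assert load_feature_mask("random_forest").sum() == 22


def test_rfe_identity_at_full_width():
    table = synthetic_feature_table(n_subjects=4)
    mask = rfe(ClassifierSpec("naive_bayes"), table, n_keep=32)
    assert mask.all()


@pytest.mark.parametrize("family", ["random_forest", "knn"])
def test_rfe_finds_the_single_informative_feature(family):
    """Feature 1 alone determines the label; n_keep=1 must select it."""
    table = synthetic_feature_table(n_subjects=8, windows_per_course=8, seed=3)
    spec = ClassifierSpec(family, {"n_estimators": 50} if family == "random_forest" else {})
    mask = rfe(spec, table, n_keep=1, seed=0)
    assert mask.sum() == 1
    assert mask[FEATURE_NAMES[0]]


def test_rfe_bounds():
    table = synthetic_feature_table(n_subjects=4)
    with pytest.raises(ValueError):
        rfe(ClassifierSpec("knn"), table, n_keep=0)


# --- training -------------------------------------------------------------

def test_separable_table_trains_to_perfect_training_accuracy():
    table = synthetic_feature_table(n_subjects=6, seed=1)
    model = train_classifier(ClassifierSpec("random_forest"), None, table, seed=0)
    acc = np.mean(model.predict(table) == table["label"].to_numpy())
    assert acc == 1.0


def test_duplicated_features_do_not_break_training():
    table = synthetic_feature_table(n_subjects=4, seed=2)
    for name in FEATURE_NAMES[1:]:
        table[name] = table[FEATURE_NAMES[0]]
    for family in ("random_forest", "svm", "knn", "naive_bayes"):
        model = train_classifier(ClassifierSpec(family), None, table, seed=0)
        assert set(model.predict(table)) <= {"on", "off"}


def test_single_class_training_set_is_degenerate():
    table = synthetic_feature_table(n_subjects=4)
    table = table[table["label"] == "on"]
    with pytest.raises(ValueError, match="single class"):
        train_classifier(ClassifierSpec("naive_bayes"), None, table, seed=0)


def test_scores_are_probabilities_of_on(small_table):
    for family in ("random_forest", "svm", "knn", "naive_bayes"):
        model = train_classifier(ClassifierSpec(family), None, small_table, seed=0)
        scores = model.score(small_table)
        assert np.all((0 <= scores) & (scores <= 1))
        # high scores should align with "on" windows on separable data
        on_mean = scores[small_table["label"] == "on"].mean()
        off_mean = scores[small_table["label"] == "off"].mean()
        assert on_mean > off_mean


def test_published_hyperparameters_are_applied():
    spec = ClassifierSpec("random_forest")
    est = gs.modeling.build_estimator(spec, seed=0)
    assert est.n_estimators == 500
    assert est.max_depth == 8
    assert est.min_samples_split == 8
    assert est.min_samples_leaf == 10
    knn = gs.modeling.build_estimator(ClassifierSpec("knn"), seed=0)
    assert knn.n_neighbors == 50 and knn.leaf_size == 40 and knn.p == 2


# --- expected improvement and SMBO ---------------------------------------

def test_expected_improvement_closed_form():
    assert expected_improvement(0.5, 0.0, 0.7) == 0.0
    assert expected_improvement(0.9, 0.0, 0.7) == pytest.approx(0.2)
    # mu = f*, sigma = 1 -> phi(0)
    assert expected_improvement(1.0, 1.0, 1.0) == pytest.approx(norm.pdf(0.0), abs=1e-7)
    assert expected_improvement(1.0, 1.0, 1.0) == pytest.approx(0.3989423, abs=1e-6)
    with pytest.raises(ValueError):
        expected_improvement(0.0, -1.0, 0.0)


def test_expected_improvement_increases_with_sigma():
    sigmas = np.linspace(0.01, 2.0, 25)
    values = expected_improvement(np.full_like(sigmas, 0.3), sigmas, 0.5)
    assert np.all(np.diff(values) > 0)


def test_smbo_recovers_quadratic_maximum():
    argmax = 0.62

    def objective(params):
        x = params["x"]
        return 1.0 - (x - argmax) ** 2

    space = SearchSpace({"x": ("float", 0.0, 1.0)})
    best, trace = smbo_optimize(space, objective, n_init=8, n_iter=22, seed=0)
    assert len(trace) == 30
    assert best["x"] == pytest.approx(argmax, abs=0.05 * argmax)
    curve = incumbent_curve(trace)
    assert all(b >= a for a, b in zip(curve, curve[1:]))


def test_smbo_survives_objective_failures():
    calls = {"n": 0}

    def objective(params):
        calls["n"] += 1
        if calls["n"] % 3 == 0:
            raise RuntimeError("boom")
        return -((params["x"] - 0.5) ** 2)

    space = SearchSpace({"x": ("float", 0.0, 1.0)})
    best, trace = smbo_optimize(space, objective, n_init=4, n_iter=6, seed=1)
    assert len(trace) == 10
    assert any(t.failed for t in trace)
    worst = min(t.score for t in trace)
    assert all(t.score >= worst for t in trace)


def test_search_space_decoding():
    space = SearchSpace(
        {"a": ("float", -1.0, 1.0), "b": ("int", 2, 5), "c": ("choice", ["x", "y"])}
    )
    lo = space.decode(np.array([0.0, 0.0, 0.0]))
    hi = space.decode(np.array([0.999999, 0.999999, 0.999999]))
    assert lo == {"a": -1.0, "b": 2, "c": "x"}
    assert hi["a"] == pytest.approx(1.0, abs=1e-5)
    assert hi["b"] == 5 and hi["c"] == "y"
    with pytest.raises(ValueError):
        SearchSpace({"bad": ("float", 1.0, 0.0)})
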