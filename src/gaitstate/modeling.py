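"""Classifiers, feature selection, data partitioning and hyperparameter search.

Four classifier families are supported with the published default
hyperparameters frozen in :data:`DEFAULT_HYPERPARAMETERS`: a random forest
(500 trees, gini, depth 8), an RBF-kernel support vector machine, a
50-neighbour k-NN and Gaussian naive Bayes. Partitioning is always at the
subject level — both the 70:30 split and leave-one-subject-out
cross-validation keep every subject's windows on one side — so no window of
a test subject can leak into training.

Hyperparameter search is Bayesian sequential model-based optimisation: a
Gaussian-process surrogate (Matern 5/2) over the observed
(hyperparameters, score) pairs, with the next evaluation chosen by maximum
expected improvement EI(x) = E[max(f(x) - f*, 0)] over a random candidate
pool.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .evaluation import POSITIVE
from .signal_io import FEATURE_NAMES

logger = logging.getLogger(__name__)

FAMILIES = ("random_forest", "svm", "knn", "naive_bayes")

#: Published per-family hyperparameters, frozen as defaults.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "random_forest": {
        "n_estimators": 500,
        "criterion": "gini",
        "max_depth": 8,
        "min_samples_split": 8,
        "min_samples_leaf": 10,
    },
    "svm": {
        "kernel": "rbf",
        "degree": 3,
        "gamma": "auto",  # legacy alias "auto_deprecated" == 1/n_features
        "C": 1.0,
        "tol": 0.001,
        "cache_size": 200,
    },
    "knn": {
        "n_neighbors": 50,
        "weights": "uniform",
        "algorithm": "auto",
        "leaf_size": 40,
        "p": 2,
        "metric": "minkowski",
    },
    "naive_bayes": {},
}


@dataclass
class ClassifierSpec:
    """A classifier family plus its hyperparameter map."""

    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


def build_estimator(spec: ClassifierSpec, seed: int | None = 0):
    """Instantiate the scikit-learn estimator for a spec."""
    hp = spec.hyperparameters
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.family == "svm":
        return SVC(random_state=seed, **hp)
    if spec.family == "knn":
        return KNeighborsClassifier(**hp)
    return GaussianNB(**hp)


# ---------------------------------------------------------------------------
# feature masks

def load_feature_mask(family: str) -> pd.Series:
    """The packaged published used/removed mask for one family."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    ref = importlib.resources.files("gaitstate.data") / "feature_masks.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col="feature")
    mask = df[family].str.strip().eq("Used")
    mask = mask.reindex(FEATURE_NAMES)
    if mask.isna().any():
        raise ValueError("packaged mask does not cover all 32 features")
    return mask.astype(bool)


def identity_mask() -> pd.Series:
    return pd.Series(True, index=list(FEATURE_NAMES))


def _feature_matrix(table: pd.DataFrame, mask: pd.Series | None = None):
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns {missing[:3]}...")
    names = list(FEATURE_NAMES) if mask is None else [n for n in FEATURE_NAMES if mask[n]]
    X = table[names].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=object)
    return X, y, names


# ---------------------------------------------------------------------------
# partitioning

def subjects_of(table: pd.DataFrame) -> list[str]:
    return sorted(map(str, table["subject_id"].unique()))


def split_70_30(
    table: pd.DataFrame, seed: int = 0, train_fraction: float = 0.7
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level 70:30 split (14/6 subjects for a 20-subject cohort)."""
    sids = subjects_of(table)
    if len(sids) < 2:
        raise ValueError("need at least 2 subjects to split")
    n_train = int(round(train_fraction * len(sids)))
    n_train = min(max(n_train, 1), len(sids) - 1)
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(sids))
    train_sids = set(order[:n_train])
    is_train = table["subject_id"].astype(str).isin(train_sids)
    return table[is_train].reset_index(drop=True), table[~is_train].reset_index(drop=True)


def loso_folds(table: pd.DataFrame) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Leave-one-subject-out folds, one per subject, in subject order."""
    sids = subjects_of(table)
    if len(sids) < 2:
        raise ValueError("need at least 2 subjects for LOSO")
    folds = []
    sid_col = table["subject_id"].astype(str)
    for sid in sids:
        test = sid_col == sid
        folds.append(
            (table[~test].reset_index(drop=True), table[test].reset_index(drop=True))
        )
    return folds


def assert_no_subject_leakage(train: pd.DataFrame, test: pd.DataFrame) -> None:
    overlap = set(train["subject_id"].astype(str)) & set(test["subject_id"].astype(str))
    if overlap:
        raise AssertionError(f"subject leakage across the split: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# recursive feature elimination

def rfe(
    spec: ClassifierSpec,
    train: pd.DataFrame,
    n_keep: int | None = None,
    seed: int = 0,
) -> pd.Series:
    """Recursive feature elimination down to ``n_keep`` features.

    Estimators exposing importances/coefficients use proper RFE (refit after
    each single-feature removal). Families without a per-feature importance
    notion (the RBF-kernel SVM, k-NN, naive Bayes) fall back to a univariate
    ANOVA-F ranking, which is logged. Defaults ``n_keep`` to the size of the
    packaged published mask for the family, so recomputed masks are
    size-comparable.
    """
    if n_keep is None:
        n_keep = int(load_feature_mask(spec.family).sum())
    if not 1 <= n_keep <= len(FEATURE_NAMES):
        raise ValueError(f"n_keep must be in [1, {len(FEATURE_NAMES)}]")
    X, y, names = _feature_matrix(train)
    if n_keep == len(names):
        return identity_mask()
    estimator = build_estimator(spec, seed=seed)
    if hasattr(estimator, "feature_importances_") or hasattr(estimator, "coef_") or (
        spec.family == "random_forest"
    ):
        selector = RFE(estimator, n_features_to_select=n_keep, step=1)
        selector.fit(X, y)
        support = selector.support_
    else:
        logger.info(
            "%s has no per-feature importance; using univariate ANOVA-F ranking",
            spec.family,
        )
        f_scores, _ = f_classif(X, y)
        f_scores = np.nan_to_num(f_scores, nan=0.0)
        keep_idx = np.sort(np.argsort(f_scores)[::-1][:n_keep])
        support = np.zeros(len(names), dtype=bool)
        support[keep_idx] = True
    return pd.Series(support, index=names)


# ---------------------------------------------------------------------------
# training and prediction

class PredictiveModel:
    """A fitted binary state classifier over a masked feature set.

    ``predict`` returns per-window "on"/"off" calls; ``score`` returns the
    estimated probability of "on". For the SVM the score is the
    distance-to-margin passed through a Platt logistic map fitted on
    out-of-fold decision values of the training set.
    """

    def __init__(self, spec: ClassifierSpec, mask: pd.Series, estimator, calibrator=None):
        self.spec = spec
        self.mask = mask
        self.estimator = estimator
        self.calibrator = calibrator
        self.feature_names = [n for n in FEATURE_NAMES if mask[n]]

    def _X(self, table: pd.DataFrame) -> np.ndarray:
        X, _, _ = _feature_matrix(table, self.mask)
        return X

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._X(table)).astype(object)

    def score(self, table: pd.DataFrame) -> np.ndarray:
        X = self._X(table)
        if self.calibrator is not None:
            d = self.estimator.decision_function(X).reshape(-1, 1)
            return self.calibrator.predict_proba(d)[:, 1]
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(POSITIVE)
        return proba[:, pos]


def train_classifier(
    spec: ClassifierSpec,
    mask: pd.Series | None,
    train: pd.DataFrame,
    seed: int = 0,
) -> PredictiveModel:
    """Fit one classifier on the masked training windows."""
    mask = identity_mask() if mask is None else mask
    X, y, _ = _feature_matrix(train, mask)
    if len(X) == 0:
        raise ValueError("empty training table")
    classes = np.unique(y.astype(str))
    if len(classes) < 2:
        raise ValueError(f"degenerate fit: training set has a single class {classes}")
    estimator = build_estimator(spec, seed=seed)
    if spec.family == "knn" and estimator.n_neighbors > len(X):
        logger.info(
            "clamping n_neighbors from %d to the %d training windows",
            estimator.n_neighbors, len(X),
        )
        estimator.set_params(n_neighbors=len(X))
    estimator.fit(X, y)
    calibrator = None
    if spec.family == "svm":
        # Platt map on out-of-fold margins: the SVM's own predictions stay
        # untouched; only probability scores come from the logistic map.
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        d = cross_val_predict(
            build_estimator(spec, seed=seed), X, y, cv=cv, method="decision_function"
        ).reshape(-1, 1)
        y_bin = (y.astype(str) == POSITIVE).astype(int)
        calibrator = LogisticRegression(random_state=seed).fit(d, y_bin)
        if list(estimator.classes_) != sorted(estimator.classes_):
            raise RuntimeError("unexpected class ordering")
    return PredictiveModel(spec, mask, estimator, calibrator)


# ---------------------------------------------------------------------------
# Bayesian sequential model-based optimisation

def expected_improvement(
    mu: np.ndarray | float, sigma: np.ndarray | float, f_star: float
) -> np.ndarray | float:
    """Closed-form Gaussian expected improvement E[max(f(x) - f*, 0)].

    (mu - f*) * Phi(z) + sigma * phi(z) with z = (mu - f*) / sigma; for
    sigma = 0 it degenerates to max(mu - f*, 0).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    diff = mu - f_star
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, diff / np.where(sigma > 0, sigma, 1.0), 0.0)
        ei = np.where(
            sigma > 0,
            diff * norm.cdf(z) + sigma * norm.pdf(z),
            np.maximum(diff, 0.0),
        )
    return float(ei) if ei.ndim == 0 else ei


@dataclass
class SearchSpace:
    """Bounded hyperparameter search space.

    ``dimensions`` maps a name to ("float", lo, hi), ("int", lo, hi) or
    ("choice", [options]); everything is encoded into the unit cube for the
    surrogate.
    """

    dimensions: Mapping[str, tuple]

    def __post_init__(self) -> None:
        for name, dim in self.dimensions.items():
            kind = dim[0]
            if kind in ("float", "int"):
                _, lo, hi = dim
                if not lo < hi:
                    raise ValueError(f"{name}: bounds must satisfy lo < hi")
            elif kind == "choice":
                if not dim[1]:
                    raise ValueError(f"{name}: empty choice list")
            else:
                raise ValueError(f"{name}: unknown dimension kind {kind!r}")

    @property
    def n_dims(self) -> int:
        return len(self.dimensions)

    def decode(self, u: np.ndarray) -> dict:
        params = {}
        for value, (name, dim) in zip(u, self.dimensions.items()):
            kind = dim[0]
            if kind == "float":
                params[name] = dim[1] + value * (dim[2] - dim[1])
            elif kind == "int":
                lo, hi = dim[1], dim[2]
                params[name] = min(lo + math.floor(value * (hi - lo + 1)), hi)
            else:
                options = dim[1]
                params[name] = options[min(int(value * len(options)), len(options) - 1)]
        return params


@dataclass
class Trial:
    params: dict
    score: float
    failed: bool = False


def smbo_optimize(
    space: SearchSpace,
    objective: Callable[[dict], float],
    n_init: int = 8,
    n_iter: int = 22,
    seed: int = 0,
    pool_size: int = 1024,
) -> tuple[dict, list[Trial]]:
    """Maximise an objective by GP-surrogate search with expected improvement.

    ``n_init`` random evaluations seed the surrogate; each of the ``n_iter``
    rounds fits a Matern-5/2 Gaussian process to all observations and
    evaluates the EI-maximising point of a fresh random candidate pool.
    Returns the incumbent parameters and the full trial trace. An objective
    failure is recorded at the worst score observed so far and the search
    continues.
    """
    if n_init < 2:
        raise ValueError("n_init must be >= 2")
    rng = np.random.default_rng(seed)
    X_obs: list[np.ndarray] = []
    trace: list[Trial] = []

    def evaluate(u: np.ndarray) -> None:
        params = space.decode(u)
        try:
            score = float(objective(params))
            failed = False
        except Exception as exc:  # noqa: BLE001 - search must survive bad points
            logger.warning("objective failed at %s: %s", params, exc)
            score = min((t.score for t in trace), default=0.0)
            failed = True
        X_obs.append(u)
        trace.append(Trial(params=params, score=score, failed=failed))

    for _ in range(n_init):
        evaluate(rng.random(space.n_dims))

    kernel = ConstantKernel(1.0) * Matern(length_scale=0.25, nu=2.5) + WhiteKernel(
        noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1)
    )
    for _ in range(n_iter):
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, alpha=1e-8, random_state=seed
        )
        gp.fit(np.vstack(X_obs), np.array([t.score for t in trace]))
        f_star = max(t.score for t in trace)
        pool = rng.random((pool_size, space.n_dims))
        mu, sigma = gp.predict(pool, return_std=True)
        ei = expected_improvement(mu, sigma, f_star)
        evaluate(pool[int(np.argmax(ei))])

    best = max(trace, key=lambda t: t.score)
    return dict(best.params), trace


def incumbent_curve(trace: Sequence[Trial]) -> list[float]:
    """Best-so-far score after each trial (monotone non-decreasing)."""
    best = -np.inf
    curve = []
    for t in trace:
        best = max(best, t.score)
        curve.append(best)
    return curve
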