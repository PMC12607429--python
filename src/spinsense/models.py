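"""Heuristic baseline and the four supervised classifier families.

The heuristic classifies a window as a spin when its mean gyroscope
magnitude strictly exceeds a threshold.  The threshold is tuned on
training data only, by exhaustive search over the midpoints between
consecutive sorted distinct training magnitudes (plus -inf/+inf
sentinels), maximising spin-class F1; ties break toward the larger
threshold so the alarm is no more trigger-happy than it has to be.

The supervised families map to their scikit-learn estimators:

=========================================  =========================
family                                      estimator
=========================================  =========================
``random_forest``                           RandomForestClassifier
``svm``                                     SVC (RBF kernel, margin scores)
``naive_bayes``                             GaussianNB
``logistic_regression``                     LogisticRegression (L2)
=========================================  =========================

Features are z-scored with training-fitted statistics for the margin and
linear models only; tree ensembles and the Gaussian model take raw
features.  Hyperparameters default to widely used values (100 trees,
C=1 RBF, variance smoothing 1e-9, L2 with 1000 iterations) and are all
overridable; the originals behind the study's reported tables are not
published, so exact replication of those numbers is not a goal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ValidationError

logger = logging.getLogger("spinsense")

FAMILIES = ("random_forest", "svm", "naive_bayes", "logistic_regression")
_ALIASES = {
    "rf": "random_forest",
    "svm": "svm",
    "nb": "naive_bayes",
    "logreg": "logistic_regression",
    "randomized-tree-ensemble": "random_forest",
    "max-margin-kernel": "svm",
    "gaussian-conditional-independence": "naive_bayes",
    "regularized-linear-logodds": "logistic_regression",
}

#: Families whose inputs are z-scored with train-fitted statistics.
_STANDARDIZED = {"svm", "logistic_regression"}


def canonical_family(name: str) -> str:
    key = name.strip().lower()
    family = _ALIASES.get(key, key)
    if family not in FAMILIES:
        raise ValidationError(f"unknown classifier family {name!r}; choose from {FAMILIES}")
    return family


# ---------------------------------------------------------------------------
# Heuristic baseline
# ---------------------------------------------------------------------------

def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


@dataclass
class HeuristicModel:
    """Mean-gyro-magnitude threshold rule, tuned by grid search on F1."""

    threshold: float
    tuning_metric: str = "f1"
    tuning_grid: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, magnitudes: np.ndarray) -> np.ndarray:
        """1 (spin) iff mean gyro magnitude strictly exceeds the threshold."""
        return (np.asarray(magnitudes, dtype=float) > self.threshold).astype(int)

    def score(self, magnitudes: np.ndarray) -> np.ndarray:
        """Continuous score for ROC analysis: the magnitude itself."""
        return np.asarray(magnitudes, dtype=float)


def fit_heuristic(
    magnitudes: np.ndarray, labels: np.ndarray, metric: str = "f1"
) -> HeuristicModel:
    """Exhaustively tune the magnitude threshold on training data only.

    The candidate grid is every midpoint between consecutive sorted
    distinct training magnitudes, plus -inf/+inf sentinels; this covers
    every achievable decision rule of the form ``magnitude > t``.
    """
    if metric != "f1":
        raise ValidationError(f"unsupported tuning metric {metric!r}")
    mags = np.asarray(magnitudes, dtype=float)
    y = np.asarray(labels, dtype=int)
    if mags.shape != y.shape:
        raise ValidationError("magnitudes and labels must align")
    if len(np.unique(y)) < 2:
        raise ValidationError("heuristic tuning needs both classes in training data")
    distinct = np.unique(mags)
    if len(distinct) == 1:
        raise ValidationError(
            "training magnitudes are all identical; classes are inseparable "
            "by a magnitude threshold"
        )
    mids = (distinct[:-1] + distinct[1:]) / 2
    grid = np.concatenate(([-np.inf], mids, [np.inf]))
    best_thr = grid[0]
    best_score = -1.0
    for thr in grid:  # ascending: later >= candidates win ties -> larger threshold
        pred = mags > thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        score = _f1(tp, fp, fn)
        if score >= best_score:
            best_score = score
            best_thr = thr
    return HeuristicModel(threshold=float(best_thr), tuning_metric=metric, tuning_grid=grid)


def predict_heuristic(model: HeuristicModel, magnitudes: np.ndarray) -> np.ndarray:
    return model.predict(magnitudes)


# ---------------------------------------------------------------------------
# Supervised families
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """Family choice plus hyperparameter overrides and the fitting seed."""

    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    standardize_features: bool | None = None  # None -> family default
    seed: int = 0

    def __post_init__(self) -> None:
        self.family = canonical_family(self.family)

    @property
    def standardize(self) -> bool:
        if self.standardize_features is None:
            return self.family in _STANDARDIZED
        return bool(self.standardize_features)


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.family == "svm":
        hp.setdefault("kernel", "rbf")
        hp.setdefault("C", 1.0)
        return SVC(random_state=spec.seed, **hp)
    if spec.family == "naive_bayes":
        hp.setdefault("var_smoothing", 1e-9)
        return GaussianNB(**hp)
    if spec.family == "logistic_regression":
        # L2 with C=1 is the estimator default; only the budget is raised.
        hp.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=spec.seed, **hp)
    raise ValidationError(f"unknown family {spec.family!r}")  # pragma: no cover


@dataclass
class FittedClassifier:
    """Uniform predict/score facade over a fitted scikit-learn pipeline."""

    spec: ClassifierSpec
    pipeline: Pipeline
    feature_names: list[str]

    def _coerce(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.feature_names if n not in X.columns]
            if missing:
                raise ValidationError(f"prediction input lacks column(s) {missing}")
            return X[self.feature_names].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def predict(self, X) -> np.ndarray:
        return self.pipeline.predict(self._coerce(X)).astype(int)

    def score(self, X) -> np.ndarray:
        """Continuous spin score: positive-class probability where the
        estimator provides one, otherwise the decision-function margin."""
        arr = self._coerce(X)
        est = self.pipeline
        if hasattr(est, "predict_proba") and hasattr(est[-1], "predict_proba"):
            return est.predict_proba(arr)[:, 1]
        return est.decision_function(arr)


def fit_classifier(spec: ClassifierSpec, train, labels: np.ndarray) -> FittedClassifier:
    """Fit one supervised family on the (already selected) training matrix."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("classifier fitting needs both classes in training data")
    if isinstance(train, pd.DataFrame):
        names = list(train.columns)
        X = train.to_numpy(dtype=float)
    else:
        X = np.asarray(train, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    steps = []
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", _build_estimator(spec)))
    pipe = Pipeline(steps)
    pipe.fit(X, y)
    return FittedClassifier(spec=spec, pipeline=pipe, feature_names=names)
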