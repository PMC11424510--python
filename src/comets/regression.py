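"""Pluggable regression layer for covariance measure tests.

Both the GCM and PCM tests are algorithm-agnostic: they only require
estimates of conditional means such as E[Y | Z], E[X | Z] or E[Y | X, Z].
This module defines the contract those estimates are obtained through
(:class:`RegressorSpec` -> :func:`fit_regression` -> :class:`FittedRegressor`)
together with a small registry of built-in learners backed by scikit-learn:

``mean_only``
    The sample mean (the correct conditional mean when the features carry
    no information, and the fallback for an empty conditioning set).
``linear``
    Ordinary least squares; logistic regression for binary targets.
``lasso_cv``
    L1-penalised regression with the cross-validation-optimal penalty,
    suited to high-dimensional feature blocks.
``random_forest``
    Random forest with defaults mirroring the reference implementations
    these tests are typically run with (500 trees, mtry ~ sqrt(p), minimum
    node size 5), requiring essentially no tuning.

User code can register additional learners with :func:`register_learner`;
anything exposing the fit/predict surface used here (``predict_proba`` for
binary targets) plugs into both tests unchanged.
"""

from __future__ import annotations

import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Any, Callable, Iterator, Mapping

import numpy as np
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import (
    LassoCV,
    LinearRegression,
    LogisticRegression,
    LogisticRegressionCV,
)
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "RegressorSpec",
    "FittedRegressor",
    "ResidualSet",
    "fit_regression",
    "residualize",
    "register_learner",
    "available_learners",
    "count_regressions",
    "RegressionCounter",
]


class RegressionError(ValueError):
    """Raised for invalid regression inputs or unusable learner states."""


# ---------------------------------------------------------------------------
# learner registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable[["RegressorSpec", int], Any]] = {}


def register_learner(name: str, factory: Callable[["RegressorSpec", int], Any]) -> None:
    """Register a learner factory under ``name``.

    ``factory(spec, p)`` receives the spec and the number of feature columns
    and must return an unfitted estimator with ``fit(X, y)`` and ``predict``
    (plus ``predict_proba`` when ``spec.target_kind == "binary"``).
    """
    _REGISTRY[name] = factory


def available_learners() -> list[str]:
    return sorted(_REGISTRY)


def _make_mean_only(spec: "RegressorSpec", p: int) -> Any:
    return DummyRegressor(strategy="mean")


def _make_linear(spec: "RegressorSpec", p: int) -> Any:
    if spec.target_kind == "binary":
        return LogisticRegression(max_iter=1000, random_state=spec.seed)
    return LinearRegression()


def _make_lasso_cv(spec: "RegressorSpec", p: int) -> Any:
    folds = int(spec.hyperparameters.get("cv_folds", 10))
    if spec.target_kind == "binary":
        return LogisticRegressionCV(
            Cs=10,
            cv=folds,
            penalty="l1",
            solver="liblinear",
            max_iter=1000,
            random_state=spec.seed,
        )
    return LassoCV(cv=folds, random_state=spec.seed)


def _make_random_forest(spec: "RegressorSpec", p: int) -> Any:
    hp = spec.hyperparameters
    kwargs = dict(
        n_estimators=int(hp.get("n_trees", 500)),
        max_features="sqrt" if p > 1 else 1.0,
        random_state=spec.seed,
        n_jobs=1,
    )
    if spec.target_kind == "binary":
        return RandomForestClassifier(min_samples_leaf=int(hp.get("min_node_size", 10)), **kwargs)
    return RandomForestRegressor(min_samples_leaf=int(hp.get("min_node_size", 5)), **kwargs)


register_learner("mean_only", _make_mean_only)
register_learner("linear", _make_linear)
register_learner("lasso_cv", _make_lasso_cv)
register_learner("random_forest", _make_random_forest)


# ---------------------------------------------------------------------------
# specs and fitted state
# ---------------------------------------------------------------------------

_TARGET_KINDS = ("continuous", "binary")


@dataclass(frozen=True)
class RegressorSpec:
    """Declarative description of a conditional-mean learner.

    Parameters
    ----------
    method
        Name of a registered learner (``mean_only``, ``linear``, ``lasso_cv``,
        ``random_forest`` or user-registered).
    target_kind
        ``continuous`` or ``binary``. Binary targets must be coded in {0, 1};
        predictions are then probabilities in [0, 1].
    hyperparameters
        Learner-specific scalar overrides, e.g. ``{"n_trees": 100}`` or
        ``{"cv_folds": 5}``.
    seed
        Seed for any learner-internal randomness; fitting is deterministic
        given (data, spec, seed).
    """

    method: str
    target_kind: str = "continuous"
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _REGISTRY:
            raise RegressionError(
                f"unknown regression method {self.method!r}; "
                f"registered methods: {available_learners()}"
            )
        if self.target_kind not in _TARGET_KINDS:
            raise RegressionError(
                f"target_kind must be one of {_TARGET_KINDS}, got {self.target_kind!r}"
            )

    def replace(self, **changes: Any) -> "RegressorSpec":
        from dataclasses import replace as _replace

        return _replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "target_kind": self.target_kind,
            "hyperparameters": dict(self.hyperparameters),
            "seed": int(self.seed),
        }


@dataclass
class FittedRegressor:
    """A fitted conditional-mean estimator.

    ``predict`` returns estimates of E[target | features]; on the probability
    scale (clipped to [0, 1]) for binary targets.
    """

    spec: RegressorSpec
    n: int
    p: int
    model: Any

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = _as_feature_matrix(features)
        if X.shape[1] != self.p:
            raise RegressionError(
                f"feature dimension mismatch: fitted with p={self.p}, got {X.shape[1]}"
            )
        X = _pad_empty(X)
        if self.spec.target_kind == "binary" and hasattr(self.model, "predict_proba"):
            proba = self.model.predict_proba(X)
            classes = list(self.model.classes_)
            if 1 in classes:
                pred = proba[:, classes.index(1)]
            else:  # constant-zero training target
                pred = np.zeros(X.shape[0])
        else:
            pred = np.asarray(self.model.predict(X), dtype=float)
        if self.spec.target_kind == "binary":
            pred = np.clip(pred, 0.0, 1.0)
        if not np.all(np.isfinite(pred)):
            raise RegressionError("learner produced non-finite predictions")
        return pred


@dataclass
class ResidualSet:
    """Paired per-observation residuals entering a covariance-measure statistic.

    ``eps`` holds response residuals (Y minus its estimated conditional mean
    given Z); ``other`` holds the companion residuals — X-on-Z residuals for
    the GCM (one column per X coordinate) or projection residuals for the PCM.
    """

    eps: np.ndarray
    other: np.ndarray

    def __post_init__(self) -> None:
        self.eps = np.asarray(self.eps, dtype=float).ravel()
        self.other = np.asarray(self.other, dtype=float)
        n = self.eps.shape[0]
        if n < 2:
            raise RegressionError("residual sets need at least 2 observations")
        if self.other.shape[0] != n:
            raise RegressionError("eps and companion residuals differ in length")
        if not (np.all(np.isfinite(self.eps)) and np.all(np.isfinite(self.other))):
            raise RegressionError("residuals must be finite")

    @property
    def n(self) -> int:
        return self.eps.shape[0]


# ---------------------------------------------------------------------------
# regression-count instrumentation
# ---------------------------------------------------------------------------


class RegressionCounter:
    """Counts nuisance-regression fits performed inside its context."""

    def __init__(self) -> None:
        self.count = 0


_COUNTER_STACK: list[RegressionCounter] = []


@contextmanager
def count_regressions() -> Iterator[RegressionCounter]:
    """Count every :func:`fit_regression` call made inside the block.

    Used to compare the computational footprint of the two tests: the GCM
    needs d + 1 regressions for a d-dimensional X while the PCM's per-split
    count does not depend on d.
    """
    counter = RegressionCounter()
    _COUNTER_STACK.append(counter)
    try:
        yield counter
    finally:
        _COUNTER_STACK.pop()


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def _as_feature_matrix(features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    elif X.ndim != 2:
        raise RegressionError(f"features must be 1- or 2-dimensional, got ndim={X.ndim}")
    return X


def _pad_empty(X: np.ndarray) -> np.ndarray:
    # p = 0 (empty conditioning set): fit on a constant pseudo-feature so the
    # learner degrades to the marginal mean.
    if X.shape[1] == 0:
        return np.zeros((X.shape[0], 1))
    return X


def _validate(features: np.ndarray, targets: np.ndarray, spec: RegressorSpec) -> tuple[np.ndarray, np.ndarray]:
    X = _as_feature_matrix(features)
    y = np.asarray(targets, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise RegressionError(
            f"features ({X.shape[0]} rows) and targets ({y.shape[0]}) differ in length"
        )
    if X.shape[0] < 10:
        raise RegressionError("need at least 10 observations to fit a regression")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise RegressionError("missing data must be handled upstream")
    if spec.target_kind == "binary":
        vals = np.unique(y)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise RegressionError("binary targets must be coded in {0, 1}")
    return X, y


def fit_regression(
    features: np.ndarray, targets: np.ndarray, spec: RegressorSpec
) -> FittedRegressor:
    """Fit E[target | features] with the learner described by ``spec``.

    Degenerate cases: a constant target with ``lasso_cv`` (or a one-class
    binary target) falls back to ``mean_only`` with a logged warning, since
    cross-validated penalties are undefined there.
    """
    X, y = _validate(features, targets, spec)
    for counter in _COUNTER_STACK:
        counter.count += 1

    effective = spec
    constant_target = np.ptp(y) == 0.0
    if constant_target and spec.method in ("lasso_cv", "linear") and spec.target_kind == "binary":
        logger.warning("constant binary target; falling back to mean_only")
        effective = spec.replace(method="mean_only", target_kind="continuous")
    elif constant_target and spec.method == "lasso_cv":
        logger.warning("constant target with lasso_cv; falling back to mean_only")
        effective = spec.replace(method="mean_only")

    p = X.shape[1]
    model = _REGISTRY[effective.method](effective, max(p, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(_pad_empty(X), y)
    fitted = FittedRegressor(spec=effective, n=X.shape[0], p=p, model=model)
    # contract check: in-sample predictions must be finite
    fitted.predict(X)
    return fitted


def residualize(
    features: np.ndarray,
    targets: np.ndarray,
    spec: RegressorSpec,
    mode: str = "in_sample",
    n_folds: int = 5,
) -> np.ndarray:
    """Return targets minus estimated conditional means.

    ``in_sample`` fits once and predicts on the training rows (the default;
    the GCM as described needs no splitting). ``cross_fit_kfold`` predicts
    each observation from a model not trained on it, which removes the
    overfitting bias of flexible learners; fold assignment is deterministic
    given ``spec.seed``.
    """
    if mode == "in_sample":
        fitted = fit_regression(features, targets, spec)
        return np.asarray(targets, dtype=float).ravel() - fitted.predict(features)
    if mode != "cross_fit_kfold":
        raise RegressionError(f"unknown residualization mode {mode!r}")
    if n_folds < 2:
        raise RegressionError("cross_fit_kfold requires n_folds >= 2")
    X, y = _validate(features, targets, spec)
    resid = np.empty_like(y)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    for train_idx, test_idx in kf.split(X):
        fitted = fit_regression(X[train_idx], y[train_idx], spec)
        resid[test_idx] = y[test_idx] - fitted.predict(X[test_idx])
    return resid
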