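"""Base-learner library for the stacking ensemble.

Ten families spanning parametric (plain and interaction logistic regression,
sparsity-path "stepwise" selection, ridge-prior logistic as a Bayesian-GLM
analogue) and nonparametric learners (spline additive model, additive
stump boosting standing in for adaptive regression splines, gradient
boosting, random forest, linear and radial-kernel support vector machines).
Hyperparameters are fixed small grids/settings; anything can be overridden
per LearnerSpec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer
from sklearn.svm import SVC, LinearSVC

__all__ = ["LearnerSpec", "build_learner", "default_library", "compact_library"]


@dataclass(frozen=True)
class LearnerSpec:
    """Named base learner: family plus family-specific hyperparameters."""

    name: str
    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)


def _logistic(hp, seed):
    return LogisticRegression(penalty=None, max_iter=2000, **hp)


def _logistic_interactions(hp, seed):
    C = hp.pop("C", 1.0)
    return Pipeline([
        ("poly", PolynomialFeatures(degree=2, interaction_only=True, include_bias=False)),
        ("lr", LogisticRegression(C=C, max_iter=2000, **hp)),
    ])


def _stepwise_aic(hp, seed):
    # L1 regularization path with CV-selected strength approximates
    # stepwise variable selection
    return LogisticRegressionCV(
        penalty="l1", solver="liblinear", Cs=np.logspace(-2, 2, 7),
        cv=3, max_iter=1000, random_state=seed, **hp)


def _bayesian_glm(hp, seed):
    # ridge MAP = Gaussian coefficient prior
    return LogisticRegression(C=hp.pop("C", 1.0), max_iter=2000, **hp)


def _gam(hp, seed):
    return Pipeline([
        ("spline", SplineTransformer(n_knots=hp.pop("n_knots", 4), degree=3)),
        ("lr", LogisticRegression(C=hp.pop("C", 1.0), max_iter=2000, **hp)),
    ])


def _mars(hp, seed):
    # additive stump boosting: piecewise-constant additive fit in the
    # spirit of adaptive regression splines
    return GradientBoostingClassifier(
        max_depth=1, n_estimators=hp.pop("n_estimators", 200),
        learning_rate=hp.pop("learning_rate", 0.1), random_state=seed, **hp)


def _gradient_boosting(hp, seed):
    return HistGradientBoostingClassifier(
        max_iter=hp.pop("max_iter", 200), learning_rate=hp.pop("learning_rate", 0.1),
        max_leaf_nodes=hp.pop("max_leaf_nodes", 31), early_stopping=False,
        random_state=seed, **hp)


def _random_forest(hp, seed):
    return RandomForestClassifier(
        n_estimators=hp.pop("n_estimators", 300),
        min_samples_leaf=hp.pop("min_samples_leaf", 5),
        random_state=seed, n_jobs=1, **hp)


def _svm(hp, seed):
    base = LinearSVC(C=hp.pop("C", 0.5), max_iter=5000, random_state=seed, **hp)
    return CalibratedClassifierCV(base, cv=3, method="sigmoid")


def _kernel_svm(hp, seed):
    return SVC(kernel="rbf", C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "scale"),
               probability=True, random_state=seed, **hp)


_FAMILIES = {
    "logistic": _logistic,
    "logistic-with-interactions": _logistic_interactions,
    "stepwise-AIC": _stepwise_aic,
    "bayesian-glm": _bayesian_glm,
    "gam": _gam,
    "mars": _mars,
    "gradient-boosting": _gradient_boosting,
    "random-forest": _random_forest,
    "svm": _svm,
    "kernel-svm": _kernel_svm,
}


def build_learner(spec: LearnerSpec, seed: int | None = None):
    """Instantiate the sklearn estimator behind a LearnerSpec."""
    if spec.family not in _FAMILIES:
        raise ValueError(f"unknown learner family {spec.family!r}; "
                         f"known: {sorted(_FAMILIES)}")
    return _FAMILIES[spec.family](dict(spec.hyperparameters), seed)


def default_library() -> tuple[LearnerSpec, ...]:
    """Full ten-family library."""
    return tuple(LearnerSpec(fam, fam) for fam in _FAMILIES)


def compact_library() -> tuple[LearnerSpec, ...]:
    """Small fast library (parametric + two tree ensembles) for simulations."""
    return (
        LearnerSpec("logistic", "logistic"),
        LearnerSpec("logistic-with-interactions", "logistic-with-interactions"),
        LearnerSpec("gradient-boosting", "gradient-boosting",
                    {"max_iter": 100, "max_leaf_nodes": 15}),
        LearnerSpec("random-forest", "random-forest", {"n_estimators": 150}),
    )
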