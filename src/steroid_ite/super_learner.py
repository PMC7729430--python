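"""Cross-validated stacking ensemble ("optimal individual model").

A Super Learner for 90-day (or 28-day) mortality given baseline covariates,
missingness indicators, trial, and the treatment actually received.  The
ensemble is built in two stages:

1. *honest level-1 matrix* — every base learner is refit within each of K
   stratified folds and predicts only its held-out fold, so row i of the
   level-1 matrix never depends on outcome i;
2. *metalearner* — a convex weight vector over the level-1 columns chosen to
   maximize the cross-validated AUC of the combined score (the AUC surface is
   piecewise constant, so the search is direct: simplex vertices, the uniform
   mixture, and multistart Nelder-Mead on softmax-parameterized weights).

Because the simplex vertices are always candidates, the ensemble's CV-AUC can
never fall below the best single learner's.  Discrete selection (all weight
on the single best column) is available as ``meta="discrete"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .cohort import TrialCohort
from .evaluation import roc_auc
from .features import FeatureMap
from .learners import LearnerSpec, build_learner, default_library

__all__ = [
    "CrossValidationPlan", "SuperLearnerClassifier", "FittedSuperLearner",
    "optimize_weights", "fit_super_learner", "predict_risk",
]

_CLIP = 1e-3


@dataclass(frozen=True)
class CrossValidationPlan:
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def optimize_weights(level1: np.ndarray, y: np.ndarray, seed: int = 0,
                     n_random_starts: int = 3) -> np.ndarray:
    """Simplex weights maximizing AUC(level1 @ w, y).

    Candidates are evaluated in a fixed order — uniform mixture, simplex
    vertices in column order, Nelder-Mead refinements, random restarts — and
    the first candidate attaining the maximum AUC (within 1e-10) wins, making
    tie-breaking deterministic.  Duplicate columns are merged before the
    search and the merged weight is assigned to the first occurrence, so a
    duplicated learner never changes the ensemble prediction.
    """
    level1 = np.asarray(level1, dtype=float)
    y = np.asarray(y)
    if level1.ndim != 2 or level1.shape[1] < 1:
        raise ValueError("level1 must be a 2-D matrix with >= 1 column")
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant; AUC is undefined")
    n, L = level1.shape
    if L == 1:
        return np.array([1.0])

    # merge exactly-duplicated columns and drop constant ones: a duplicate's
    # weight split is irrelevant and a constant shifts every score equally,
    # so neither can change any ranking
    uniq_idx: list[int] = []
    for j in range(L):
        if any(np.array_equal(level1[:, j], level1[:, k]) for k in uniq_idx):
            continue
        if np.ptp(level1[:, j]) == 0:
            continue
        uniq_idx.append(j)
    if not uniq_idx:  # every column constant: AUC is 0.5 regardless
        w = np.zeros(L)
        w[0] = 1.0
        return w
    Z = level1[:, uniq_idx]
    m = Z.shape[1]
    if m == 1:
        w = np.zeros(L)
        w[uniq_idx[0]] = 1.0
        return w

    def score(w: np.ndarray) -> float:
        return roc_auc(Z @ w, y)

    candidates: list[np.ndarray] = [np.full(m, 1.0 / m)]
    for j in range(m):
        v = np.zeros(m)
        v[j] = 1.0
        candidates.append(v)
    candidates.extend(_simplex_grid(m))

    rng = np.random.default_rng(seed)
    starts = [np.zeros(m)] + [5.0 * v for v in candidates[1:m + 1]]
    starts += [rng.normal(size=m) for _ in range(n_random_starts)]
    aucs = [score(w) for w in candidates]
    best_so_far = candidates[int(np.argmax(aucs))]
    starts.append(np.log(np.clip(best_so_far, 1e-6, None)))
    for z0 in starts:
        res = minimize(lambda z: -score(softmax(z)), z0, method="Nelder-Mead",
                       options={"maxiter": 200 * m, "xatol": 1e-4, "fatol": 1e-10})
        candidates.append(softmax(res.x))
        aucs.append(score(candidates[-1]))

    best = max(aucs)
    w_small = next(w for w, a in zip(candidates, aucs) if a >= best - 1e-10)

    w = np.zeros(L)
    for j_small, j_orig in enumerate(uniq_idx):
        w[j_orig] = w_small[j_small]
    return w / w.sum()


def _simplex_grid(m: int) -> list[np.ndarray]:
    """Deterministic coarse grid on the weight simplex (small libraries only);
    the AUC surface is piecewise constant, so a grid scan anchors the direct
    search away from poor local plateaus."""
    steps = {2: 100, 3: 20, 4: 10, 5: 6}.get(m)
    if steps is None:
        return []
    from itertools import combinations_with_replacement

    out = []
    for combo in combinations_with_replacement(range(m), steps):
        w = np.bincount(combo, minlength=m) / steps
        out.append(w)
    return out


class SuperLearnerClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style Super Learner for binary outcomes.

    Parameters
    ----------
    library : sequence of LearnerSpec, optional
        Base-learner library; defaults to the full ten-family library.
    n_folds, stratified : cross-validation plan for the level-1 matrix.
    meta : {"convex", "discrete"}
        Convex AUC-maximizing combination (default) or discrete selection of
        the single best column.
    clip : float
        Ensemble probabilities are clipped to [clip, 1-clip] for downstream
        logit stability.
    """

    def __init__(self, library: Sequence[LearnerSpec] | None = None,
                 n_folds: int = 10, stratified: bool = True,
                 meta: str = "convex", clip: float = _CLIP,
                 random_state: int | None = 0):
        self.library = library
        self.n_folds = n_folds
        self.stratified = stratified
        self.meta = meta
        self.clip = clip
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("SuperLearnerClassifier requires exactly 2 classes")
        y01 = (y == self.classes_[1]).astype(int)
        library = tuple(self.library) if self.library is not None else default_library()
        if len(library) == 0:
            raise ValueError("learner library must be nonempty")
        names = [s.name for s in library]
        if len(set(names)) != len(names):
            raise ValueError("learner names must be unique within a library")

        seed = 0 if self.random_state is None else int(self.random_state)
        splitter_cls = StratifiedKFold if self.stratified else KFold
        folds = list(splitter_cls(n_splits=self.n_folds, shuffle=True,
                                  random_state=seed).split(X, y01))

        level1 = np.full((len(y01), len(library)), np.nan)
        ok = np.ones(len(library), dtype=bool)
        for j, spec in enumerate(library):
            try:
                for tr, te in folds:
                    est = build_learner(spec, seed)
                    est.fit(X[tr], y01[tr])
                    level1[te, j] = est.predict_proba(X[te])[:, 1]
            except Exception as exc:  # noqa: BLE001 — any learner failure drops it
                warnings.warn(f"learner {spec.name!r} failed during CV and was "
                              f"dropped: {exc}")
                ok[j] = False

        fitted = []
        for j, spec in enumerate(library):
            if not ok[j]:
                fitted.append(None)
                continue
            try:
                est = build_learner(spec, seed)
                est.fit(X, y01)
                fitted.append(est)
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"learner {spec.name!r} failed on the full data "
                              f"and was dropped: {exc}")
                ok[j] = False
                fitted.append(None)
        if not ok.any():
            raise RuntimeError("every learner in the library failed to fit")

        keep = np.flatnonzero(ok)
        level1 = level1[:, keep]
        self.learner_specs_ = tuple(library[j] for j in keep)
        self.learner_names_ = tuple(names[j] for j in keep)
        self.learners_ = [fitted[j] for j in keep]
        self.level1_ = level1
        if self.meta == "discrete":
            col_aucs = [roc_auc(level1[:, j], y01) for j in range(level1.shape[1])]
            w = np.zeros(level1.shape[1])
            w[int(np.argmax(col_aucs))] = 1.0
            self.weights_ = w
        elif self.meta == "convex":
            self.weights_ = optimize_weights(level1, y01, seed=seed)
        else:
            raise ValueError(f"unknown meta {self.meta!r}")
        self.cv_auc_ = roc_auc(level1 @ self.weights_, y01)
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        p = np.zeros(X.shape[0])
        for w, est in zip(self.weights_, self.learners_):
            if w > 0:
                p += w * est.predict_proba(X)[:, 1]
        p = np.clip(p, self.clip, 1.0 - self.clip)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


@dataclass
class FittedSuperLearner:
    """A Super Learner fit bound to its cohort feature encoding."""

    feature_map: FeatureMap
    model: SuperLearnerClassifier
    outcome: str

    @property
    def weights(self) -> np.ndarray:
        return self.model.weights_

    @property
    def learner_names(self) -> tuple[str, ...]:
        return self.model.learner_names_

    @property
    def level1(self) -> np.ndarray:
        return self.model.level1_

    @property
    def cv_auc(self) -> float:
        return self.model.cv_auc_


def fit_super_learner(cohort: TrialCohort, outcome: str = "y90",
                      library: Sequence[LearnerSpec] | None = None,
                      plan: CrossValidationPlan | None = None,
                      meta: str = "convex") -> FittedSuperLearner:
    """Fit the optimal individual model on a cohort.

    Treatment received enters the design as a categorical feature with
    treatment x severity and treatment x cortisol-increment interaction
    columns, so counterfactual per-arm risks are available from
    :func:`predict_risk`.
    """
    plan = plan or CrossValidationPlan()
    if outcome not in ("y90", "y28"):
        raise ValueError("outcome must be 'y90' or 'y28'")
    fm = FeatureMap().fit(cohort)
    X = fm.transform(cohort)
    y = cohort.data[outcome].to_numpy(dtype=int)
    model = SuperLearnerClassifier(library=library, n_folds=plan.n_folds,
                                   stratified=plan.stratified, meta=meta,
                                   random_state=plan.seed)
    model.fit(X, y)
    return FittedSuperLearner(fm, model, outcome)


def predict_risk(fsl: FittedSuperLearner, records: TrialCohort | pd.DataFrame,
                 arm_override: str | None = None) -> np.ndarray:
    """Predicted event probability per record, optionally under a
    counterfactual arm (the treatment feature is overridden for every row)."""
    if not fsl.feature_map.include_treatment and arm_override is not None:
        raise ValueError("model was fitted without the treatment feature")
    X = fsl.feature_map.transform(records, arm_override=arm_override)
    return fsl.model.predict_proba(X)[:, 1]
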