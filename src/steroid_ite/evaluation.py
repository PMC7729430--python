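"""Discrimination and calibration metrics for mortality risk models.

AUC with the DeLong nonparametric variance, pooled cross-validated AUC,
Brier score, and an equal-frequency calibration table with Wilson intervals
plus a lowess smooth for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AucEstimate", "EvaluationReport",
    "roc_auc", "delong_auc_ci", "cross_validated_auc",
    "brier_score", "calibration_curve", "evaluate_model",
]


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    se: float
    ci: tuple[float, float]


@dataclass
class EvaluationReport:
    """Bundle of discrimination/calibration metrics for one risk model."""

    auc: AucEstimate
    brier: float
    calibration: pd.DataFrame
    cv_auc: AucEstimate | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "auc": self.auc.auc, "auc_ci": list(self.auc.ci),
            "brier": self.brier,
            "calibration": self.calibration.to_dict(orient="records"),
        }
        if self.cv_auc is not None:
            out["cv_auc"] = self.cv_auc.auc
            out["cv_auc_ci"] = list(self.cv_auc.ci)
        out.update(self.extras)
        return out


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if not np.isin(classes, [0, 1]).all():
        raise ValueError("outcome must be coded 0/1")
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")
    return y.astype(int)


def roc_auc(scores, y) -> float:
    """Mann-Whitney AUC with ties counted one half."""
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placements(xs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """For each x, fraction of ``ref`` below it, ties counted one half."""
    ref_sorted = np.sort(ref)
    lo = np.searchsorted(ref_sorted, xs, side="left")
    hi = np.searchsorted(ref_sorted, xs, side="right")
    return (lo + 0.5 * (hi - lo)) / ref.size


def delong_auc_ci(scores, y, alpha: float = 0.05) -> AucEstimate:
    """AUC and a Wald CI with the DeLong structural-component variance."""
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[y == 1], scores[y == 0]
    v10 = _placements(pos, neg)   # P(pos > neg) per case
    v01 = 1.0 - _placements(neg, pos)
    auc = float(v10.mean())
    if pos.size > 1 and neg.size > 1:
        var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    else:
        var = np.nan
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (float(np.clip(auc - z * se, 0, 1)), float(np.clip(auc + z * se, 0, 1)))
    return AucEstimate(auc, se, ci)


def cross_validated_auc(model, X, y, n_folds: int = 10, stratified: bool = True,
                        seed: int = 0) -> tuple[AucEstimate, np.ndarray]:
    """Pooled out-of-fold AUC of an (unfitted) probabilistic classifier.

    Out-of-fold predictions from every fold are pooled into a single vector
    and one DeLong interval is reported on it.  Folds that would lose an
    outcome class are avoided by stratification.
    """
    y = _check_binary(y)
    X = np.asarray(X)
    stratifiable = min(np.bincount(y)) >= n_folds
    if not stratified and not stratifiable and n_folds < y.size:
        warnings.warn("refolding with stratification is infeasible at this "
                      "fold count; using plain folds")
    use_strat = stratified and stratifiable
    splitter = (StratifiedKFold if use_strat else KFold)(
        n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X, y))
    if not use_strat and any(np.unique(y[tr]).size < 2 for tr, _ in splits) \
            and stratifiable:
        warnings.warn("refolding with stratification to keep both classes "
                      "in every training fold")
        splits = list(StratifiedKFold(n_splits=n_folds, shuffle=True,
                                      random_state=seed).split(X, y))
    oof = np.full(y.size, np.nan)
    for tr, te in splits:
        est = clone(model)
        est.fit(X[tr], y[tr])
        oof[te] = est.predict_proba(X[te])[:, 1]
    return delong_auc_ci(oof, y), oof


def brier_score(scores, y) -> float:
    """Mean squared difference between predicted probability and outcome."""
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must be probabilities in [0,1]")
    y = np.asarray(y, dtype=float)
    return float(np.mean((scores - y) ** 2))


def calibration_curve(scores, y, bins: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """Equal-frequency calibration table.

    Returns one row per bin of predicted risk: mean prediction, observed
    prevalence with a Wilson interval, and the bin count.  Constant scores
    collapse to a single bin with a warning.
    """
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y.size < bins:
        raise ValueError("need at least as many observations as bins")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: single calibration bin")
        assignments = pd.Series(np.zeros(y.size, dtype=int))
    else:
        assignments = pd.qcut(pd.Series(scores).rank(method="first"), q=bins,
                              labels=False, duplicates="drop")
    rows = []
    for _, idx in pd.Series(np.arange(y.size)).groupby(assignments):
        s, o = scores[idx], y[idx]
        lo, hi = proportion_confint(o.sum(), o.size, alpha=alpha, method="wilson")
        rows.append({"pred_mean": s.mean(), "observed": o.mean(),
                     "count": int(o.size), "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def calibration_smooth(scores, y, frac: float = 0.5) -> pd.DataFrame:
    sm = lowess(np.asarray(y, float), np.asarray(scores, float), frac=frac)
    return pd.DataFrame(sm, columns=["pred", "observed_smooth"])


def evaluate_model(scores, y, cv_auc: AucEstimate | None = None,
                   bins: int = 10) -> EvaluationReport:
    """One-call evaluation: DeLong AUC, Brier score, calibration table."""
    return EvaluationReport(
        auc=delong_auc_ci(scores, y),
        brier=brier_score(scores, y),
        calibration=calibration_curve(scores, y, bins=bins),
        cv_auc=cv_auc,
    )
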