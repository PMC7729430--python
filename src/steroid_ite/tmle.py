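"""Targeted maximum likelihood estimation of the average treatment effect.

For a binary outcome and a two-group contrast, TMLE takes an initial
machine-learning fit of P(Y=1 | A, W), fluctuates it along a one-dimensional
logistic submodel whose covariate is the inverse-propensity "clever
covariate"

    H(A, W) = A / g(W) - (1 - A) / (1 - g(W)),

with the initial fit entering as an offset, and reads the absolute risk
reduction (ARR = psi0 - psi1) and relative risk (RR = psi1 / psi0) off the
targeted counterfactual mean outcomes.  The fluctuation MLE solves the
efficient-score equation, so the efficient influence curve has mean zero and
supplies the variance; the RR interval is Wald on the log scale.

In randomized cohorts the propensity g is the (per-trial) randomization
probability; an estimated-g option exists for observational use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression

from .cohort import ACTIVE_ARMS, ARMS, CONTROL, TrialCohort
from .features import FeatureMap

__all__ = [
    "ANY_STEROID", "PropensityModel", "TargetedEstimate",
    "tmle_ate", "tmle_from_cohort", "pooled_and_per_trial",
]

ANY_STEROID = "any_steroid"
_QCLIP = 1e-3


class PositivityError(RuntimeError):
    """Propensity too extreme even after truncation; review positivity."""


@dataclass
class PropensityModel:
    """Treatment-probability model for a two-group contrast.

    kind="empirical" uses per-trial observed treated fractions (the natural
    choice when randomization probabilities are known but unrecorded);
    kind="known" takes per-trial probabilities; kind="estimated" fits a
    logistic regression of treatment on the encoded covariates.
    """

    kind: str = "empirical"
    probabilities: Mapping[str, float] | None = None
    truncation: tuple[float, float] = (0.01, 0.99)

    def treated_probability(self, cohort: TrialCohort, treated: np.ndarray) -> np.ndarray:
        df = cohort.data
        if self.kind == "empirical":
            g = df.groupby("trial")["trial"].transform(
                lambda s: treated[s.index].mean())
            g = g.to_numpy(dtype=float)
        elif self.kind == "known":
            if self.probabilities is None:
                raise ValueError("known propensity requires probabilities")
            g = df["trial"].map(dict(self.probabilities)).to_numpy(dtype=float)
            if np.any(~np.isfinite(g)):
                raise ValueError("probabilities missing for some trial")
        elif self.kind == "estimated":
            fm = FeatureMap(include_treatment=False).fit(cohort)
            X = fm.transform(cohort)
            g = LogisticRegression(max_iter=2000).fit(X, treated).predict_proba(X)[:, 1]
        else:
            raise ValueError(f"unknown propensity kind {self.kind!r}")
        lo, hi = self.truncation
        if np.any((g <= 0) | (g >= 1)):
            raise PositivityError("propensity 0 or 1 in some stratum; review positivity")
        return np.clip(g, lo, hi)


@dataclass
class TargetedEstimate:
    """TMLE result for one arm contrast."""

    contrast: tuple[str, str]
    mean1: float
    mean0: float
    arr: float
    rr: float
    ci_arr: tuple[float, float]
    ci_rr: tuple[float, float]
    p_value: float           # two-sided Wald on log RR
    p_value_arr: float       # two-sided Wald on the risk difference
    epsilon: float
    ic: np.ndarray = field(repr=False)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "contrast": list(self.contrast), "n": self.n,
            "mean_treated": self.mean1, "mean_control": self.mean0,
            "rr": self.rr, "rr_ci": list(self.ci_rr), "p_value": self.p_value,
            "arr": self.arr, "arr_ci": list(self.ci_arr),
            "p_value_arr": self.p_value_arr,
        }


def _fluctuate(y: np.ndarray, h: np.ndarray, offset: np.ndarray) -> float:
    try:
        res = sm.GLM(y, h[:, None], family=sm.families.Binomial(),
                     offset=offset).fit(tol=1e-12, maxiter=200)
        eps = float(res.params[0])
        if not np.isfinite(eps):
            raise ValueError("non-finite epsilon")
    except Exception as exc:  # noqa: BLE001
        warnings.warn(f"fluctuation failed ({exc}); epsilon set to 0")
        eps = 0.0
    return eps


def tmle_ate(y, a, q0, q1, g1, contrast: tuple[str, str] = ("treated", "control"),
             alpha: float = 0.05) -> TargetedEstimate:
    """TMLE for the risk difference and relative risk of a binary contrast.

    Parameters are plain arrays: outcome ``y`` (0/1), treated indicator
    ``a`` (0/1), initial counterfactual risk predictions ``q0``/``q1`` in
    (0,1), and the treated-probability vector ``g1`` (already truncated).
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    q0 = np.clip(np.asarray(q0, dtype=float), _QCLIP, 1 - _QCLIP)
    q1 = np.clip(np.asarray(q1, dtype=float), _QCLIP, 1 - _QCLIP)
    g1 = np.asarray(g1, dtype=float)
    if np.any((g1 < 0.01 - 1e-12) | (g1 > 0.99 + 1e-12)):
        raise PositivityError("propensity outside [0.01, 0.99]; review positivity")
    n = y.size

    qa = np.where(a == 1, q1, q0)
    h = a / g1 - (1 - a) / (1 - g1)
    eps = _fluctuate(y, h, logit(qa))

    q1s = expit(logit(q1) + eps / g1)
    q0s = expit(logit(q0) - eps / (1 - g1))
    qas = np.where(a == 1, q1s, q0s)
    psi1, psi0 = float(q1s.mean()), float(q0s.mean())

    ic1 = a / g1 * (y - qas) + q1s - psi1
    ic0 = (1 - a) / (1 - g1) * (y - qas) + q0s - psi0
    ic_arr = ic0 - ic1
    z = stats.norm.ppf(1 - alpha / 2)

    se_arr = float(np.sqrt(ic_arr.var(ddof=1) / n))
    arr = psi0 - psi1
    ci_arr = (arr - z * se_arr, arr + z * se_arr)
    p_arr = float(2 * stats.norm.sf(abs(arr) / se_arr)) if se_arr > 0 else np.nan

    rr = psi1 / psi0
    ic_logrr = ic1 / psi1 - ic0 / psi0
    se_logrr = float(np.sqrt(ic_logrr.var(ddof=1) / n))
    ci_rr = (float(np.exp(np.log(rr) - z * se_logrr)),
             float(np.exp(np.log(rr) + z * se_logrr)))
    p_rr = float(2 * stats.norm.sf(abs(np.log(rr)) / se_logrr)) if se_logrr > 0 else np.nan

    return TargetedEstimate(contrast=contrast, mean1=psi1, mean0=psi0, arr=arr,
                            rr=rr, ci_arr=ci_arr, ci_rr=ci_rr, p_value=p_rr,
                            p_value_arr=p_arr, epsilon=eps, ic=ic_arr, n=n)


def _contrast_indicator(df: pd.DataFrame, contrast: tuple[str, str]) -> np.ndarray:
    treated_arm, control_arm = contrast
    if treated_arm == ANY_STEROID:
        return df["arm"].isin(ACTIVE_ARMS).to_numpy()
    return (df["arm"] == treated_arm).to_numpy()


def _restrict(cohort: TrialCohort, contrast: tuple[str, str]) -> TrialCohort:
    treated_arm, control_arm = contrast
    arms = list(ACTIVE_ARMS) + [control_arm] if treated_arm == ANY_STEROID \
        else [treated_arm, control_arm]
    for arm in arms:
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}")
    return cohort.restrict_arms(arms)


def tmle_from_cohort(cohort: TrialCohort, contrast: tuple[str, str] = (ANY_STEROID, CONTROL),
                     outcome: str = "y90",
                     q_init: tuple[np.ndarray, np.ndarray] | None = None,
                     g: PropensityModel | None = None,
                     adjust: bool = True, alpha: float = 0.05) -> TargetedEstimate:
    """TMLE of an arm contrast from a cohort table.

    The default initial fit is a logistic regression of the outcome on the
    encoded baseline covariates (with trial dummies) and the treated
    indicator; pass ``q_init=(q0, q1)`` to supply e.g. Super Learner
    counterfactual predictions instead.  ``adjust=False`` drops the
    covariates (intercept + treatment only), under which TMLE collapses to
    the unadjusted difference in proportions.
    """
    sub = _restrict(cohort, contrast)
    # a trial that never randomized one of the contrast groups violates
    # positivity for that contrast and is excluded
    counts = sub.data.groupby("trial").apply(
        lambda s: _contrast_indicator(s, contrast).mean(), include_groups=False)
    bad = counts[(counts <= 0) | (counts >= 1)].index
    if len(bad):
        warnings.warn(f"trial(s) {sorted(bad)} lack a {contrast} group and are "
                      "excluded from this contrast")
        keep = ~sub.data["trial"].isin(bad)
        sub = TrialCohort(sub.data[keep].reset_index(drop=True), sub.covariates,
                          dict(sub.provenance))
    df = sub.data
    treated = _contrast_indicator(df, contrast).astype(int)
    if treated.min() == treated.max():
        raise ValueError("cohort lacks one of the contrast groups")
    y = df[outcome].to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError("outcome is constant in the contrast cohort")

    if q_init is None:
        if adjust:
            fm = FeatureMap(include_treatment=False).fit(sub)
            X = fm.transform(sub)
            Xd = np.column_stack([X, treated])
            lr = LogisticRegression(max_iter=5000, C=1e4).fit(Xd, y)
            q0 = lr.predict_proba(np.column_stack([X, np.zeros(len(df))]))[:, 1]
            q1 = lr.predict_proba(np.column_stack([X, np.ones(len(df))]))[:, 1]
        else:
            m0 = y[treated == 0].mean()
            m1 = y[treated == 1].mean()
            q0 = np.full(len(df), m0)
            q1 = np.full(len(df), m1)
    else:
        q0, q1 = q_init
        q0, q1 = np.asarray(q0, float), np.asarray(q1, float)
        if q0.size != len(df):
            raise ValueError("q_init must match the contrast-restricted cohort size")

    g = g or PropensityModel()
    g1 = g.treated_probability(sub, treated)
    return tmle_ate(y, treated, q0, q1, g1, contrast=contrast, alpha=alpha)


def pooled_and_per_trial(cohort: TrialCohort,
                         contrast: tuple[str, str] = (ANY_STEROID, CONTROL),
                         outcome: str = "y90", g: PropensityModel | None = None,
                         adjust: bool = True) -> dict[str, TargetedEstimate]:
    """One TMLE per trial plus the pooled estimate (trial as a covariate).

    Trials missing a contrast group or an outcome class are skipped with a
    warning, mirroring how a pooled individual-patient-data analysis handles
    trials that never randomized a given regimen.
    """
    out: dict[str, TargetedEstimate] = {}
    for trial, tdf in cohort.data.groupby("trial"):
        sub = TrialCohort(tdf.reset_index(drop=True), cohort.covariates,
                          dict(cohort.provenance))
        restricted = _restrict(sub, contrast)
        treated = _contrast_indicator(restricted.data, contrast)
        y = restricted.data[outcome]
        if treated.min() == treated.max() or y.min() == y.max():
            warnings.warn(f"trial {trial!r} skipped for contrast {contrast}: "
                          "missing a group or outcome class")
            continue
        out[str(trial)] = tmle_from_cohort(sub, contrast, outcome, g=g, adjust=adjust)
    out["pooled"] = tmle_from_cohort(cohort, contrast, outcome, g=g, adjust=adjust)
    return out
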