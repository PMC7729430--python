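"""Pruned recursive-partitioning translation of the individualized rule.

Maps baseline covariates to the treat / don't-treat recommendation implied
by thresholding the estimated individual treatment effect at a chosen NWT.
The tree is CART (Gini) grown on the binary recommendation label and pruned
by cost-complexity: the complexity parameter is chosen over the pruning path
by 20-fold cross-validation with the one-standard-error rule.  Regression on
the effect itself is available via ``mode="regression"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .cohort import TrialCohort
from .ite import ITEEstimate
from .net_benefit import Threshold

__all__ = ["TreeNode", "PolicyTreeClassifier", "fit_tree", "tree_design"]

#: default covariate list for the clinical decision aid
TREE_COVARIATES = (
    "age", "male", "admission_category", "saps2", "sofa", "hospital_acquired",
    "infection_site", "cortisol_baseline", "cortisol_increment", "lactate",
    "norepinephrine_max",
)


@dataclass
class TreeNode:
    """One node of the fitted policy tree (JSON-serializable)."""

    n: int
    impurity: float
    leaf_label: str | None = None
    split: tuple[str, float] | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    def to_dict(self) -> dict:
        out = {"n": self.n, "impurity": round(self.impurity, 6)}
        if self.split is not None:
            out["split"] = {"covariate": self.split[0], "threshold": self.split[1]}
            out["children"] = [c.to_dict() for c in self.children]
        else:
            out["leaf_label"] = self.leaf_label
        return out

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.split is None:
            return f"{pad}-> {self.leaf_label} (n={self.n})"
        name, thr = self.split
        lines = [f"{pad}if {name} <= {thr:.4g}:",
                 self.children[0].render(indent + 1),
                 f"{pad}else:  # {name} > {thr:.4g}",
                 self.children[1].render(indent + 1)]
        return "\n".join(lines)


def tree_design(cohort: TrialCohort,
                covariates: Sequence[str] = TREE_COVARIATES
                ) -> tuple[np.ndarray, list[str]]:
    """Raw-unit numeric design for the tree: continuous/binary as observed
    (median/mode imputed), categoricals one-hot."""
    df = cohort.data
    specs = {c.name: c for c in cohort.covariates}
    cols, names = [], []
    for name in covariates:
        if name not in specs:
            raise ValueError(f"unknown covariate {name!r}")
        spec = specs[name]
        col = df[name]
        if spec.kind == "categorical":
            filled = col.fillna(col.mode().iloc[0]).astype(str)
            for lv in spec.levels[1:]:
                cols.append((filled == lv).to_numpy(dtype=float))
                names.append(f"{name}={lv}")
        else:
            fill = col.median() if spec.kind == "continuous" else col.mode().iloc[0]
            cols.append(col.fillna(fill).to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names


class PolicyTreeClassifier(ClassifierMixin, BaseEstimator):
    """CART with cost-complexity pruning selected by CV and the 1-SE rule.

    ``ccp_alpha=None`` (default) triggers the cross-validated selection;
    a numeric value (including ``np.inf`` for a root-only tree) bypasses it.
    """

    def __init__(self, cv_folds: int = 20, min_samples_leaf: int = 20,
                 ccp_alpha: float | None = None, mode: str = "classification",
                 random_state: int | None = 0):
        self.cv_folds = cv_folds
        self.min_samples_leaf = min_samples_leaf
        self.ccp_alpha = ccp_alpha
        self.mode = mode
        self.random_state = random_state

    def _base(self, alpha: float):
        cls = DecisionTreeClassifier if self.mode == "classification" \
            else DecisionTreeRegressor
        kw = {"criterion": "gini"} if self.mode == "classification" else {}
        return cls(min_samples_leaf=self.min_samples_leaf, ccp_alpha=alpha,
                   random_state=self.random_state, **kw)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.mode == "classification" and self.classes_.size < 2:
            warnings.warn("single-class labels: returning a trivial root-only tree")
            self.ccp_alpha_ = 0.0
            self.tree_model_ = self._base(0.0).fit(X, y)
            return self
        if self.ccp_alpha is not None:
            alpha = min(float(self.ccp_alpha), 1e12)  # inf -> prune to the root
            self.ccp_alpha_ = alpha
            self.tree_model_ = self._base(alpha).fit(X, y)
            return self

        path = self._base(0.0).cost_complexity_pruning_path(X, y)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        splitter = (StratifiedKFold if self.mode == "classification" else KFold)(
            n_splits=min(self.cv_folds, len(y)), shuffle=True,
            random_state=self.random_state)
        errs = np.zeros((splitter.get_n_splits(), alphas.size))
        for i, (tr, te) in enumerate(splitter.split(X, y)):
            for j, a in enumerate(alphas):
                fit = self._base(a).fit(X[tr], y[tr])
                pred = fit.predict(X[te])
                errs[i, j] = np.mean(pred != y[te]) if self.mode == "classification" \
                    else np.mean((pred - y[te]) ** 2)
        mean = errs.mean(axis=0)
        se = errs.std(axis=0, ddof=1) / np.sqrt(errs.shape[0])
        j_min = int(np.argmin(mean))
        ok = mean <= mean[j_min] + se[j_min]
        j_sel = int(np.max(np.flatnonzero(ok)))  # largest alpha within 1 SE
        self.cv_table_ = pd.DataFrame({"ccp_alpha": alphas, "cv_error": mean, "se": se})
        self.ccp_alpha_ = float(alphas[j_sel])
        self.tree_model_ = self._base(self.ccp_alpha_).fit(X, y)
        return self

    def predict(self, X):
        return self.tree_model_.predict(np.asarray(X, dtype=float))

    def to_node(self, feature_names: Sequence[str],
                labels: Sequence[str] | None = None) -> TreeNode:
        t = self.tree_model_.tree_

        def label(i: int) -> str:
            if self.mode == "regression":
                return f"{t.value[i].ravel()[0]:.4f}"
            k = int(np.argmax(t.value[i]))
            cls = self.tree_model_.classes_[k]
            return str(labels[int(cls)]) if labels is not None else str(cls)

        def build(i: int) -> TreeNode:
            if t.children_left[i] == -1:
                return TreeNode(n=int(t.n_node_samples[i]),
                                impurity=float(t.impurity[i]), leaf_label=label(i))
            return TreeNode(
                n=int(t.n_node_samples[i]), impurity=float(t.impurity[i]),
                split=(feature_names[t.feature[i]], float(t.threshold[i])),
                children=(build(t.children_left[i]), build(t.children_right[i])))

        return build(0)


def fit_tree(cohort: TrialCohort, ite: ITEEstimate, threshold: Threshold,
             covariates: Sequence[str] = TREE_COVARIATES, cv_folds: int = 20,
             min_samples_leaf: int = 20, ccp_alpha: float | None = None,
             seed: int = 0) -> tuple[PolicyTreeClassifier, TreeNode]:
    """Fit the clinical decision tree for one decision threshold.

    Labels are 1{D_i > t}; returns the fitted classifier and its
    JSON-serializable node structure, leaves labelled ``treat`` /
    ``no_treat`` (deterministic leaf labels: majority class).
    """
    X, names = tree_design(cohort, covariates)
    y = (ite.d.to_numpy() > threshold.t).astype(int)
    clf = PolicyTreeClassifier(cv_folds=cv_folds, min_samples_leaf=min_samples_leaf,
                               ccp_alpha=ccp_alpha, random_state=seed)
    clf.fit(X, y)
    node = clf.to_node(names, labels=("no_treat", "treat"))
    return clf, node
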