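"""Design-matrix encoding shared by every outcome model.

Encodes a cohort table into a numeric design: standardized continuous
covariates (median-imputed), one-hot categoricals (mode-imputed, first level
dropped), the binary missingness indicators, trial dummies, treatment-arm
dummies, and arm x covariate interaction columns so that parametric learners
can express treatment-effect heterogeneity.  Counterfactual prediction is an
``arm_override`` at transform time.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import ARMS, TrialCohort
from .marginals import CovariateSpec

__all__ = ["FeatureMap", "EncodingError"]


class EncodingError(ValueError):
    pass


#: covariates whose interaction with treatment enters the design by default
DEFAULT_INTERACTIONS = ("saps2", "cortisol_increment")


class FeatureMap:
    """Covariate -> design encoding fitted on a training cohort."""

    def __init__(self, interactions: Sequence[str] = DEFAULT_INTERACTIONS,
                 include_treatment: bool = True):
        self.interactions = tuple(interactions)
        self.include_treatment = include_treatment

    def fit(self, cohort: TrialCohort) -> "FeatureMap":
        df = cohort.data
        self.covariates_ = cohort.covariates
        self.trial_levels_ = tuple(sorted(df["trial"].astype(str).unique()))
        self.arm_levels_ = tuple(a for a in ARMS if a in set(df["arm"]))
        self.impute_: dict[str, object] = {}
        self.scale_: dict[str, tuple[float, float]] = {}
        for cov in self.covariates_:
            col = df[cov.name]
            if cov.kind == "continuous":
                med = float(col.median())
                self.impute_[cov.name] = med
                filled = col.fillna(med).astype(float)
                sd = float(filled.std())
                self.scale_[cov.name] = (float(filled.mean()), sd if sd > 0 else 1.0)
            elif cov.kind == "binary":
                mode = col.mode()
                self.impute_[cov.name] = float(mode.iloc[0]) if len(mode) else 0.0
            else:
                mode = col.mode()
                self.impute_[cov.name] = str(mode.iloc[0]) if len(mode) else cov.levels[0]
        self.feature_names_ = self._names()
        return self

    def _names(self) -> list[str]:
        names: list[str] = []
        for cov in self.covariates_:
            if cov.kind == "categorical":
                names += [f"{cov.name}={lv}" for lv in cov.levels[1:]]
            else:
                names.append(cov.name)
        names += [f"miss_{c.name}" for c in self.covariates_]
        names += [f"trial={t}" for t in self.trial_levels_[1:]]
        if self.include_treatment:
            arm_names = [f"arm={a}" for a in self.arm_levels_[1:]]
            names += arm_names
            for an in arm_names:
                names += [f"{an}:{x}" for x in self.interactions]
        return names

    def transform(self, data: TrialCohort | pd.DataFrame,
                  arm_override: str | None = None) -> np.ndarray:
        df = data.data if isinstance(data, TrialCohort) else data
        n = len(df)
        cols: list[np.ndarray] = []
        std_cache: dict[str, np.ndarray] = {}
        for cov in self.covariates_:
            col = df[cov.name] if cov.name in df.columns else pd.Series(np.nan, index=df.index)
            if cov.kind == "continuous":
                mean, sd = self.scale_[cov.name]
                x = (col.fillna(self.impute_[cov.name]).to_numpy(dtype=float) - mean) / sd
                std_cache[cov.name] = x
                cols.append(x)
            elif cov.kind == "binary":
                cols.append(col.fillna(self.impute_[cov.name]).to_numpy(dtype=float))
            else:
                filled = col.fillna(self.impute_[cov.name]).astype(str)
                unknown = set(filled.unique()) - set(cov.levels)
                if unknown:
                    raise EncodingError(
                        f"column {cov.name!r}: unknown level(s) {sorted(unknown)}")
                for lv in cov.levels[1:]:
                    cols.append((filled == lv).to_numpy(dtype=float))
        for cov in self.covariates_:
            mc = f"miss_{cov.name}"
            if mc in df.columns:
                cols.append(df[mc].to_numpy(dtype=float))
            else:
                cols.append(np.zeros(n))
        trial = df["trial"].astype(str)
        unknown = set(trial.unique()) - set(self.trial_levels_)
        if unknown:
            raise EncodingError(f"column 'trial': unknown level(s) {sorted(unknown)}")
        for t in self.trial_levels_[1:]:
            cols.append((trial == t).to_numpy(dtype=float))
        if self.include_treatment:
            if arm_override is not None:
                if arm_override not in ARMS:
                    raise EncodingError(f"column 'arm': unknown level(s) [{arm_override!r}]")
                arm = pd.Series(arm_override, index=df.index)
            else:
                arm = df["arm"].astype(str)
                unknown = set(arm.unique()) - set(ARMS)
                if unknown:
                    raise EncodingError(f"column 'arm': unknown level(s) {sorted(unknown)}")
            for a in self.arm_levels_[1:]:
                dummy = (arm == a).to_numpy(dtype=float)
                cols.append(dummy)
            for a in self.arm_levels_[1:]:
                dummy = (arm == a).to_numpy(dtype=float)
                for x in self.interactions:
                    cols.append(dummy * std_cache[x])
        return np.column_stack(cols)
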