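"""Named simulation scenarios built on the cohort generator.

Each scenario is a fully specified data-generating process used by the
package's simulation studies: a null process (no treatment effect anywhere),
a constant-target two-arm trial whose true average risk difference is solved
to a requested value, and a strong-heterogeneity process in which a large
fraction of patients is actively harmed.  True average effects are computed
by Monte-Carlo integration over the covariate distribution with a fixed
internal seed, independent of any estimator.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .cohort import (ARMS, CONTROL, HYDRO, DGPParams, _true_risks,
                     default_dgp, generate_cohort)
from .marginals import default_covariates

__all__ = ["null_effect_dgp", "constant_arr_two_arm_dgp", "strong_hte_dgp",
           "true_average_effect"]

_PROBE_SEED = 424242
_PROBE_N = 400_000


def null_effect_dgp() -> DGPParams:
    """Default process with every arm effect switched off."""
    base = default_dgp()
    zero = {arm: {"main": 0.0} for arm in base.arm_effects}
    return dataclasses.replace(base, arm_effects=zero)


def strong_hte_dgp() -> DGPParams:
    """Heavily heterogeneous effects: steep severity and adrenal-response
    interactions, so benefit and harm are both common."""
    base = default_dgp()
    effects = {
        HYDRO: {"main": -0.35, "saps2_slope": -0.030, "responder_coef": 0.90,
                "responder_cut": 9.0, "responder_rate": 0.41},
        "hydrocortisone_fludrocortisone": {
            "main": -0.25, "saps2_slope": -0.035, "responder_coef": 0.90,
            "responder_cut": 9.0, "responder_rate": 0.41},
    }
    return dataclasses.replace(base, arm_effects=effects)


def _two_arm(main: float) -> DGPParams:
    return DGPParams(
        trial_names=("rct",),
        trial_probs=(1.0,),
        trial_intercepts={"rct": 0.0},
        arm_probs={"rct": {CONTROL: 0.5, HYDRO: 0.5}},
        intercept=-0.1,
        baseline_terms=(
            {"name": "saps2", "coef": 0.035, "center": 55.0},
            {"name": "lactate", "coef": 0.08, "center": 3.0},
        ),
        arm_effects={HYDRO: {"main": main, "saps2_slope": -0.008,
                             "responder_coef": 0.20, "responder_cut": 9.0,
                             "responder_rate": 0.41}},
        missingness={},
    )


@lru_cache(maxsize=8)
def _probe_frame(dgp_key: float):
    # covariate draws only depend on the spec, not the effect parameters
    return generate_cohort(default_covariates(), _two_arm(0.0), _PROBE_N,
                           seed=np.random.SeedSequence(_PROBE_SEED)).data


@lru_cache(maxsize=8)
def constant_arr_two_arm_dgp(target_arr: float = -0.05) -> DGPParams:
    """Single two-arm trial whose true ARR (control risk minus treated risk,
    averaged over the covariate distribution) equals ``target_arr``.

    The treatment main effect is solved by root finding against a 400k-draw
    Monte-Carlo integral; the residual calibration error is far below the
    Monte-Carlo noise of any simulation that uses it.
    """
    df = _probe_frame(0.0)

    def gap(main: float) -> float:
        risks = _true_risks(df, _two_arm(main))
        return float(np.mean(risks[CONTROL] - risks[HYDRO])) - target_arr

    main = brentq(gap, -3.0, 3.0, xtol=1e-10)
    return _two_arm(float(main))


def true_average_effect(dgp: DGPParams, arm: str, n: int = _PROBE_N) -> float:
    """Monte-Carlo integral of the true risk difference control - arm."""
    cohort = generate_cohort(default_covariates(), dgp, n,
                             seed=np.random.SeedSequence(_PROBE_SEED + 1))
    df = cohort.data
    return float(np.mean(df[f"risk_{CONTROL}"] - df[f"risk_{arm}"]))
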