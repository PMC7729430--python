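"""SAPS II hospital-mortality equation.

The Simplified Acute Physiology Score II converts to a death probability
through a published logistic equation,

    logit P(death | SAPS2) = -7.7631 + 0.0737 * SAPS2 + 0.9971 * ln(SAPS2 + 1),

which serves here as the untreated baseline risk P(Y=1 | A=0, W) of the
severity-based individual-treatment-effect estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

#: practical SAPS II range; the equation itself is defined for any score >= 0
SAPS2_MAX = 163.0

__all__ = ["SapsRiskModel", "saps2_baseline_risk"]


@dataclass(frozen=True)
class SapsRiskModel:
    """Coefficients of the SAPS II logistic mortality equation."""

    intercept: float = -7.7631
    linear_coef: float = 0.0737
    log_coef: float = 0.9971

    def linear_predictor(self, saps2):
        s = np.asarray(saps2, dtype=float)
        return self.intercept + self.linear_coef * s + self.log_coef * np.log(s + 1.0)


def saps2_baseline_risk(saps2, model: SapsRiskModel | None = None):
    """Baseline (untreated) death probability from the SAPS II score.

    Strictly increasing in the score; scalar in, scalar out.  Scores outside
    the conventional [0, 163] range are allowed with a logged warning.
    """
    model = model or SapsRiskModel()
    s = np.asarray(saps2, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("SAPS II score must be finite")
    if np.any(s < 0):
        raise ValueError("SAPS II score must be non-negative")
    if np.any(s > SAPS2_MAX):
        logger.warning("SAPS II score above %s supplied; extrapolating the equation", SAPS2_MAX)
    out = expit(model.linear_predictor(s))
    return float(out) if np.isscalar(saps2) else out
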