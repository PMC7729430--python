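"""Decision-curve comparison of treatment strategies: net benefit vs NWT.

Net benefit of a treatment policy at decision threshold T is

    net benefit = decrease in event rate - treatment rate x T,

with treating no one as the zero reference.  T encodes how much harm the
treatment itself carries; clinicians reason more naturally with its inverse,
the number willing to treat (NWT = 1/T), the maximum number of patients one
would treat to prevent one event.  Strategies compared: treat everyone with
a regimen (net benefit = ATE - T), treat nobody, and threshold rules that
treat patient i when their estimated individual effect D_i exceeds T (net
benefit = E[D 1{D > T}] - P[D > T] x T).

For synthetic cohorts carrying both potential outcomes, an oracle variant
scores any assignment rule against the actual counterfactual outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ACTIVE_ARMS, ARMS, CONTROL, TrialCohort

__all__ = [
    "Threshold", "nwt_to_threshold", "threshold_to_nwt",
    "net_benefit_treat_all", "net_benefit_rule",
    "oracle_net_benefit", "net_benefit_curves",
]


@dataclass(frozen=True)
class Threshold:
    """A decision threshold T in (0, 1] and its NWT = 1/T."""

    t: float
    nwt: float

    def __post_init__(self) -> None:
        if not 0 < self.t <= 1:
            raise ValueError(f"threshold {self.t} outside (0, 1]")
        if abs(self.t * self.nwt - 1.0) > 1e-12:
            raise ValueError("t and nwt must be exact inverses")


def nwt_to_threshold(nwt: float) -> Threshold:
    """Threshold from a number willing to treat (NWT 10 -> T = 0.10)."""
    if not np.isfinite(nwt) or nwt <= 0:
        raise ValueError("number willing to treat must be positive")
    if nwt < 1:
        raise ValueError("number willing to treat below 1 implies a threshold above 1")
    return Threshold(t=1.0 / nwt, nwt=float(nwt))


def threshold_to_nwt(t: float) -> float:
    """Number willing to treat implied by a decision threshold."""
    if not np.isfinite(t) or not 0 < t <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    return 1.0 / t


def net_benefit_treat_all(ate_arr: float, t: float) -> float:
    """Treat-everybody strategy: ATE - 1 x T (everyone pays the cost)."""
    if not (np.isfinite(ate_arr) and np.isfinite(t)):
        raise ValueError("inputs must be finite")
    return float(ate_arr - t)


def net_benefit_rule(ite_values, t: float) -> tuple[float, float]:
    """Threshold rule "treat if D_i > t": net benefit and treated fraction.

    The event-rate decrease is the population average E[D 1{D > t}] (treated
    patients contribute their effect, untreated contribute zero), so the
    curve collapses to treat-none when nobody crosses the threshold and to
    treat-all when everybody does.
    """
    d = np.asarray(ite_values, dtype=float)
    if d.size == 0:
        raise ValueError("ite_values must be nonempty")
    treat = d > t
    treated_fraction = float(treat.mean())
    decrease = float((d * treat).mean())
    return decrease - treated_fraction * t, treated_fraction


def oracle_net_benefit(cohort: TrialCohort, assignments, t: float) -> tuple[float, float]:
    """Net benefit of an arbitrary assignment rule against the true
    counterfactual outcomes of a synthetic cohort.

    ``assignments`` is a per-patient arm label (control meaning untreated).
    The event-rate decrease is the sum over treated patients of their actual
    outcome difference Y(control) - Y(assigned regimen), divided by the
    cohort size.
    """
    if not cohort.has_truth:
        raise ValueError("oracle net benefit requires a synthetic cohort with "
                         "potential-outcome columns")
    df = cohort.data
    assignments = np.asarray(assignments, dtype=object)
    if assignments.shape != (len(df),):
        raise ValueError("one assignment per patient required")
    unknown = set(assignments) - set(ARMS) - {None}
    if unknown:
        raise ValueError(f"unknown arm(s) in assignments: {sorted(unknown)}")
    treated = np.array([a not in (None, CONTROL) for a in assignments])
    n = len(df)
    decrease = 0.0
    for arm in ACTIVE_ARMS:
        mask = treated & (assignments == arm)
        if mask.any():
            decrease += float((df.loc[mask, f"po_{CONTROL}"].to_numpy()
                               - df.loc[mask, f"po_{arm}"].to_numpy()).sum())
    decrease /= n
    treated_fraction = float(treated.mean())
    return decrease - treated_fraction * t, treated_fraction


def _curve_point(name: str, d, t: float) -> tuple[float, float]:
    if name == "treat_none":
        return 0.0, 0.0
    if name.startswith("treat_all"):
        ate = float(np.mean(d))
        return net_benefit_treat_all(ate, t), 1.0
    return net_benefit_rule(d, t)


def net_benefit_curves(strategies: Mapping[str, object],
                       nwt_grid: Sequence[float] = tuple(range(2, 101)),
                       bootstrap_b: int = 500, seed: int = 0,
                       trial_labels: Sequence | None = None) -> pd.DataFrame:
    """Net-benefit curves over an NWT grid with percentile bootstrap bands.

    ``strategies`` maps a name to its per-patient D values (scalar allowed
    for treat-all); names ``treat_none`` and ``treat_all*`` get their fixed
    interpretations.  The bootstrap resamples patients (stratified by trial
    when labels are given), re-evaluating every strategy on the same
    resample, and is reproducible given ``seed``.
    """
    if len(nwt_grid) == 0:
        raise ValueError("nwt_grid must be nonempty")
    thresholds = [nwt_to_threshold(v) for v in nwt_grid]

    sizes = {np.size(d) for name, d in strategies.items()
             if name != "treat_none" and np.size(d) > 1}
    if len(sizes) > 1:
        raise ValueError("per-patient strategies must share the cohort size")
    n = sizes.pop() if sizes else 0

    do_ci = bootstrap_b >= 2 and n > 0
    if bootstrap_b < 2:
        warnings.warn("bootstrap_b < 2: confidence bands omitted")
    if do_ci:
        # positions index into per-stratum *sorted* value vectors, so bands
        # depend only on the multiset of patient values (order-invariant)
        # and on the seed
        rng = np.random.default_rng(seed)
        if trial_labels is not None:
            labels = np.asarray(trial_labels)
            groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
        else:
            groups = [np.arange(n)]
        boot_pos = [[rng.integers(0, g.size, g.size) for g in groups]
                    for _ in range(bootstrap_b)]

    rows = []
    for name, d in strategies.items():
        d_arr = None if name == "treat_none" else np.atleast_1d(np.asarray(d, dtype=float))
        resamples = None
        if do_ci and name != "treat_none" and d_arr.size > 1:
            sorted_groups = [np.sort(d_arr[g]) for g in groups]
            resamples = [np.concatenate([sg[p] for sg, p in zip(sorted_groups, pos)])
                         for pos in boot_pos]
        for th in thresholds:
            nb, frac = _curve_point(name, d_arr, th.t)
            lo = hi = np.nan
            if resamples is not None:
                reps = np.array([_curve_point(name, vals, th.t)[0]
                                 for vals in resamples])
                lo, hi = np.percentile(reps, [2.5, 97.5])
            rows.append({"strategy": name, "nwt": th.nwt, "t": th.t,
                         "net_benefit": nb, "treated_fraction": frac,
                         "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)
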