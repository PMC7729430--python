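"""End-to-end orchestration: simulate -> ATE -> models -> ITE -> net benefit -> tree.

A YAML-configured run reproduces the full analysis on a synthetic cohort (or
a cohort CSV): TMLE ATE tables per trial and pooled for both endpoints, the
Super Learner fit with its evaluation report (optionally on a held-out
shifted-mortality cohort, emulating external validation), both per-patient
effect estimators, net-benefit curves with bootstrap bands and a plot, and
the clinical decision tree.  A manifest records the configuration, seeds and
stage timings; stage outputs are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .cohort import (ACTIVE_ARMS, COMBO, CONTROL, HYDRO, TrialCohort,
                     default_dgp, simulate_default_cohort)
from .evaluation import brier_score, delong_auc_ci, calibration_curve
from .ite import ite_optimal, ite_saps2_cohort
from .learners import LearnerSpec, compact_library, default_library
from .net_benefit import net_benefit_curves, nwt_to_threshold
from .risk_models import saps2_baseline_risk
from .super_learner import CrossValidationPlan, fit_super_learner, predict_risk
from .tmle import ANY_STEROID, pooled_and_per_trial
from .tree import fit_tree

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]

_CONTRASTS = (
    ("any_steroid_vs_control", (ANY_STEROID, CONTROL)),
    ("hydrocortisone_vs_control", (HYDRO, CONTROL)),
    ("combination_vs_control", (COMBO, CONTROL)),
    ("hydrocortisone_vs_combination", (HYDRO, COMBO)),
)


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    out_dir: str = "results/run"
    n: int = 2548
    seed: int = 0
    outcome: str = "y90"
    cohort_csv: str | None = None          # analyse an existing cohort instead
    library: str | Sequence[Mapping] = "compact"
    n_folds: int = 10
    nwt_min: int = 2
    nwt_max: int = 100
    bootstrap_b: int = 500
    tree_nwt: float = 50
    heldout: Mapping | None = None         # {"n": ..., "seed": ..., "mortality_shift": ...}

    def __post_init__(self) -> None:
        if self.outcome not in ("y90", "y28"):
            raise ValueError("outcome must be 'y90' or 'y28'")
        if self.n < 1 or self.n_folds < 2 or self.nwt_min < 1 \
                or self.nwt_max < self.nwt_min:
            raise ValueError("invalid run configuration")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolve_library(self) -> tuple[LearnerSpec, ...]:
        if self.library == "default":
            return default_library()
        if self.library == "compact":
            return compact_library()
        return tuple(LearnerSpec(d["name"], d["family"], d.get("hyperparameters", {}))
                     for d in self.library)


def _shifted_cohort(spec: Mapping, base_seed: int) -> TrialCohort:
    """Held-out cohort from the same process with a mortality log-odds shift."""
    dgp = dataclasses.replace(default_dgp(),
                              intercept=default_dgp().intercept
                              + float(spec.get("mortality_shift", 0.0)))
    from .cohort import apply_missingness, generate_cohort
    from .marginals import default_covariates
    ss = np.random.SeedSequence(int(spec.get("seed", base_seed + 1)))
    cov_ss, miss_ss = ss.spawn(2)
    cohort = generate_cohort(default_covariates(), dgp, int(spec.get("n", 500)),
                             seed=cov_ss)
    return apply_missingness(cohort, dgp, seed=miss_ss)


def _evaluation_payload(scores, y, cv_auc=None) -> dict:
    auc = delong_auc_ci(scores, y)
    out = {"auc": auc.auc, "auc_ci": list(auc.ci),
           "brier": brier_score(scores, y),
           "calibration": calibration_curve(scores, y).to_dict(orient="records")}
    if cv_auc is not None:
        out["cv_auc"] = float(cv_auc)
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and persist its outputs under ``config.out_dir``.

    Returns the manifest.  Any stage failure aborts with the stage name;
    outputs written so far are left on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": dataclasses.asdict(config),
                      "stages": {}}
    stage = "setup"
    try:
        t0 = time.perf_counter()
        stage = "cohort"
        if config.cohort_csv:
            cohort = TrialCohort.from_csv(config.cohort_csv)
        else:
            cohort = simulate_default_cohort(config.n, seed=config.seed)
        cohort.to_csv(out / "cohort.csv")
        manifest["stages"]["cohort"] = {"n": len(cohort.data),
                                        "seconds": round(time.perf_counter() - t0, 2)}

        t0 = time.perf_counter()
        stage = "ate"
        ate: dict = {}
        for outcome in ("y90", "y28"):
            ate[outcome] = {}
            for cname, contrast in _CONTRASTS:
                ests = pooled_and_per_trial(cohort, contrast, outcome=outcome)
                ate[outcome][cname] = {k: v.to_dict() for k, v in ests.items()}
        (out / "ate.json").write_text(json.dumps(ate, indent=2))
        manifest["stages"]["ate"] = {"seconds": round(time.perf_counter() - t0, 2)}

        t0 = time.perf_counter()
        stage = "super_learner"
        plan = CrossValidationPlan(n_folds=config.n_folds, seed=config.seed)
        fsl = fit_super_learner(cohort, outcome=config.outcome,
                                library=config.resolve_library(), plan=plan)
        y = cohort.data[config.outcome].to_numpy(dtype=int)
        level1_scores = fsl.level1 @ fsl.weights   # honest CV predictions
        report = {
            "weights": dict(zip(fsl.learner_names, map(float, fsl.weights))),
            "internal_cv": _evaluation_payload(level1_scores, y, cv_auc=fsl.cv_auc),
            "saps2": _evaluation_payload(
                saps2_baseline_risk(cohort.data["saps2"].to_numpy(float)), y),
        }
        if config.heldout is not None:
            held = _shifted_cohort(config.heldout, config.seed)
            held.to_csv(out / "heldout_cohort.csv")
            hy = held.data[config.outcome].to_numpy(dtype=int)
            report["heldout"] = _evaluation_payload(predict_risk(fsl, held), hy)
        (out / "evaluation.json").write_text(json.dumps(report, indent=2))
        manifest["stages"]["super_learner"] = {
            "cv_auc": float(fsl.cv_auc),
            "seconds": round(time.perf_counter() - t0, 2)}

        t0 = time.perf_counter()
        stage = "ite"
        est_opt = ite_optimal(fsl, cohort)
        est_saps = ite_saps2_cohort(cohort)
        est_opt.to_frame().to_csv(out / "ite_optimal.csv", index=False)
        est_saps.to_frame().to_csv(out / "ite_saps2.csv", index=False)
        manifest["stages"]["ite"] = {"seconds": round(time.perf_counter() - t0, 2)}

        t0 = time.perf_counter()
        stage = "net_benefit"
        strategies = {
            "treat_none": None,
            f"treat_all:{HYDRO}": est_opt.arr[HYDRO].to_numpy(),
            f"treat_all:{COMBO}": est_opt.arr[COMBO].to_numpy(),
            "rule_saps2": est_saps.d.to_numpy(),
            "rule_optimal": est_opt.d.to_numpy(),
        }
        curves = net_benefit_curves(
            strategies, nwt_grid=range(config.nwt_min, config.nwt_max + 1),
            bootstrap_b=config.bootstrap_b, seed=config.seed,
            trial_labels=cohort.data["trial"].to_numpy())
        curves.to_csv(out / "net_benefit.csv", index=False)
        _plot_curves(curves, out / "net_benefit.png")
        manifest["stages"]["net_benefit"] = {
            "seconds": round(time.perf_counter() - t0, 2)}

        t0 = time.perf_counter()
        stage = "tree"
        clf, node = fit_tree(cohort, est_opt, nwt_to_threshold(config.tree_nwt),
                             seed=config.seed)
        (out / "tree.json").write_text(json.dumps(
            {"nwt": config.tree_nwt, "ccp_alpha": clf.ccp_alpha_,
             "tree": node.to_dict()}, indent=2))
        (out / "tree.txt").write_text(node.render() + "\n")
        manifest["stages"]["tree"] = {"ccp_alpha": clf.ccp_alpha_,
                                      "seconds": round(time.perf_counter() - t0, 2)}
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _plot_curves(curves, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, sub in curves.groupby("strategy"):
        sub = sub.sort_values("nwt")
        ax.plot(sub["nwt"], sub["net_benefit"], label=name)
        if sub["ci_lo"].notna().any():
            ax.fill_between(sub["nwt"], sub["ci_lo"], sub["ci_hi"], alpha=0.15)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("number willing to treat (1 / decision threshold)")
    ax.set_ylabel("net benefit vs treating no one")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
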