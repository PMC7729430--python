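import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from steroid_ite.cohort import (
    ACTIVE_ARMS, ARMS, COMBO, CONTROL, HYDRO, TrialCohort,
    apply_missingness, default_dgp, generate_cohort, simulate_default_cohort,
    true_ite,
)
from steroid_ite.marginals import ConfigurationError, default_covariates
from steroid_ite.scenarios import null_effect_dgp, true_average_effect


def _csv_bytes(cohort):
    buf = io.StringIO()
    cohort.data.to_csv(buf, index=False)
    return buf.getvalue()


def test_same_seed_gives_byte_identical_cohorts():
    a = simulate_default_cohort(400, seed=7)
    b = simulate_default_cohort(400, seed=7)
    assert _csv_bytes(a) == _csv_bytes(b)
    assert _csv_bytes(a) != _csv_bytes(simulate_default_cohort(400, seed=8))


@pytest.mark.parametrize("seed", range(10))
def test_default_cohort_reproduces_printed_pooled_marginals(seed):
    d = simulate_default_cohort(2548, seed=seed).data
    # process-level mortality: the generator's event rate for this cohort,
    # free of the terminal Bernoulli draw's binomial noise
    assigned_risk = np.select([d["arm"] == a for a in ARMS],
                              [d[f"risk_{a}"] for a in ARMS])
    assert 0.457 <= assigned_risk.mean() <= 0.496
    assert 42 <= d["saps2"].median() <= 69
    assert 55 <= d["age"].median() <= 76
    assert 9 <= d["sofa"].median() <= 13
    assert 0.60 <= d["male"].mean() <= 0.70


def test_realized_mortality_matches_the_printed_rate_across_seeds():
    # single-cohort realized mortality carries ~1pp binomial noise, so the
    # printed 95% CI is checked on the across-seed average
    rates = [simulate_default_cohort(2548, seed=s).data["y90"].mean()
             for s in range(10)]
    assert 0.457 <= np.mean(rates) <= 0.496


def test_trial_and_arm_composition_mirrors_the_pooled_cohort():
    d = simulate_default_cohort(2548, seed=0).data
    frac = d["trial"].value_counts(normalize=True)
    for trial, n in zip(("annane", "corticus", "coiitss", "crics"),
                        (299, 499, 509, 1241)):
        assert frac[trial] == pytest.approx(n / 2548, abs=0.03)
    assert set(d.loc[d.trial == "coiitss", "arm"]) == {HYDRO, COMBO}
    assert set(d.loc[d.trial == "corticus", "arm"]) == {CONTROL, HYDRO}


def test_null_effect_process_shows_no_arm_difference():
    cohort = generate_cohort(default_covariates(), null_effect_dgp(), 20_000, seed=3)
    d = cohort.data
    p = d.groupby("arm")["y90"].mean()
    n_arm = d["arm"].value_counts()
    for a in ACTIVE_ARMS:
        se = np.sqrt(0.25 / n_arm[CONTROL] + 0.25 / n_arm[a])
        assert abs(p[CONTROL] - p[a]) < 3 * se
    assert np.allclose(d[f"risk_{CONTROL}"], d[f"risk_{HYDRO}"])


def test_28_day_deaths_are_nested_in_90_day_deaths():
    d = simulate_default_cohort(3000, seed=2).data
    assert (d["y28"] <= d["y90"]).all()
    assert 0 < d["y28"].sum() < d["y90"].sum()


def test_missingness_indicators_match_blanked_values():
    c = simulate_default_cohort(3000, seed=4)
    d = c.data
    for cov in c.covariate_names:
        miss = d[f"miss_{cov}"].astype(bool)
        assert miss.equals(d[cov].isna())
    assert d[["trial", "arm", "y90", "y28"]].notna().all().all()


def test_zero_probability_missingness_is_identity():
    base = generate_cohort(default_covariates(), default_dgp(), 500, seed=5)
    dgp = dataclasses.replace(default_dgp(), missingness={})
    out = apply_missingness(base, dgp, seed=5)
    pd.testing.assert_frame_equal(
        out.data[list(base.covariate_names)], base.data[list(base.covariate_names)])
    assert out.data.filter(like="miss_").to_numpy().sum() == 0


def test_value_independent_missingness_rate_is_binomial():
    base = generate_cohort(default_covariates(), default_dgp(), 5000, seed=6)
    dgp = dataclasses.replace(
        default_dgp(),
        missingness={"cortisol_increment": {"kind": "mcar", "p": 0.3}})
    out = apply_missingness(base, dgp, seed=6)
    rate = out.data["miss_cortisol_increment"].mean()
    assert rate == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / 5000))


def test_value_dependent_missingness_biases_the_observed_subsample():
    # default mechanism blanks high cortisol increments more often,
    # so the observed mean must undershoot the complete-data mean
    base = generate_cohort(default_covariates(), default_dgp(), 8000, seed=7)
    out = apply_missingness(base, default_dgp(), seed=7)
    full = base.data["cortisol_increment"].mean()
    observed = out.data["cortisol_increment"].mean()
    assert observed < full - 0.2


def test_missingness_mechanism_for_unknown_covariate_is_rejected():
    base = generate_cohort(default_covariates(), default_dgp(), 50, seed=8)
    dgp = dataclasses.replace(default_dgp(),
                              missingness={"troponin": {"kind": "mcar", "p": 0.1}})
    with pytest.raises(ConfigurationError, match="troponin"):
        apply_missingness(base, dgp, seed=8)


def test_true_ite_is_direct_risk_subtraction_and_zero_under_null():
    cohort = generate_cohort(default_covariates(), null_effect_dgp(), 200, seed=9)
    assert (true_ite(null_effect_dgp(), cohort).to_numpy() == 0).all()

    df = pd.DataFrame({"trial": ["t"], "arm": [CONTROL], "y90": [1], "y28": [1],
                       **{f"risk_{a}": [r] for a, r in
                          zip(ARMS, (0.5, 0.4, 0.45))},
                       **{f"po_{a}": [1] for a in ARMS}})
    tiny = TrialCohort(df, covariates=())
    ti = true_ite(default_dgp(), tiny)
    assert ti[HYDRO].iloc[0] == pytest.approx(0.10)
    assert ti[COMBO].iloc[0] == pytest.approx(0.05)


def test_true_ite_requires_counterfactual_columns():
    c = simulate_default_cohort(50, seed=1)
    stripped = TrialCohort(c.data.drop(columns=[f"risk_{a}" for a in ARMS]),
                           c.covariates)
    with pytest.raises(ValueError, match="risk_"):
        true_ite(default_dgp(), stripped)


def test_mean_true_ite_matches_monte_carlo_integral_of_the_process():
    dgp = default_dgp()
    cohort = generate_cohort(default_covariates(), dgp, 30_000, seed=10)
    ti = true_ite(dgp, cohort)
    for arm in ACTIVE_ARMS:
        truth = true_average_effect(dgp, arm)
        mc_se = ti[arm].std() / np.sqrt(len(ti))
        assert ti[arm].mean() == pytest.approx(truth, abs=3 * mc_se + 1e-3)


def test_generate_rejects_empty_cohort():
    with pytest.raises(ValueError):
        generate_cohort(default_covariates(), default_dgp(), 0, seed=0)


def test_csv_round_trip_preserves_the_table(tmp_path):
    c = simulate_default_cohort(120, seed=3)
    path = tmp_path / "cohort.csv"
    c.to_csv(path)
    back = TrialCohort.from_csv(path)
    assert back.covariate_names == c.covariate_names
    pd.testing.assert_frame_equal(back.data, c.data, check_dtype=False)
    assert (tmp_path / "cohort.dict.json").exists()
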