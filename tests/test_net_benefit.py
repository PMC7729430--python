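import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from steroid_ite.cohort import ARMS, COMBO, CONTROL, HYDRO, TrialCohort
from steroid_ite.net_benefit import (
    Threshold, net_benefit_curves, net_benefit_rule, net_benefit_treat_all,
    nwt_to_threshold, oracle_net_benefit, threshold_to_nwt,
)


class TestThreshold:
    def test_worked_conversions(self):
        assert nwt_to_threshold(10).t == pytest.approx(0.10)
        assert nwt_to_threshold(25).t == pytest.approx(0.04)
        assert nwt_to_threshold(1).t == 1.0
        assert threshold_to_nwt(0.10) == pytest.approx(10.0)

    def test_domain_errors(self):
        for bad in (0, -3, np.inf, np.nan):
            with pytest.raises(ValueError):
                nwt_to_threshold(bad)
        with pytest.raises(ValueError):
            Threshold(t=0.1, nwt=11)  # not exact inverses


class TestTreatAll:
    def test_printed_pooled_example_rounds_to_one_cent(self):
        nb = net_benefit_treat_all(0.0511, nwt_to_threshold(25).t)
        assert nb == pytest.approx(0.0111)
        assert round(nb, 2) == 0.01

    def test_equivalence_point_and_free_treatment(self):
        assert net_benefit_treat_all(0.04, 0.04) == 0.0
        assert net_benefit_treat_all(0.0511, 0.0) == 0.0511


class TestThresholdRule:
    def test_hand_computed_example(self):
        nb, frac = net_benefit_rule([0.10, 0.00], 0.05)
        assert nb == pytest.approx(0.025)
        assert frac == 0.5

    def test_collapses_to_treat_none_and_treat_all(self):
        nb, frac = net_benefit_rule([0.01, 0.02], 0.05)
        assert nb == 0.0 and frac == 0.0
        d = np.array([0.2, 0.3, 0.25])
        nb, frac = net_benefit_rule(d, 0.05)
        assert frac == 1.0
        assert nb == pytest.approx(net_benefit_treat_all(d.mean(), 0.05))

    def test_empty_input_is_a_contract_error(self):
        with pytest.raises(ValueError):
            net_benefit_rule([], 0.1)

    @given(st.lists(st.floats(-0.5, 0.5), min_size=1, max_size=50),
           st.floats(0.01, 1.0))
    def test_bounds_hold_for_any_effect_distribution(self, d, t):
        nb, frac = net_benefit_rule(d, t)
        assert nb >= -t - 1e-12
        assert nb <= float(np.mean(np.clip(d, 0, None))) + 1e-12
        assert 0.0 <= frac <= 1.0

    def test_treated_fraction_is_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.05, 0.1, 500)
        fracs = [net_benefit_rule(d, t)[1] for t in np.linspace(0.01, 0.5, 40)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


def _potential_outcome_cohort(y0, y1, seed=0):
    n = len(y0)
    df = pd.DataFrame({
        "trial": "t", "arm": CONTROL, "y90": list(y0), "y28": list(y0),
        "risk_control": 0.5, "risk_hydrocortisone": 0.5,
        "risk_hydrocortisone_fludrocortisone": 0.5,
        "po_control": list(y0), "po_hydrocortisone": list(y1),
        "po_hydrocortisone_fludrocortisone": list(y1)})
    return TrialCohort(df, ())


class TestOracle:
    def test_treating_no_one_is_the_zero_reference(self):
        cohort = _potential_outcome_cohort([1, 0, 1, 0], [0, 0, 1, 1])
        nb, frac = oracle_net_benefit(cohort, [CONTROL] * 4, 0.1)
        assert nb == 0.0 and frac == 0.0

    def test_threshold_rule_attains_the_brute_force_maximum(self):
        rng = np.random.default_rng(5)
        y0 = rng.integers(0, 2, 10)
        y1 = rng.integers(0, 2, 10)
        cohort = _potential_outcome_cohort(y0, y1)
        t = 0.04
        best = max(
            oracle_net_benefit(cohort,
                               [HYDRO if b else CONTROL for b in bits], t)[0]
            for bits in itertools.product([0, 1], repeat=10))
        rule = [HYDRO if d > t else CONTROL for d in (y0 - y1)]
        assert oracle_net_benefit(cohort, rule, t)[0] == pytest.approx(best)

    def test_estimated_rule_never_beats_the_oracle_rule(self):
        rng = np.random.default_rng(6)
        y0, y1 = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        cohort = _potential_outcome_cohort(y0, y1)
        t = 0.1
        oracle_rule = [HYDRO if d > t else CONTROL for d in (y0 - y1)]
        noisy = (y0 - y1) + rng.normal(0, 1, 50)
        estimated_rule = [HYDRO if d > t else CONTROL for d in noisy]
        assert (oracle_net_benefit(cohort, estimated_rule, t)[0]
                <= oracle_net_benefit(cohort, oracle_rule, t)[0] + 1e-12)

    def test_requires_potential_outcomes_and_known_arms(self):
        cohort = _potential_outcome_cohort([1, 0], [0, 1])
        stripped = TrialCohort(cohort.data.drop(columns=["risk_control"]), ())
        with pytest.raises(ValueError, match="potential"):
            oracle_net_benefit(stripped, [CONTROL, CONTROL], 0.1)
        with pytest.raises(ValueError, match="unknown arm"):
            oracle_net_benefit(cohort, ["prednisone", CONTROL], 0.1)


class TestCurves:
    def _strategies(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.04, 0.08, n)
        return {"treat_none": None, "treat_all:hydro": d, "rule": d}, d

    def test_treat_none_is_identically_zero(self):
        strategies, _ = self._strategies()
        curves = net_benefit_curves(strategies, nwt_grid=[5, 10, 25],
                                    bootstrap_b=20, seed=1)
        none = curves[curves.strategy == "treat_none"]
        assert (none.net_benefit == 0).all() and (none.treated_fraction == 0).all()

    def test_treat_all_curve_matches_the_pointwise_formula(self):
        strategies, d = self._strategies()
        curves = net_benefit_curves(strategies, nwt_grid=[4, 20], bootstrap_b=5,
                                    seed=1)
        sub = curves[curves.strategy == "treat_all:hydro"].set_index("nwt")
        for nwt in (4, 20):
            assert sub.loc[nwt, "net_benefit"] == pytest.approx(
                net_benefit_treat_all(d.mean(), 1 / nwt))
            assert sub.loc[nwt, "treated_fraction"] == 1.0

    def test_bands_are_seed_reproducible_and_order_invariant(self):
        strategies, d = self._strategies(seed=3)
        kw = dict(nwt_grid=[10, 25], bootstrap_b=40, seed=9)
        a = net_benefit_curves(strategies, **kw)
        b = net_benefit_curves(strategies, **kw)
        pd.testing.assert_frame_equal(a, b)
        perm = np.random.default_rng(0).permutation(len(d))
        shuffled = {"treat_none": None, "treat_all:hydro": d[perm], "rule": d[perm]}
        c = net_benefit_curves(shuffled, **kw)
        pd.testing.assert_frame_equal(a, c)

    def test_tiny_bootstrap_warns_and_omits_bands(self):
        strategies, _ = self._strategies()
        with pytest.warns(UserWarning, match="bootstrap"):
            curves = net_benefit_curves(strategies, nwt_grid=[10], bootstrap_b=1)
        assert curves["ci_lo"].isna().all()

    def test_empty_grid_is_rejected(self):
        with pytest.raises(ValueError):
            net_benefit_curves({"treat_none": None}, nwt_grid=[])
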