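import numpy as np
import pytest

from steroid_ite.cohort import HYDRO
from steroid_ite.evaluation import roc_auc
from steroid_ite.learners import LearnerSpec, build_learner, compact_library
from steroid_ite.super_learner import (
    CrossValidationPlan, SuperLearnerClassifier, fit_super_learner,
    optimize_weights, predict_risk,
)


def _toy(n=400, p=6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    logits = X[:, 0] - 0.8 * X[:, 1] + 0.5 * X[:, 2]
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    return X, y


class TestWeightOptimization:
    def test_single_column_gets_full_weight(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        w = optimize_weights(rng.random((50, 1)), y)
        assert w.tolist() == [1.0]

    def test_perfect_column_dominates_noise_column(self):
        # column 0 separates perfectly; column 1 is loud noise, so any
        # appreciable mixing destroys the separation
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 50)
        perfect = y + 0.01 * rng.random(100)
        noise = 50 * rng.normal(size=100)
        level1 = np.column_stack([perfect, noise])
        w = optimize_weights(level1, y)
        assert w[0] >= 0.99
        assert roc_auc(level1 @ w, y) == 1.0

    def test_matches_brute_force_grid_on_two_columns(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 120)
        level1 = np.column_stack([y * 0.5 + rng.random(120) * 0.8,
                                  rng.random(120)])
        w = optimize_weights(level1, y)
        grid_best = max(roc_auc(level1 @ np.array([a, 1 - a]), y)
                        for a in np.linspace(0, 1, 201))
        assert roc_auc(level1 @ w, y) >= grid_best - 1e-12

    def test_constant_column_never_changes_the_optimum(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        level1 = rng.random((100, 2))
        base = roc_auc(level1 @ optimize_weights(level1, y), y)
        with_const = np.column_stack([level1, np.full(100, 0.5)])
        aug = roc_auc(with_const @ optimize_weights(with_const, y), y)
        assert aug == pytest.approx(base, abs=1e-12)

    def test_constant_outcome_is_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            optimize_weights(np.random.default_rng(0).random((20, 2)),
                             np.ones(20))


class TestSuperLearnerClassifier:
    def test_degenerate_single_learner_library(self):
        X, y = _toy()
        lib = (LearnerSpec("logistic", "logistic"),)
        sl = SuperLearnerClassifier(library=lib, random_state=0).fit(X, y)
        assert sl.weights_.tolist() == [1.0]
        solo = build_learner(lib[0], 0).fit(X, y)
        assert np.allclose(sl.predict_proba(X)[:, 1],
                           np.clip(solo.predict_proba(X)[:, 1], 1e-3, 1 - 1e-3))

    def test_duplicated_learner_leaves_predictions_unchanged(self):
        X, y = _toy(seed=4)
        single = SuperLearnerClassifier(
            library=(LearnerSpec("a", "logistic"), LearnerSpec("rf", "random-forest",
                     {"n_estimators": 50})), random_state=0).fit(X, y)
        doubled = SuperLearnerClassifier(
            library=(LearnerSpec("a", "logistic"), LearnerSpec("a2", "logistic"),
                     LearnerSpec("rf", "random-forest", {"n_estimators": 50})),
            random_state=0).fit(X, y)
        assert np.allclose(single.predict_proba(X), doubled.predict_proba(X))

    def test_ensemble_never_below_best_single_learner(self):
        X, y = _toy(seed=5)
        sl = SuperLearnerClassifier(library=compact_library(), random_state=0).fit(X, y)
        col_aucs = [roc_auc(sl.level1_[:, j], y) for j in range(sl.level1_.shape[1])]
        assert sl.cv_auc_ >= max(col_aucs) - 1e-12

    def test_refit_with_same_seed_is_deterministic(self):
        X, y = _toy(seed=6)
        lib = compact_library()
        w1 = SuperLearnerClassifier(library=lib, random_state=3).fit(X, y).weights_
        w2 = SuperLearnerClassifier(library=lib, random_state=3).fit(X, y).weights_
        assert np.allclose(w1, w2, atol=1e-6)

    def test_failing_learner_is_dropped_with_warning(self):
        X, y = _toy()
        lib = (LearnerSpec("logistic", "logistic"),
               LearnerSpec("broken", "kernel-svm", {"C": -1.0}))
        with pytest.warns(UserWarning, match="broken"):
            sl = SuperLearnerClassifier(library=lib, random_state=0).fit(X, y)
        assert sl.learner_names_ == ("logistic",)

    def test_all_learners_failing_is_a_hard_error(self):
        X, y = _toy()
        lib = (LearnerSpec("broken", "kernel-svm", {"C": -1.0}),)
        with pytest.warns(UserWarning):
            with pytest.raises(RuntimeError, match="every learner"):
                SuperLearnerClassifier(library=lib, random_state=0).fit(X, y)

    def test_discrete_metalearner_puts_all_weight_on_one_column(self):
        X, y = _toy(seed=7)
        sl = SuperLearnerClassifier(library=compact_library(), meta="discrete",
                                    random_state=0).fit(X, y)
        assert sorted(sl.weights_)[-1] == 1.0 and sl.weights_.sum() == 1.0


class TestCohortInterface:
    def test_counterfactual_override_equals_factual_on_own_arm(self, cohort800,
                                                               compact_fsl):
        own = (cohort800.data["arm"] == HYDRO).to_numpy()
        factual = predict_risk(compact_fsl, cohort800)
        forced = predict_risk(compact_fsl, cohort800, arm_override=HYDRO)
        assert np.allclose(factual[own], forced[own])
        assert np.all((factual > 0) & (factual < 1))

    def test_level1_rows_are_honest_out_of_fold_predictions(self, compact_fsl):
        lvl = compact_fsl.level1
        assert np.isfinite(lvl).all()
        assert ((lvl >= 0) & (lvl <= 1)).all()
        w = compact_fsl.weights
        assert np.all(w >= 0) and w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_plan_and_outcome_are_rejected(self, cohort800):
        with pytest.raises(ValueError):
            CrossValidationPlan(n_folds=1)
        with pytest.raises(ValueError, match="outcome"):
            fit_super_learner(cohort800, outcome="y365")
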