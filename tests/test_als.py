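"""Implicit-feedback ALS: cost function, alternating solves, recommendation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from abarec.als import (
    ConfidenceParams,
    ImplicitALS,
    InteractionMatrix,
    als_fit,
    build_interactions,
    confidence,
    implicit_cost,
    mask_split,
    sparsity_ratio,
)
from abarec.cohort import TreatmentCode
from abarec.exceptions import ConfigError, EmptyInteractionError, MissingFeatureError
from abarec.simulate import planted_block_interactions


def _matrix(R, level="domain"):
    R = np.asarray(R, dtype=float)
    ids = tuple(f"u{i}" for i in range(R.shape[0]))
    items = tuple(TreatmentCode(j + 1) for j in range(R.shape[1]))
    return InteractionMatrix(ids, items, R, level)


def brute_force_cost(X, Y, M, params):
    """Independent term-by-term summation of the objective (double loop)."""
    total = 0.0
    for u in range(M.shape[0]):
        for i in range(M.shape[1]):
            r = M.ratings[u, i]
            if not params.all_cells and r == 0:
                continue
            p = 1.0 if r > 0 else 0.0
            c = 1.0 + params.alpha * r
            total += c * (p - float(X[u] @ Y[i])) ** 2
    for u in range(M.shape[0]):
        total += params.regularization * float(X[u] @ X[u])
    for i in range(M.shape[1]):
        total += params.regularization * float(Y[i] @ Y[i])
    return total


class TestConfidence:
    def test_zero_rating_gives_unit_confidence(self):
        assert confidence(0.0, 40.0) == 1.0

    def test_linear_in_rating(self):
        assert confidence(1.0, 40.0) == 41.0

    def test_alpha_must_be_positive(self):
        with pytest.raises(ConfigError):
            confidence(1.0, 0.0)
        with pytest.raises(ConfigError):
            confidence(-1.0, 40.0)


class TestInteractionMatrix:
    def test_built_from_plans_with_rescaled_srs2_ratings(self, tiny_cohort):
        M = build_interactions(tiny_cohort, "domain")
        # four plans over domains {1,2},{2,4},{2,5},{1,2} -> items 1,2,4,5
        assert [c.render() for c in M.item_ids] == ["1", "2", "4", "5"]
        assert (M.ratings > 0).sum() == 8
        assert M.preferences.sum() == 8
        # ratings carry the participant's SRS-2 total rescaled to [1, 10]
        assert M.ratings.min() >= 0 and M.ratings[M.ratings > 0].max() <= 10

    def test_participant_without_plan_keeps_zero_row(self, tiny_cohort, caplog):
        import logging

        cohort_no_plan = type(tiny_cohort)(
            tiny_cohort.participants, tiny_cohort.profiles,
            tiny_cohort.plans[:3], tiny_cohort.mastery,
        )
        with caplog.at_level(logging.WARNING, logger="abarec.als"):
            M = build_interactions(cohort_no_plan, "domain")
        assert (M.ratings[3] == 0).all()
        assert any("P004" in rec.message for rec in caplog.records)

    def test_inverted_rating_range_rejected(self, tiny_cohort):
        with pytest.raises(ConfigError):
            build_interactions(tiny_cohort, "domain", rating_range=(10.0, 1.0))

    def test_no_plans_is_empty_interaction_error(self, tiny_cohort):
        bare = type(tiny_cohort)(tiny_cohort.participants, tiny_cohort.profiles,
                                 [], tiny_cohort.mastery)
        with pytest.raises(EmptyInteractionError):
            build_interactions(bare, "domain")


class TestSparsity:
    def test_three_of_fifty_nonzero_is_094(self):
        R = np.zeros((5, 10))
        R[0, 0] = R[1, 3] = R[2, 7] = 1.0
        assert sparsity_ratio(_matrix(R)) == pytest.approx(0.94)

    def test_all_zero_is_one_dense_is_zero(self):
        assert sparsity_ratio(_matrix(np.zeros((3, 3)))) == 1.0
        assert sparsity_ratio(_matrix(np.ones((3, 3)))) == 0.0


class TestMaskSplit:
    def test_deterministic_and_proportional(self):
        rng = np.random.default_rng(0)
        R = np.zeros((10, 20))
        for u in range(10):
            R[u, rng.choice(20, size=10, replace=False)] = 5.0
        M = _matrix(R)
        s1 = mask_split(M, 0.2, seed=1)
        s2 = mask_split(M, 0.2, seed=1)
        assert s1.held_out == s2.held_out
        assert len(s1.held_out) == 20  # 20% of 100 nonzeros, stratified 2/user
        for u, j in s1.held_out:
            assert M.ratings[u, j] > 0 and s1.train.ratings[u, j] == 0

    def test_user_with_single_interaction_keeps_it(self):
        R = np.zeros((2, 4))
        R[0, 1] = 3.0
        R[1, :] = 3.0
        split = mask_split(_matrix(R), 0.5, seed=0)
        assert all(u != 0 for u, _ in split.held_out)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, 1.5])
    def test_fraction_must_be_strictly_inside_unit_interval(self, fraction):
        with pytest.raises(ConfigError):
            mask_split(_matrix(np.ones((2, 2))), fraction, seed=0)


class TestImplicitCost:
    def test_zero_factors_closed_form(self):
        M = _matrix([[2.0, 0.0], [0.0, 1.0]])
        params = ConfidenceParams(alpha=3.0, regularization=0.0)
        X, Y = np.zeros((2, 2)), np.zeros((2, 2))
        # sum of c_ui * p_ui^2 over cells = (1+3*2) + (1+3*1)
        assert implicit_cost(X, Y, M, params) == pytest.approx(7.0 + 4.0)

    def test_exact_reconstruction_costs_only_regularization(self):
        M = _matrix([[1.0, 1.0], [1.0, 1.0]])
        X = np.array([[1.0], [1.0]])
        Y = np.array([[1.0], [1.0]])
        params = ConfidenceParams(alpha=5.0, regularization=0.0)
        assert implicit_cost(X, Y, M, params) == pytest.approx(0.0)

    @pytest.mark.parametrize("all_cells", [True, False])
    def test_matches_term_by_term_oracle(self, all_cells):
        rng = np.random.default_rng(42)
        for _ in range(10):
            R = np.where(rng.random((4, 3)) < 0.5, rng.uniform(1, 10, (4, 3)), 0.0)
            X = rng.standard_normal((4, 2))
            Y = rng.standard_normal((3, 2))
            params = ConfidenceParams(alpha=float(rng.uniform(1, 50)),
                                      regularization=0.1, all_cells=all_cells)
            assert implicit_cost(X, Y, _matrix(R), params) == pytest.approx(
                brute_force_cost(X, Y, _matrix(R), params), abs=1e-10
            )

    def test_shape_mismatch_rejected(self):
        M = _matrix(np.ones((2, 3)))
        with pytest.raises(ConfigError):
            implicit_cost(np.zeros((2, 2)), np.zeros((2, 2)), M, ConfidenceParams())


class TestAlsFit:
    def test_cost_never_increases_across_sweeps(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            R = np.where(rng.random((8, 6)) < 0.4, rng.uniform(1, 10, (8, 6)), 0.0)
            params = ConfidenceParams(alpha=10.0, regularization=0.1, n_factors=3,
                                      n_iterations=25, seed=trial, tol=0.0)
            res = ImplicitALS(_matrix(R), params).fit()
            log = np.asarray(res.training_log)
            assert (np.diff(log) <= 1e-9).all()

    def test_converged_cost_matches_general_purpose_optimizer(self):
        R = np.array([[2.0, 0.0, 1.0], [0.0, 3.0, 0.0], [1.5, 0.0, 0.0]])
        M = _matrix(R)
        params = ConfidenceParams(alpha=2.0, regularization=0.1, n_factors=2,
                                  n_iterations=500, seed=5, tol=1e-12)
        als_cost = ImplicitALS(M, params).fit().training_log[-1]

        rng = np.random.default_rng(params.seed)
        x0 = 0.01 * rng.standard_normal(12)  # same init as the model

        def objective(v):
            return implicit_cost(v[:6].reshape(3, 2), v[6:].reshape(3, 2), M, params)

        opt = minimize(objective, x0, method="L-BFGS-B",
                       options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12})
        assert als_cost == pytest.approx(opt.fun, abs=1e-4)

    def test_zero_iterations_returns_initialization(self):
        M = _matrix(np.eye(3))
        params = ConfidenceParams(n_factors=2, n_iterations=0, seed=9)
        res = ImplicitALS(M, params).fit()
        assert len(res.training_log) == 1
        rng = np.random.default_rng(9)
        np.testing.assert_allclose(res.user_factors, 0.01 * rng.standard_normal((3, 2)))

    def test_fit_is_seed_deterministic(self):
        M = planted_block_interactions(n_users=30, seed=2)
        params = ConfidenceParams(n_factors=4, n_iterations=10, seed=3)
        r1 = ImplicitALS(M, params).fit()
        r2 = ImplicitALS(M, params).fit()
        np.testing.assert_array_equal(r1.user_factors, r2.user_factors)
        assert r1.training_log == r2.training_log

    def test_als_fit_wrapper_uses_mask_train(self):
        M = planted_block_interactions(n_users=20, n_blocks=2, items_per_block=10,
                                       positives_per_user=5, seed=0)
        split = mask_split(M, 0.2, seed=1)
        res = als_fit(M, ConfidenceParams(n_factors=2, n_iterations=5, seed=0), mask=split)
        assert res.interactions is split.train
        assert res.validation is split


class TestRecommend:
    def _fitted(self, R, n_factors=2, seed=0):
        M = _matrix(R)
        params = ConfidenceParams(n_factors=n_factors, n_iterations=20, seed=seed)
        return M, ImplicitALS(M, params).fit()

    def test_more_than_candidates_returns_all_ranked(self):
        M, res = self._fitted([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
        recs = res.recommend("u0", n=10)
        assert len(recs) == 2  # item 1 observed, two candidates left
        assert recs[0].score >= recs[1].score

    def test_equal_scores_tie_break_by_ascending_code(self):
        M = _matrix(np.zeros((2, 3)))
        params = ConfidenceParams(n_factors=1, n_iterations=0, seed=0)
        res = ImplicitALS(M, params).fit()
        res.item_factors = np.ones((3, 1))
        res.user_factors = np.ones((2, 1))
        recs = res.recommend("u0", n=3, exclude_observed=False)
        assert [r.code.render() for r in recs] == ["1", "2", "3"]

    def test_unknown_user_rejected(self):
        M, res = self._fitted(np.eye(2))
        with pytest.raises(MissingFeatureError):
            res.recommend("stranger", n=1)

    def test_masked_positive_beats_cross_block_items(self):
        """Block structure: the held-out positive outranks every item of the
        other block for nearly all users (rank-2 factorisation, 2 blocks)."""
        ok = total = 0
        for seed in range(3):
            M = planted_block_interactions(n_users=100, n_blocks=2, items_per_block=20,
                                           positives_per_user=10, seed=seed)
            rng = np.random.default_rng(seed + 50)
            train = M.ratings.copy()
            masked = {}
            for u in range(M.shape[0]):
                j = int(rng.choice(np.flatnonzero(train[u])))
                masked[u] = j
                train[u, j] = 0.0
            Mt = InteractionMatrix(M.patient_ids, M.item_ids, train, M.level)
            res = ImplicitALS(Mt, ConfidenceParams(n_factors=2, n_iterations=30,
                                                   seed=seed)).fit()
            pred = res.predicted()
            for u in range(M.shape[0]):
                own_block = (masked[u] // 20) * 20
                cross = [j for j in range(40)
                         if not own_block <= j < own_block + 20 and train[u, j] == 0]
                ok += pred[u, masked[u]] > pred[u, cross].max()
                total += 1
        assert ok / total >= 0.90
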