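"""Observation weights, weighted ROC/AUC, theta, rank weights, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from wrforest import (
    MembershipMatrix,
    aggregate,
    observation_weights,
    rank_trees,
    rank_weights,
    score_trees,
    tree_performance,
    weighted_auc,
    weighted_roc,
)
from conftest import pair_count_auc

HYP = settings(deadline=None, derandomize=True, max_examples=60)


class TestObservationWeights:
    def test_mean_absolute_oob_residual(self):
        # row 0: OOB in trees 0 and 1 with probs 0.8, 0.6 and label 1 -> 0.3
        probs = np.array([[0.8, 0.6, 0.1], [0.2, 0.9, 0.5]])
        counts = np.array([[0, 0, 2], [1, 0, 1]])
        ow = observation_weights(probs, np.array([1, 0]), MembershipMatrix(counts))
        np.testing.assert_allclose(ow.w_obs, [(0.2 + 0.4) / 2, 0.9])
        np.testing.assert_array_equal(ow.n_oob_trees, [2, 1])

    def test_perfect_oob_predictions_give_zero_weight(self):
        probs = np.array([[1.0, 1.0], [0.0, 0.0]])
        counts = np.array([[0, 1], [1, 0]])
        ow = observation_weights(probs, np.array([1, 0]), MembershipMatrix(counts))
        np.testing.assert_array_equal(ow.w_obs, [0.0, 0.0])

    def test_never_oob_falls_back_to_mean(self):
        probs = np.array([[0.5, 0.5], [1.0, 0.2], [0.4, 0.0]])
        counts = np.array([[1, 2], [0, 1], [1, 0]])  # row 0 never OOB
        with pytest.warns(UserWarning, match="never out-of-bag"):
            ow = observation_weights(
                probs, np.array([1, 1, 0]), MembershipMatrix(counts)
            )
        defined_mean = np.mean([abs(1 - 1.0), abs(0 - 0.0)])
        assert ow.w_obs[0] == defined_mean
        assert ow.fallback[0] and not ow.fallback[1:].any()
        assert ow.n_oob_trees[0] == 0

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        probs = rng.random((30, 15))
        counts = rng.integers(0, 3, size=(30, 15))
        ow = observation_weights(
            probs, rng.integers(0, 2, 30), MembershipMatrix(counts)
        )
        assert (ow.w_obs >= 0).all() and (ow.w_obs <= 1).all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            observation_weights(
                np.empty((0, 0)), np.array([]), MembershipMatrix(np.empty((0, 0)))
            )


class TestWeightedROC:
    def test_curve_endpoints(self):
        roc = weighted_roc(
            np.array([0.9, 0.8, 0.4, 0.2]), np.array([1, 1, 0, 0]), None
        )
        assert roc.thresholds[0] == np.inf
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_perfect_separation_gives_unit_auc(self):
        assert weighted_auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]) == 1.0

    def test_perfect_inversion_gives_zero_auc(self):
        assert weighted_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_matches_weighted_pair_count_oracle_example(self):
        s = np.array([0.9, 0.4, 0.8, 0.2])
        y = np.array([1, 0, 1, 0])
        w = np.array([2.0, 1.0, 1.0, 2.0])
        assert weighted_auc(s, y, w) == pytest.approx(
            pair_count_auc(s, y, w), abs=1e-12
        )

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_pair_count_oracle_random(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 20))
        y = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        s = np.round(rng.random(n), 1)  # coarse grid to exercise ties
        w = rng.random(n) * 2
        assert weighted_auc(s, y, w) == pytest.approx(
            pair_count_auc(s, y, w), abs=1e-12
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_equal_weights_match_rank_based_auc(self, trial):
        rng = np.random.default_rng(100 + trial)
        y = np.r_[1, 0, rng.integers(0, 2, 13)]
        s = rng.random(15)
        assert weighted_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        y = np.r_[1, 0, rng.integers(0, 2, 10)]
        s = rng.random(12)
        w = rng.random(12)
        a = weighted_auc(s, y, w)
        assert weighted_auc(np.exp(3 * s), y, w) == pytest.approx(a, abs=1e-12)
        assert weighted_auc(2 * s - 5, y, w) == pytest.approx(a, abs=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            weighted_auc([0.1, 0.9], [0, 1], [-1.0, 1.0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            weighted_auc([0.1, 0.9], [1, 1])

    def test_zero_class_weight_falls_back_to_uniform(self):
        s = np.array([0.9, 0.8, 0.4, 0.2])
        y = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning, match="zero total"):
            auc = weighted_auc(s, y, np.array([0.0, 0.0, 1.0, 1.0]))
        assert auc == 1.0


class TestTreePerformance:
    def test_balanced_tree_midpoint(self):
        assert tree_performance(0.70, 0.70, alpha=0.5) == pytest.approx(0.350)

    def test_pure_stability_scores_zero_for_stable_tree(self):
        for x in (0.1, 0.5, 0.95):
            assert tree_performance(x, x, alpha=1.0) == 0.0

    def test_penalized_unstable_tree(self):
        # -0.5 * |0.90 - 0.80| + 0.5 * 0.80
        assert tree_performance(0.90, 0.80, alpha=0.5) == pytest.approx(0.350)

    @pytest.mark.parametrize(
        "inb,oob,alpha", [(-0.1, 0.5, 0.5), (0.5, 1.1, 0.5), (0.5, 0.5, 2.0)]
    )
    def test_out_of_range_rejected(self, inb, oob, alpha):
        with pytest.raises(ValueError):
            tree_performance(inb, oob, alpha)

    @HYP
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    def test_theta_bounded(self, inb, oob, alpha):
        theta = tree_performance(inb, oob, alpha)
        assert -alpha - 1e-12 <= theta <= 1 - alpha + 1e-12


class TestRankTrees:
    def test_largest_theta_gets_rank_one(self):
        ranks = rank_trees(np.array([0.350, 0.325, 0.450, 0.425]))
        np.testing.assert_array_equal(ranks, [3, 4, 1, 2])

    def test_ties_broken_by_tree_index(self):
        np.testing.assert_array_equal(rank_trees(np.full(4, 0.2)), [1, 2, 3, 4])

    def test_single_tree(self):
        np.testing.assert_array_equal(rank_trees(np.array([0.9])), [1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_trees(np.array([]))


class TestRankWeights:
    def test_four_tree_example(self):
        tw = rank_weights(np.array([3, 4, 1, 2]), p_exp=2)
        np.testing.assert_allclose(tw.weights, [4 / 30, 1 / 30, 16 / 30, 9 / 30])

    def test_p_zero_gives_equal_weights(self):
        tw = rank_weights(np.array([5, 2, 4, 1, 3]), p_exp=0)
        np.testing.assert_array_equal(tw.weights, np.full(5, 0.2))

    def test_linear_rank_sum_case(self):
        np.testing.assert_allclose(
            rank_weights(np.array([1, 2]), p_exp=1).weights, [2 / 3, 1 / 3]
        )

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            rank_weights(np.array([1, 1, 3]), p_exp=1)

    def test_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            rank_weights(np.array([1, 2]), p_exp=-0.5)

    @HYP
    @given(
        st.integers(1, 30),
        # p = 0 exactly, or a working-range exponent: subnormal p makes
        # k^p collapse to 1.0 in floats, voiding strictness vacuously
        st.one_of(st.just(0.0), st.floats(0.05, 6)),
        st.randoms(use_true_random=False),
    )
    def test_sum_one_and_monotone_in_rank(self, ntree, p_exp, rnd):
        ranks = np.array(rnd.sample(range(1, ntree + 1), ntree))
        tw = rank_weights(ranks, p_exp)
        assert abs(tw.weights.sum() - 1.0) < 1e-12
        order = np.argsort(ranks)
        diffs = np.diff(tw.weights[order])
        assert (diffs <= 1e-15).all()
        if p_exp > 0 and ntree > 1:
            assert (diffs < 0).all()

    @HYP
    @given(st.integers(2, 25), st.randoms(use_true_random=False))
    def test_concentration_nondecreasing_in_p(self, ntree, rnd):
        """Larger p makes the weight distribution steeper on a fixed ranking."""
        ranks = np.array(rnd.sample(range(1, ntree + 1), ntree))
        maxima = [
            rank_weights(ranks, p).weights.max() for p in (0, 0.5, 1, 2, 4)
        ]
        assert (np.diff(maxima) >= -1e-15).all()


class TestAggregate:
    def test_equal_weights_reduce_to_mean(self):
        probs = np.random.default_rng(1).random((20, 7))
        w = np.full(7, 1 / 7)
        np.testing.assert_allclose(
            aggregate(probs, w).scores,
            aggregate(probs, method="mean").scores,
            atol=1e-15,
        )

    def test_one_hot_weight_selects_column(self):
        probs = np.random.default_rng(2).random((10, 4))
        w = np.array([0.0, 0.0, 1.0, 0.0])
        np.testing.assert_array_equal(aggregate(probs, w).scores, probs[:, 2])

    def test_vote_fraction(self):
        scores = aggregate(
            np.array([[0.6, 0.7, 0.4]]), method="vote", vote_cutoff=0.5
        ).scores
        assert scores[0] == pytest.approx(2 / 3)

    def test_weighted_requires_weights(self):
        with pytest.raises(ValueError, match="weights"):
            aggregate(np.ones((2, 3)), method="weighted")

    def test_literal_scale_is_rank_preserving(self):
        probs = np.random.default_rng(3).random((15, 5))
        w = rank_weights(np.array([2, 1, 4, 3, 5]), 2.0)
        plain = aggregate(probs, w).scores
        literal = aggregate(probs, w, literal_scale=True).scores
        np.testing.assert_allclose(literal, plain / 5)

    def test_scores_bounded(self):
        probs = np.random.default_rng(4).random((25, 6))
        w = rank_weights(np.array([1, 2, 3, 4, 5, 6]), 3.0)
        s = aggregate(probs, w).scores
        assert (s >= 0).all() and (s <= 1).all()


class TestScoreTrees:
    def test_degenerate_single_class_samples_score_half(self):
        """A tree whose OOB rows are single-class is neither rewarded nor excluded."""
        probs = np.array([[0.9, 0.1], [0.8, 0.9], [0.2, 0.7], [0.1, 0.4]])
        # tree 0: rows 0,1 OOB (both positive) -> degenerate
        counts = np.array([[0, 1], [0, 1], [2, 0], [2, 2]])
        labels = np.array([1, 1, 0, 1])
        from wrforest import observation_weights as ow_fn

        ow = ow_fn(probs, labels, MembershipMatrix(counts))
        with pytest.warns(UserWarning, match="degenerate"):
            perf = score_trees(
                probs, labels, MembershipMatrix(counts), ow, alpha=0.5
            )
        assert perf.auc_oob[0] == 0.5
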