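"""Uncertainty core: mean prediction, decomposition, CL masks, losses, KL."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from radstab.errors import InputError, ParameterError, UndefinedDivergenceError
from radstab.uncmask import (
    ProbStack,
    confidence_masks,
    dice_loss,
    dice_plus_loss,
    dice_score,
    histogram_kl,
    kl_uncertainty_separability,
    mean_prediction,
    uncertainty_decompose,
)

prob_stacks = hnp.arrays(
    dtype=float,
    shape=st.tuples(
        st.integers(2, 6), st.integers(1, 4), st.integers(1, 4), st.integers(1, 4)
    ),
    elements=st.floats(0.0, 1.0),
)


class TestMeanPrediction:
    def test_two_replicate_average_and_tie_to_foreground(self):
        stack = np.array([0.2, 0.8]).reshape(2, 1, 1, 1)
        mp = mean_prediction(stack)
        assert mp.pbar.item() == pytest.approx(0.5)
        assert bool(mp.mp_mask.item()) is True  # tie at 0.5 -> foreground

    def test_constant_stack_is_identity(self, rng):
        c = 0.37
        stack = np.full((5, 3, 3, 3), c)
        assert np.allclose(mean_prediction(stack).pbar, c)

    def test_matches_looped_voxelwise_mean(self, rng):
        stack = rng.random((10, 8, 8))
        expected = np.empty((8, 8))
        for i in range(8):
            for j in range(8):
                expected[i, j] = sum(stack[t, i, j] for t in range(10)) / 10
        assert np.abs(mean_prediction(stack).pbar - expected).max() <= 1e-12

    def test_rejects_single_replicate(self):
        with pytest.raises(InputError):
            mean_prediction(np.zeros((1, 2, 2)))


class TestUncertaintyDecompose:
    @pytest.mark.parametrize(
        "value, expected",
        [(1.0, (0.0, 0.0, 0.0)), (0.5, (0.25, 0.0, 0.25))],
    )
    def test_constant_stacks(self, value, expected):
        u = uncertainty_decompose(np.full((4, 2, 2), value))
        got = (u.aleatoric.max(), u.epistemic.max(), u.predictive.max())
        assert got == pytest.approx(expected)

    def test_half_zero_half_one_is_pure_epistemic(self):
        stack = np.concatenate([np.zeros((3, 2, 2)), np.ones((3, 2, 2))])
        u = uncertainty_decompose(stack)
        assert np.allclose(u.aleatoric, 0.0)
        assert np.allclose(u.epistemic, 0.25)
        assert np.allclose(u.predictive, 0.25)

    @settings(deadline=None, derandomize=True)
    @given(prob_stacks)
    def test_predictive_identity_and_bounds(self, values):
        u = uncertainty_decompose(values)
        pbar = values.mean(axis=0)
        assert np.abs(u.predictive - (u.aleatoric + u.epistemic)).max() <= 1e-12
        assert np.abs(u.predictive - pbar * (1 - pbar)).max() <= 1e-12
        assert u.aleatoric.min() >= 0 and u.epistemic.min() >= 0
        assert u.predictive.max() <= 0.25 + 1e-15


class TestConfidenceMasks:
    def test_vote_count_worked_examples(self):
        # one voxel foreground in 5/50 replicates, another in 50/50
        stack = np.zeros((50, 1, 2))
        stack[:5, 0, 0] = 0.9
        stack[:, 0, 1] = 0.9
        cl = confidence_masks(stack)
        assert cl[10.0][0, 0] and not cl[20.0][0, 0]
        assert cl[100.0][0, 1]

    @settings(deadline=None, derandomize=True)
    @given(prob_stacks)
    def test_nesting(self, values):
        cl = confidence_masks(values)
        ths = cl.thresholds
        for lo, hi in zip(ths, ths[1:]):
            assert not np.any(cl[hi] & ~cl[lo])  # CL_hi subset of CL_lo

    def test_majority_vote_agreement_just_above_half(self, rng):
        stack = rng.random((9, 4, 4))
        cl = confidence_masks(stack, thresholds=[51.0])
        majority = (stack >= 0.5).sum(axis=0) > 9 / 2
        assert np.array_equal(cl[51.0], majority)

    @pytest.mark.parametrize("bad", [0.0, -5.0, 101.0])
    def test_threshold_range(self, bad, rng):
        with pytest.raises(ParameterError):
            confidence_masks(rng.random((3, 2, 2)), thresholds=[bad])


class TestDice:
    def test_score_limits(self):
        a = np.zeros((4, 4), dtype=bool)
        a[:2] = True
        assert dice_score(a, a) == 1.0
        assert dice_score(a, ~a) == 0.0
        assert dice_score(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 1.0

    def test_score_counts(self):
        a = np.array([1, 1, 0, 0], bool)
        b = np.array([1, 0, 1, 0], bool)
        assert dice_score(a, b) == pytest.approx(0.5)

    def test_score_shape_mismatch(self):
        with pytest.raises(InputError):
            dice_score(np.zeros((2, 2), bool), np.zeros((3, 2), bool))

    def test_loss_hand_value(self):
        assert dice_loss([0.5, 0.5], [1, 0]) == pytest.approx(0.5, abs=1e-5)

    def test_loss_perfect_and_empty(self):
        y = np.array([1.0, 0.0, 1.0])
        assert dice_loss(y, y) == pytest.approx(0.0, abs=1e-6)
        assert dice_loss(np.zeros(3), np.zeros(3)) == pytest.approx(0.0, abs=1e-6)

    def test_plus_hand_value_gamma2(self):
        # 1 - 1/(1 + 0.25 + 0.25) = 1/3
        assert dice_plus_loss([0.5, 0.5], [1, 0], gamma=2) == pytest.approx(
            1 / 3, abs=1e-5
        )

    def test_plus_reduces_to_dice_at_gamma1(self, rng):
        for _ in range(100):
            shape = tuple(rng.integers(2, 6, size=2))
            p = rng.random(shape)
            y = (rng.random(shape) < 0.5).astype(float)
            assert abs(
                dice_plus_loss(p, y, gamma=1.0) - dice_loss(p, y)
            ) <= 1e-12

    def test_plus_gamma_validation(self):
        with pytest.raises(ParameterError):
            dice_plus_loss([0.5], [1], gamma=0.0)


class TestKL:
    def test_two_bin_closed_form(self):
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert histogram_kl([0.5, 0.5], [0.25, 0.75]) == pytest.approx(expected)

    def test_identical_histograms_zero(self):
        assert histogram_kl([3, 1, 4], [3, 1, 4]) == 0.0

    def test_null_distribution_small(self, rng):
        n = 10**5
        u = np.concatenate([rng.random(n), rng.random(n)])
        pred = np.concatenate([np.ones(n), np.zeros(n)]).astype(bool)
        gt = np.ones(2 * n, dtype=bool)  # first half correct, second wrong
        kl = kl_uncertainty_separability(u, pred, gt, n_bins=20)
        assert 0.0 <= kl <= 0.05

    def test_undefined_without_errors(self):
        m = np.ones((3, 3), bool)
        with pytest.raises(UndefinedDivergenceError):
            kl_uncertainty_separability(np.random.rand(3, 3), m, m)
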