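import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pearspec import lpmtf as lp
from pearspec.lpmtf import (
    build_pyramids,
    fuse_pyramid,
    lpmtf,
    mtf_expand,
    paa,
    quantile_discretize,
    transition_matrix,
)


def brute_force_transitions(states, q):
    counts = np.zeros((q, q))
    for a, b in zip(states[:-1], states[1:]):
        counts[a, b] += 1
    W = np.zeros_like(counts)
    for i in range(q):
        if counts[i].sum() > 0:
            W[i] = counts[i] / counts[i].sum()
    return W


class TestPaa:
    def test_window_means(self):
        np.testing.assert_allclose(paa(np.arange(1, 11), 5), [3.0, 8.0])

    def test_1044_gives_208(self):
        assert paa(np.zeros(1044), 5).shape == (208,)

    def test_constant_preserved(self):
        np.testing.assert_allclose(paa(np.full(23, 2.5), 4), np.full(5, 2.5))

    def test_remainder_dropped(self):
        out = paa(np.array([1.0, 1.0, 1.0, 99.0]), 3)
        np.testing.assert_allclose(out, [1.0])

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            paa(np.zeros(10), 0)


class TestQuantileDiscretize:
    def test_six_point_rank_oracle(self):
        out = quantile_discretize(np.array([1.0, 2, 3, 4, 5, 6]), q=3)
        np.testing.assert_array_equal(out.states, [0, 0, 1, 1, 2, 2])

    def test_one_point_per_bin(self):
        out = quantile_discretize(np.arange(12.0), q=12)
        np.testing.assert_array_equal(out.states, np.arange(12))

    def test_q_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            quantile_discretize(np.arange(5.0), q=6)

    def test_small_q_rejected(self):
        with pytest.raises(ValueError):
            quantile_discretize(np.arange(10.0), q=1)

    def test_order_independent_of_values(self):
        """States follow ranks, not magnitudes."""
        out = quantile_discretize(np.array([10.0, 200.0, 3000.0, 4e6]), q=2)
        np.testing.assert_array_equal(out.states, [0, 0, 1, 1])

    @settings(max_examples=40, deadline=None)
    @given(hnp.arrays(np.float64, st.integers(12, 60),
                      elements=st.floats(-100, 100, allow_nan=False)))
    def test_equal_frequency_property(self, x):
        if np.unique(x).size < x.size:
            return  # ties relax the occupancy guarantee
        out = quantile_discretize(x, q=4)
        counts = np.bincount(out.states, minlength=4)
        assert counts.max() - counts.min() <= 1


class TestTransitionMatrix:
    def test_hand_counted_pairs(self):
        model = transition_matrix(np.array([0, 0, 1, 1, 2, 2]), q=3)
        expected = [[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.0, 0.0, 1.0]]
        np.testing.assert_allclose(model.W, expected)

    def test_constant_states(self):
        model = transition_matrix(np.array([1, 1, 1]), q=3)
        assert model.W[1, 1] == 1.0
        assert model.W.sum() == 1.0

    def test_rows_stochastic(self, rng):
        states = rng.integers(0, 5, 200)
        W = transition_matrix(states, q=5).W
        sums = W.sum(axis=1)
        observed = np.isin(np.arange(5), states[:-1])
        np.testing.assert_allclose(sums[observed], 1.0, atol=1e-12)
        np.testing.assert_allclose(sums[~observed], 0.0)

    @pytest.mark.parametrize("n", [2, 10, 60])
    def test_matches_brute_force(self, rng, n):
        states = rng.integers(0, 4, n)
        W = transition_matrix(states, q=4).W
        np.testing.assert_array_equal(W, brute_force_transitions(states, 4))


class TestMtfExpand:
    def test_lookup_oracle(self):
        W = np.array([[0.5, 0.5], [0.0, 1.0]])
        model = lp.TransitionModel(W=W)
        field = mtf_expand(np.array([0, 0, 1, 1]), model)
        expected = [[0.5, 0.5, 0.5, 0.5], [0.5, 0.5, 0.5, 0.5],
                    [0.0, 0.0, 1.0, 1.0], [0.0, 0.0, 1.0, 1.0]]
        np.testing.assert_array_equal(field.M, expected)

    def test_all_ones_field(self):
        model = lp.TransitionModel(W=np.array([[1.0]]))
        field = mtf_expand(np.zeros(5, dtype=int), model)
        np.testing.assert_array_equal(field.M, np.ones((5, 5)))

    def test_values_closed_under_w(self, rng):
        states = rng.integers(0, 3, 30)
        model = transition_matrix(states, q=3)
        field = mtf_expand(states, model)
        assert set(np.round(field.M.ravel(), 12)) <= set(np.round(model.W.ravel(), 12))

    def test_out_of_range_state_rejected(self):
        model = lp.TransitionModel(W=np.eye(2))
        with pytest.raises(ValueError):
            mtf_expand(np.array([0, 2]), model)

    @pytest.mark.parametrize("n", [12, 37, 60])
    def test_matches_elementwise_lookup(self, rng, n):
        states = rng.integers(0, 6, n)
        model = transition_matrix(states, q=6)
        M = mtf_expand(states, model).M
        for i in range(n):
            for j in range(n):
                assert M[i, j] == model.W[states[i], states[j]]


class TestPyramids:
    def test_constant_image_gives_zero_laplacians(self):
        stack = build_pyramids(np.full((64, 64), 3.3))
        for level in stack.laplacian:
            np.testing.assert_allclose(level, 0.0, atol=1e-12)

    def test_reconstruction_oracle(self, rng):
        img = rng.uniform(0, 1, (64, 64))
        stack = build_pyramids(img)
        recon = stack.gaussian[-1]
        for k in range(len(stack.laplacian) - 1, -1, -1):
            recon = stack.laplacian[k] + lp._upsample(recon, stack.gaussian[k].shape[0])
        np.testing.assert_allclose(recon, img, atol=1e-10)

    def test_level_sides_halve(self):
        stack = build_pyramids(np.zeros((208, 208)))
        assert [g.shape[0] for g in stack.gaussian] == [208, 104, 52, 26]

    def test_odd_sides_ceil(self):
        stack = build_pyramids(np.zeros((25, 25)), levels=2)
        assert [g.shape[0] for g in stack.gaussian] == [25, 13, 7]

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_pyramids(np.zeros((4, 4)), levels=3)


class TestFusePyramid:
    def test_unit_range(self, rng):
        stack = build_pyramids(rng.uniform(0, 1, (48, 48)))
        fused = fuse_pyramid(stack)
        assert fused.min() == pytest.approx(0.0, abs=1e-12)
        assert fused.max() == pytest.approx(1.0, abs=1e-12)

    def test_single_weight_selects_layer(self, rng):
        stack = build_pyramids(rng.uniform(0, 1, (32, 32)))
        fused = fuse_pyramid(stack, weights=np.array([1.0, 0.0, 0.0, 0.0]))
        l0 = stack.laplacian[0]
        expected = (l0 - l0.min()) / (l0.max() - l0.min())
        np.testing.assert_allclose(fused, expected, atol=1e-12)

    def test_constant_pyramid_degenerates_to_zero(self):
        stack = build_pyramids(np.full((32, 32), 0.5))
        fused = fuse_pyramid(stack, weights=np.array([1.0, 0.0, 0.0, 0.0]))
        np.testing.assert_array_equal(fused, 0.0)

    def test_weight_sum_enforced(self, rng):
        stack = build_pyramids(rng.uniform(0, 1, (32, 32)))
        with pytest.raises(ValueError):
            fuse_pyramid(stack, weights=np.array([0.5, 0.5, 0.5, 0.5]))

    def test_negative_weight_rejected(self, rng):
        stack = build_pyramids(rng.uniform(0, 1, (32, 32)))
        with pytest.raises(ValueError):
            fuse_pyramid(stack, weights=np.array([1.5, -0.5, 0.0, 0.0]))

    def test_equal_weights_order_invariant(self, rng):
        """With equal weights the weighted sum commutes over layers."""
        stack = build_pyramids(rng.uniform(0, 1, (32, 32)))
        reordered = lp.PyramidStack(
            gaussian=stack.gaussian,
            laplacian=(stack.laplacian[2], stack.laplacian[0], stack.laplacian[1]),
        )
        np.testing.assert_allclose(fuse_pyramid(stack), fuse_pyramid(reordered), atol=1e-12)


class TestLpmtfPipeline:
    def test_length_1044_default_params(self, class_spectra):
        img = lpmtf(class_spectra["healthy"].intensities)
        assert img.shape == (208, 208)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_ablation_q6_w5(self, class_spectra):
        img = lpmtf(class_spectra["slight"].intensities, q=6, window_size=5)
        assert img.shape == (208, 208)

    def test_ablation_q12_w10(self, class_spectra):
        img = lpmtf(class_spectra["severe"].intensities, q=12, window_size=10)
        assert img.shape == (104, 104)

    def test_deterministic(self, class_spectra):
        x = class_spectra["healthy"].intensities
        np.testing.assert_array_equal(lpmtf(x), lpmtf(x))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lpmtf(np.arange(50.0), q=12, window_size=5)
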