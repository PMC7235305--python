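"""ROPE/HDI comparison framework: pairwise, multi-group, predictive."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from psybayes import (
    AlignmentError,
    CompatibilityError,
    RopeInterval,
    ValidationError,
    compare_distributions,
    compare_mean_to_point,
    compare_means,
    compare_means_multi,
    compare_means_pair,
    mean_draws_of,
    posterior_predictive_draws,
)

EU = np.array([123.0, 128.0, 121.0, 137.0, 110.0])
US = np.array([118.0, 126.0, 119.0, 110.0, 122.0])


def naive_pair(a, b, rope=None):
    """Independent oracle: explicit loop over draw indexes."""
    n_eq = n_gt = n_lt = 0
    for x, y in zip(a, b):
        d = x - y
        if rope is not None and rope[0] <= d <= rope[1]:
            n_eq += 1
        elif d > (rope[1] if rope else 0):
            n_gt += 1
        elif d < (rope[0] if rope else 0):
            n_lt += 1
        else:  # exact tie without ROPE
            n_gt += 0.5
            n_lt += 0.5
    n = len(a)
    return n_lt / n, n_gt / n, (n_eq / n if rope is not None else None)


class TestPair:
    def test_worked_example_four_of_five(self):
        # index-aligned comparison of the two five-draw location vectors
        r = compare_means_pair(EU, US)
        assert r.pair(0, 1).p_greater == 0.8
        assert r.pair(0, 1).p_smaller == 0.2

    def test_identical_vectors_with_rope(self):
        a = np.array([1.0, 2.0, 3.0])
        r = compare_means_pair(a, a, rope=RopeInterval(-0.2, 0.2))
        p = r.pair(0, 1)
        assert p.p_equal == 1.0 and p.p_smaller == 0.0 and p.p_greater == 0.0

    @given(st.integers(0, 1000))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        rope = (-0.3, 0.3) if seed % 2 else None
        r = compare_means_pair(a, b, rope=RopeInterval(*rope) if rope else None)
        lt, gt, eq = naive_pair(a, b, rope)
        p = r.pair(0, 1)
        assert p.p_smaller == pytest.approx(lt)
        assert p.p_greater == pytest.approx(gt)
        if rope:
            assert p.p_equal == pytest.approx(eq)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        r = compare_means_pair(rng.normal(size=999), rng.normal(size=999), RopeInterval(-0.1, 0.1))
        p = r.pair(0, 1)
        assert p.p_smaller + p.p_greater + p.p_equal == pytest.approx(1.0, abs=1e-12)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=500), rng.normal(0.3, 1, 500)
        fwd = compare_means_pair(a, b).pair(0, 1)
        rev = compare_means_pair(b, a).pair(0, 1)
        assert fwd.p_smaller == rev.p_greater
        assert fwd.hdi.lower == pytest.approx(-rev.hdi.upper)
        assert fwd.hdi.upper == pytest.approx(-rev.hdi.lower)

    @given(st.floats(0.01, 100), st.floats(-50, 50))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=300), rng.normal(size=300)
        base = compare_means_pair(a, b).pair(0, 1)
        trans = compare_means_pair(scale * a + shift, scale * b + shift).pair(0, 1)
        assert trans.p_greater == pytest.approx(base.p_greater)

    def test_unequal_lengths_alignment_error(self):
        with pytest.raises(AlignmentError, match="settings"):
            compare_means_pair(np.zeros(10), np.zeros(11))


class TestMulti:
    def test_constant_sets(self):
        r = compare_means_multi([np.full(4, 1.0), np.full(4, 2.0), np.full(4, 3.0)])
        np.testing.assert_allclose(r.p_largest, [0, 0, 1])
        np.testing.assert_allclose(r.p_smallest, [1, 0, 0])

    def test_tied_sets_split_evenly(self):
        a = np.array([1.0, 2.0, 3.0])
        r = compare_means_multi([a, a.copy()])
        np.testing.assert_allclose(r.p_largest, [0.5, 0.5])

    @given(st.integers(0, 500))
    def test_argmax_counting_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        sets = [rng.normal(size=100) for _ in range(5)]
        r = compare_means_multi(sets)
        stacked = np.stack(sets)
        largest = np.zeros(5)
        smallest = np.zeros(5)
        for i in range(100):
            col = stacked[:, i]
            top = np.flatnonzero(col == col.max())
            bot = np.flatnonzero(col == col.min())
            largest[top] += 1 / top.size
            smallest[bot] += 1 / bot.size
        np.testing.assert_allclose(r.p_largest, largest / 100)
        np.testing.assert_allclose(r.p_smallest, smallest / 100)
        assert r.p_largest.sum() == pytest.approx(1.0, abs=1e-12)
        assert r.p_smallest.sum() == pytest.approx(1.0, abs=1e-12)


class TestPoint:
    def test_all_above(self):
        r = compare_mean_to_point(np.array([1.0, 2.0, 3.0]), 0.0)
        assert r.pair(0, 1).p_greater == 1.0

    def test_symmetric_draws(self):
        x = np.random.default_rng(4).standard_normal(100_000)
        r = compare_mean_to_point(x, 0.0)
        assert 0.49 <= r.pair(0, 1).p_greater <= 0.51

    def test_point_inside_rope(self):
        r = compare_mean_to_point(np.full(10, 2.0), 2.0, rope=RopeInterval(-0.1, 0.1))
        assert r.pair(0, 1).p_equal == 1.0


class TestMeanDrawsOf:
    def test_ttest_passthrough(self, ttest_fit):
        np.testing.assert_array_equal(mean_draws_of(ttest_fit), ttest_fit.group_draws("mu"))

    def test_rt_formula(self, rt_fit):
        e = mean_draws_of(rt_fit)
        np.testing.assert_allclose(
            e, rt_fit.group_draws("mu_mu") + 1.0 / rt_fit.group_draws("mu_lambda")
        )

    def test_linear_needs_selector(self, linear_fits):
        with pytest.raises(ValidationError, match="slope"):
            mean_draws_of(linear_fits[0])
        assert mean_draws_of(linear_fits[0], "slope").shape == (linear_fits[0].n_draws,)


class TestCircular:
    def test_rotated_hue_draws_equal_under_any_rope(self):
        rng = np.random.default_rng(5)
        h = rng.vonmises(0.0, 10.0, 500) % (2 * np.pi)
        r = compare_means_pair(h, h + 2 * np.pi, rope=RopeInterval(-0.01, 0.01), circular=True)
        assert r.pair(0, 1).p_equal == 1.0

    def test_wrapped_difference(self):
        a = np.full(10, np.deg2rad(5.0))
        b = np.full(10, np.deg2rad(355.0))
        r = compare_means_pair(a, b, circular=True)
        assert r.pair(0, 1).hdi.lower == pytest.approx(np.deg2rad(10.0))


class TestPredictive:
    def test_ttest_normal_limit(self, ttest_fit):
        # build a fit-like object with pinned parameters
        from psybayes.draws import DrawMatrix
        from psybayes.ttest import TTestFit

        n = 2000
        group = DrawMatrix(
            np.stack(
                [np.full(n, 0.0), np.full(n, 1.0), np.full(n, 1e6)], axis=1
            )[None, :, :],
            ["mu", "sigma", "nu"],
        )
        fit = TTestFit(model="ttest", group=group)
        draws = posterior_predictive_draws(fit, n_per_draw=50, seed=6)
        assert draws.mean() == pytest.approx(0.0, abs=0.02)
        assert draws.std() == pytest.approx(1.0, rel=0.02)

    def test_success_rate_mean(self, success_fit):
        draws = posterior_predictive_draws(success_fit, n_per_draw=10, seed=7)
        p_mean = success_fit.group_draws("p").mean()
        assert draws.mean() == pytest.approx(p_mean, abs=0.02)

    def test_seed_determinism(self, ttest_fit):
        a = posterior_predictive_draws(ttest_fit, n_per_draw=3, seed=8)
        b = posterior_predictive_draws(ttest_fit, n_per_draw=3, seed=8)
        np.testing.assert_array_equal(a, b)

    def test_linear_needs_x(self, linear_fits):
        with pytest.raises(ValidationError, match="x"):
            posterior_predictive_draws(linear_fits[0], 1, 1)


class TestCompareDistributions:
    def test_identical_fits_near_half(self, ttest_fit):
        r = compare_distributions([ttest_fit, ttest_fit], n_per_draw=5, seed=9)
        assert r.pair(0, 1).p_greater == pytest.approx(0.5, abs=0.05)

    def test_separated_fits(self):
        from psybayes.draws import DrawMatrix
        from psybayes.ttest import TTestFit

        def pinned(mu):
            n = 2000
            group = DrawMatrix(
                np.stack([np.full(n, mu), np.full(n, 1.0), np.full(n, 50.0)], axis=1)[None],
                ["mu", "sigma", "nu"],
            )
            return TTestFit(model="ttest", group=group)

        r = compare_distributions([pinned(0.0), pinned(100.0)], n_per_draw=5, seed=10)
        assert r.pair(0, 1).p_smaller > 0.999

    def test_incompatible_models_rejected(self, ttest_fit, success_fit):
        with pytest.raises(CompatibilityError):
            compare_distributions([ttest_fit, success_fit])

    def test_equals_oracle_on_generated_vectors(self, ttest_fit):
        a = posterior_predictive_draws(ttest_fit, n_per_draw=2, seed=11)
        b = posterior_predictive_draws(ttest_fit, n_per_draw=2, seed=12)
        r = compare_distributions([ttest_fit, ttest_fit], n_per_draw=2, seed=11)
        lt, gt, _ = naive_pair(a, b)
        assert r.pair(0, 1).p_greater == pytest.approx(gt)


class TestCompareMeansWrapper:
    def test_two_fit_wrapper(self, ttest_fit):
        r = compare_means([ttest_fit, ttest_fit])
        assert r.pair(0, 1).p_greater == pytest.approx(0.5, abs=1e-12)

    def test_frame_serialization(self, linear_fits):
        r = compare_means(linear_fits, which="slope", rope=RopeInterval(-0.01, 0.01))
        frame = r.to_frame()
        assert {"comparison", "p_smaller", "p_greater", "p_equal"} <= set(frame.columns)
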