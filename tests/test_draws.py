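"""DrawMatrix container, HDI, split-R-hat, ESS and summary machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from psybayes import (
    DegenerateChainError,
    DrawMatrix,
    UnknownParameterError,
    UnsupportedOperationError,
    ValidationError,
    circular_hdi,
    compute_hdi,
    effective_sample_size,
    extract_group_draws,
    extract_subject_draws,
    split_rhat,
    summarize_draws,
    summarize_fit,
)


def brute_force_hdi(draws, mass):
    """Independent oracle: scan every ceil(mass*n)-window over sorted draws."""
    x = np.sort(np.asarray(draws, float))
    n = x.size
    k = max(int(np.ceil(mass * n)), 2)
    best = None
    for i in range(n - k + 1):
        width = x[i + k - 1] - x[i]
        if best is None or width < best[0] - 1e-15:
            best = (width, x[i], x[i + k - 1])
    return best[1], best[2]


class TestDrawMatrix:
    def test_shape_and_name_validation(self):
        with pytest.raises(ValidationError):
            DrawMatrix(np.zeros((2, 3)), ["a"])
        with pytest.raises(ValidationError):
            DrawMatrix(np.zeros((2, 3, 2)), ["a"])
        with pytest.raises(ValidationError):
            DrawMatrix(np.zeros((2, 3, 2)), ["a", "a"])

    def test_flatten_is_chain_major(self):
        values = np.arange(12, dtype=float).reshape(2, 3, 2)
        dm = DrawMatrix(values, ["a", "b"])
        assert dm.flatten("a").tolist() == [0, 2, 4, 6, 8, 10]

    def test_unknown_parameter_lists_valid_names(self):
        dm = DrawMatrix(np.zeros((1, 2, 2)), ["mu", "sigma"])
        with pytest.raises(UnknownParameterError, match="mu, sigma"):
            dm.chains_for("zeta")

    def test_frame_round_trip(self):
        rng = np.random.default_rng(0)
        dm = DrawMatrix(rng.normal(size=(3, 5, 2)), ["a", "b"])
        back = DrawMatrix.from_frame(dm.to_frame())
        np.testing.assert_allclose(back.values, dm.values)
        assert back.parameter_names == dm.parameter_names


class TestHDI:
    def test_degenerate_constant_draws(self):
        h = compute_hdi(np.full(1000, 3.0), 0.95)
        assert (h.lower, h.upper) == (3.0, 3.0)

    def test_standard_normal_draws(self):
        x = np.random.default_rng(2).standard_normal(100_000)
        h = compute_hdi(x, 0.95)
        assert h.lower == pytest.approx(-1.96, abs=0.05)
        assert h.upper == pytest.approx(1.96, abs=0.05)

    def test_unit_exponential_draws(self):
        # shortest 95% interval of Exp(1) is [0, -ln 0.05]
        x = np.random.default_rng(3).exponential(size=100_000)
        h = compute_hdi(x, 0.95)
        assert h.lower == pytest.approx(0.0, abs=0.05)
        assert h.upper == pytest.approx(-np.log(0.05), abs=0.05)

    def test_needs_two_draws(self):
        with pytest.raises(ValidationError):
            compute_hdi([1.0], 0.95)

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=1000),
        st.floats(0.05, 0.99),
    )
    def test_matches_brute_force_oracle(self, draws, mass):
        h = compute_hdi(draws, mass)
        lo, hi = brute_force_hdi(draws, mass)
        assert (h.lower, h.upper) == pytest.approx((lo, hi))

    @given(st.integers(0, 2**31 - 1), st.floats(0.2, 0.6), st.floats(0.65, 0.99))
    def test_mass_monotone_on_unimodal_draws(self, seed, mass1, mass2):
        # nesting of HDIs across masses holds for unimodal draw sets
        x = np.random.default_rng(seed).standard_normal(400)
        small = compute_hdi(x, mass1)
        big = compute_hdi(x, mass2)
        assert big.lower <= small.lower and small.upper <= big.upper

    def test_circular_hdi_wraps_through_zero(self):
        rng = np.random.default_rng(4)
        angles = np.mod(rng.vonmises(0.0, 20.0, 20_000), 2 * np.pi)
        lo, hi = circular_hdi(angles, 0.95)
        assert lo > hi  # the arc crosses 0
        assert lo > 5.5 and hi < 0.8


class TestSplitRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(5)
        dm = DrawMatrix(rng.standard_normal((4, 1000, 1)), ["x"])
        assert 0.99 <= split_rhat(dm, "x") <= 1.01

    def test_separated_chains_large(self):
        rng = np.random.default_rng(6)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        dm = DrawMatrix(chains[:, :, None], ["x"])
        r = split_rhat(dm, "x")
        assert r > 1.5
        # oracle: direct formula on the split half-chains
        halves = np.concatenate([chains[:, :500], chains[:, 500:]], axis=0)
        w = halves.var(axis=1, ddof=1).mean()
        b = 500 * halves.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((499 * w + b) / 500) / w)
        assert r == pytest.approx(expected)

    def test_constant_chains_error(self):
        dm = DrawMatrix(np.ones((2, 100, 1)), ["x"])
        with pytest.raises(DegenerateChainError):
            split_rhat(dm, "x")

    @given(st.floats(0.1, 50), st.floats(-100, 100))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((4, 200, 1))
        base = split_rhat(DrawMatrix(x, ["x"]), "x")
        transformed = split_rhat(DrawMatrix(scale * x + shift, ["x"]), "x")
        assert transformed == pytest.approx(base, rel=1e-8)


class TestEffectiveSampleSize:
    def test_iid_draws_near_total(self):
        rng = np.random.default_rng(8)
        dm = DrawMatrix(rng.standard_normal((4, 1000, 1)), ["x"])
        assert 3200 <= effective_sample_size(dm, "x") <= 4800

    def test_ar1_matches_closed_form(self):
        rho, n = 0.9, 10_000
        rng = np.random.default_rng(9)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
        ess = effective_sample_size(DrawMatrix(x[None, :, None], ["x"]), "x")
        expected = n * (1 - rho) / (1 + rho)
        assert ess == pytest.approx(expected, rel=0.30)

    def test_antithetic_chain_capped_at_total(self):
        x = np.tile([1.0, -1.0], 500)
        ess = effective_sample_size(DrawMatrix(x[None, :, None], ["x"]), "x")
        assert ess == 1000

    def test_constant_chain_error(self):
        with pytest.raises(DegenerateChainError):
            effective_sample_size(DrawMatrix(np.zeros((1, 100, 1)), ["x"]), "x")


class TestAgainstArviz:
    """Independent cross-check of the diagnostics against arviz."""

    def test_rhat_ess_hdi_close(self):
        # arviz defaults to rank-normalized estimators, so the comparison
        # uses stationary AR(1) chains where the two families agree well
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(10)
        rho = 0.7
        innov = rng.standard_normal((4, 800)) * np.sqrt(1 - rho**2)
        x = np.empty((4, 800))
        x[:, 0] = rng.standard_normal(4)
        for i in range(1, 800):
            x[:, i] = rho * x[:, i - 1] + innov[:, i]
        dm = DrawMatrix(x[:, :, None], ["x"])
        ours = split_rhat(dm, "x")
        theirs = float(az.rhat(az.convert_to_dataset(x))["x"])
        assert ours == pytest.approx(theirs, abs=0.05)
        ess_ours = effective_sample_size(dm, "x")
        ess_theirs = float(az.ess(az.convert_to_dataset(x))["x"])
        assert ess_ours == pytest.approx(ess_theirs, rel=0.25)
        flat = rng.standard_normal(100_000)  # dense draws: window conventions converge
        h = compute_hdi(flat, 0.95)
        lo, hi = az.hdi(flat, hdi_prob=0.95)
        assert (h.lower, h.upper) == pytest.approx((lo, hi), abs=0.01)


class TestSummaries:
    def test_se_mean_identity_all_rows(self, rt_fit):
        report = summarize_fit(rt_fit)
        t = report.table
        np.testing.assert_allclose(t["se_mean"], t["sd"] / np.sqrt(t["n_eff"]))

    def test_mu_recovery_within_mc_error(self, ttest_fit):
        report = summarize_fit(ttest_fit)
        row = report.row("mu")
        assert abs(row["mean"] - 5.0) < 3 * row["se_mean"] + 3 * 2.0 / np.sqrt(2000)

    def test_constant_parameter_propagates_error(self):
        class Fake:
            group = DrawMatrix(np.ones((2, 50, 1)), ["c"])
            subject = None

        with pytest.raises(DegenerateChainError):
            summarize_fit(Fake())

    def test_serializes_expected_columns(self, tmp_path, ttest_fit):
        path = tmp_path / "report.csv"
        summarize_fit(ttest_fit).to_csv(path)
        cols = list(pd.read_csv(path).columns)
        assert cols == ["parameter", "mean", "se_mean", "sd", "2.5%", "97.5%", "n_eff", "Rhat"]


class TestExtraction:
    def test_group_draw_shape_and_mean_consistency(self, ttest_fit):
        mu = extract_group_draws(ttest_fit, "mu")
        assert mu.shape == (ttest_fit.n_draws,)
        report = summarize_fit(ttest_fit)
        assert mu.mean() == pytest.approx(report.row("mu")["mean"])

    def test_unknown_group_parameter(self, ttest_fit):
        with pytest.raises(UnknownParameterError):
            extract_group_draws(ttest_fit, "zeta")

    def test_subject_draws_shape(self, rt_fit):
        mu1 = extract_subject_draws(rt_fit, "mu", 1)
        assert mu1.shape == (rt_fit.n_draws,)

    def test_subject_out_of_range(self, rt_fit):
        with pytest.raises(IndexError):
            extract_subject_draws(rt_fit, "mu", rt_fit.n_subjects + 1)

    def test_flat_model_has_no_subjects(self, ttest_fit):
        with pytest.raises(UnsupportedOperationError):
            extract_subject_draws(ttest_fit, "mu", 1)
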