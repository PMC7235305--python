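"""Color model: conversions, circular statistics, component fits."""

import numpy as np
import pytest
from scipy import integrate, special, stats

from psybayes import (
    ColorData,
    SamplerSettings,
    UndefinedMeanError,
    ValidationError,
    circular_hdi,
    circular_mean,
    fit_color,
    hsv_to_rgb,
    rgb_to_hsv,
    von_mises_log_density,
)


class TestConversion:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((255, 0, 0), (0.0, 1.0, 1.0)),
            ((0, 0, 0), (0.0, 0.0, 0.0)),
            ((128, 128, 128), (0.0, 0.0, 128 / 255)),
            ((0, 255, 255), (180.0, 1.0, 1.0)),
        ],
    )
    def test_known_colors(self, rgb, expected):
        h, s, v = rgb_to_hsv(*rgb)
        assert (h, s, v) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            rgb_to_hsv(300, 0, 0)

    def test_round_trip_on_6bit_grid(self):
        # full 6-bit-per-channel grid: 64^3 colors, vectorized
        levels = np.arange(0, 256, 4.047619).round()  # 64 levels incl. 0, 255
        r, g, b = np.meshgrid(levels, levels, levels, indexing="ij")
        h, s, v = rgb_to_hsv(r.ravel(), g.ravel(), b.ravel())
        r2, g2, b2 = hsv_to_rgb(h, s, v)
        for orig, back in ((r.ravel(), r2), (g.ravel(), g2), (b.ravel(), b2)):
            assert np.max(np.abs(orig - back)) <= 1.0  # within 1/255 scaled


class TestVonMises:
    def test_uniform_limit(self):
        assert von_mises_log_density(1.234, 0.0, 0.0) == pytest.approx(
            np.log(1 / (2 * np.pi)), abs=1e-12
        )

    def test_mode_value_kappa_one(self):
        expected = np.log(np.e / (2 * np.pi * special.i0(1.0)))
        assert von_mises_log_density(0.7, 0.7, 1.0) == pytest.approx(expected, abs=1e-4)

    def test_periodicity(self):
        a = von_mises_log_density(0.3, 1.0, 2.5)
        b = von_mises_log_density(0.3 + 2 * np.pi, 1.0, 2.5)
        assert a == pytest.approx(b)

    def test_matches_scipy(self):
        assert von_mises_log_density(0.4, 1.1, 3.0) == pytest.approx(
            stats.vonmises.logpdf(0.4, 3.0, loc=1.1)
        )

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValidationError):
            von_mises_log_density(0.0, 0.0, -1.0)


class TestCircularMean:
    def test_wraparound_symmetry(self):
        assert circular_mean(np.deg2rad([350, 10])) == pytest.approx(0.0, abs=1e-9)

    def test_antipodal_pair_undefined(self):
        with pytest.raises(UndefinedMeanError):
            circular_mean(np.deg2rad([0, 180]))

    def test_simple_average(self):
        assert circular_mean(np.deg2rad([10, 20, 30])) == pytest.approx(
            np.deg2rad(20), abs=1e-9
        )


class TestColorData:
    def test_out_of_range_rgb(self):
        with pytest.raises(ValidationError):
            ColorData(np.array([[0, 0, 300], [1, 2, 3]]))

    def test_hsv_ranges(self):
        with pytest.raises(ValidationError):
            ColorData(np.array([[10.0, 1.2, 0.5], [20.0, 0.5, 0.5]]), is_hsv=True)

    def test_identical_rows_degenerate(self):
        with pytest.raises(ValidationError):
            fit_color(np.tile([[200, 30, 30]], (20, 1)), settings=SamplerSettings(1, 50, 50, 1))


class TestTruncatedNormal:
    def test_likelihood_normalizes_over_interval(self):
        # the truncated-normal density with the normalization used in the
        # component fits integrates to one over its interval
        m, sd, lo, hi = 0.8, 0.3, 0.0, 1.0
        z = stats.norm.cdf((hi - m) / sd) - stats.norm.cdf((lo - m) / sd)
        pdf = lambda x: stats.norm.pdf(x, m, sd) / z
        total, _ = integrate.quad(pdf, lo, hi)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_component_far_from_bounds_matches_untruncated_posterior(self):
        rng = np.random.default_rng(22)
        x = np.clip(rng.normal(120, 15, 300), 0, 255)
        data = np.stack([x, np.full_like(x, 30), np.full_like(x, 60)], axis=1)
        data[:, 1] += rng.normal(0, 5, x.size)
        data[:, 2] += rng.normal(0, 5, x.size)
        data = np.clip(data, 0, 255)
        fit = fit_color(data, settings=SamplerSettings(2, 400, 400, seed=15))
        mu = fit.group_draws("r_mu")
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert mu.mean() == pytest.approx(x.mean(), abs=3 * se + 3 * mu.std() / 10)
        assert mu.std() == pytest.approx(se, rel=0.25)


class TestFit:
    def test_hue_recovery(self, color_fit, afterimages):
        truth = afterimages.ground_truth["stimuli"]["red"]["target_hue_rad"]
        h = color_fit.group_draws("h_mu")
        lo, hi = circular_hdi(h, 0.95)
        wrapped = np.mod(truth, 2 * np.pi)
        if lo <= hi:
            assert lo <= wrapped <= hi or abs(wrapped - 2 * np.pi) < 1e-9
        else:
            assert wrapped >= lo or wrapped <= hi
        kappa = color_fit.group_draws("h_kappa")
        assert 10 <= kappa.mean() <= 60

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(23)
        n = 150
        base_h = np.mod(rng.vonmises(0.5 - np.pi, 25.0, n) + np.pi, 2 * np.pi)
        s = np.clip(rng.normal(0.9, 0.05, n), 0, 1)
        v = np.clip(rng.normal(0.9, 0.05, n), 0, 1)
        delta = 2.0
        settings = SamplerSettings(2, 400, 400, seed=16)
        fit_a = fit_color(
            np.stack([np.rad2deg(base_h), s, v], axis=1), settings=settings, is_hsv=True
        )
        rotated = np.mod(base_h + delta, 2 * np.pi)
        fit_b = fit_color(
            np.stack([np.rad2deg(rotated), s, v], axis=1), settings=settings, is_hsv=True
        )
        mean_a = circular_mean(fit_a.group_draws("h_mu"))
        mean_b = circular_mean(fit_b.group_draws("h_mu"))
        diff = np.mod(mean_b - mean_a, 2 * np.pi)
        assert diff == pytest.approx(delta, abs=0.1)
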