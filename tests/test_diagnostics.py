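"""Digit preference, limit-of-detection uniformity, and plot data."""

import numpy as np
import pytest

from bloodloss import (
    BloodLossSample,
    LognormalParams,
    cdf_overlay_data,
    digit_preference,
    fit_mle_3p,
    lod_assess,
    probability_plot_data,
    qq_data,
)
from bloodloss.synthetic import ArmConfig, SyntheticConfig, generate, model_volume_draws

MISO = LognormalParams(5.58, 0.71, -8.60)


class TestDigitPreference:
    def test_expected_column_is_fixed(self, rng):
        s = BloodLossSample("a", rng.uniform(1, 2000, 50))
        rep = digit_preference(s)
        assert rep.expected_freq == {10: 0.10, 50: 0.02, 100: 0.01}

    def test_all_multiples_of_100(self):
        s = BloodLossSample("a", np.arange(100.0, 2100.0, 100.0))
        rep = digit_preference(s)
        assert rep.observed_freq == {10: 1.0, 50: 1.0, 100: 1.0}

    def test_nesting_of_observed_frequencies(self, rng):
        v = np.round(rng.uniform(1, 2000, 5000))
        v = v[v > 0]
        rep = digit_preference(BloodLossSample("a", v))
        assert rep.observed_freq[100] <= rep.observed_freq[50] <= rep.observed_freq[10]

    def test_unheaped_integer_recording_matches_expectation(self, rng):
        n = 10**5
        v = np.round(MISO.t + np.exp(MISO.m + MISO.s * rng.standard_normal(n)))
        v = v[v > 0]
        rep = digit_preference(BloodLossSample("a", v))
        for k, p in rep.expected_freq.items():
            tol = 3 * np.sqrt(p * (1 - p) / v.size)
            assert rep.observed_freq[k] == pytest.approx(p, abs=tol)

    def test_non_integer_values_are_non_multiples(self):
        s = BloodLossSample("a", np.array([100.5, 200.3, 1000.0, 50.0]))
        rep = digit_preference(s)
        assert rep.observed_freq[50] == 0.5


class TestLOD:
    def test_uniform_sub_lod_flagged_plausible(self):
        rng = np.random.default_rng(42)
        body = 200.0 + np.exp(5.0 + 0.5 * rng.standard_normal(800))
        sub = rng.uniform(0.0, 50.0, 200)
        sub = sub[sub > 0]
        s = BloodLossSample("a", np.r_[body, sub])
        rep = lod_assess(s, candidates=(50.0,))[0]
        assert rep.flag and not rep.skipped
        assert rep.n_below == sub.size

    def test_lognormal_body_not_uniform(self):
        # sub-50 values from a smooth lognormal body are not uniform on
        # (0, 50) once enough of them are seen
        params = LognormalParams(4.4, 0.9, 0.0)
        sample, _ = model_volume_draws(params, 20_000, seed=21)
        rep = lod_assess(sample, candidates=(50.0,))[0]
        assert rep.n_below >= 200
        assert not rep.flag

    def test_too_few_below_candidate_skipped(self, rng):
        s = BloodLossSample("a", rng.uniform(500, 2000, 100))
        reps = lod_assess(s, candidates=(50.0, 100.0))
        assert all(r.skipped for r in reps)

    def test_type_i_error_near_nominal(self):
        # flag is false (uniformity wrongly rejected) in ~5% of datasets
        # where the sub-LOD values truly are uniform
        rejections = 0
        reps = 400
        for r in range(reps):
            rng = np.random.default_rng(3000 + r)
            sub = rng.uniform(0.0, 50.0, 150)
            sub = sub[sub > 0]
            body = rng.uniform(60.0, 2000.0, 300)
            s = BloodLossSample("a", np.r_[sub, body])
            rejections += not lod_assess(s, candidates=(50.0,))[0].flag
        assert 0.02 <= rejections / reps <= 0.09


class TestPlotData:
    def test_probability_plot_self_simulated_inside_band(self):
        sample, _ = model_volume_draws(MISO, 2000, seed=22)
        fit = fit_mle_3p(sample)
        pd_ = probability_plot_data(sample, fit)
        inside = np.mean((pd_.x >= pd_.band_lower) & (pd_.x <= pd_.band_upper))
        assert inside >= 0.95

    def test_lod_smearing_breaks_band_in_left_tail(self):
        cfg = SyntheticConfig(
            arms=(ArmConfig("a", LognormalParams(5.0, 0.8, 0.0), 8000),),
            lod=50.0, seed=23,
        )
        samples, _ = generate(cfg)
        fit = fit_mle_3p(samples[0])
        pd_ = probability_plot_data(samples[0], fit)
        sub = pd_.x < 50.0
        assert sub.sum() > 50
        outside_sub = np.mean(
            (pd_.x[sub] < pd_.band_lower[sub]) | (pd_.x[sub] > pd_.band_upper[sub])
        )
        assert outside_sub > 0.25

    def test_qq_slope_near_unity_for_self_simulated(self):
        sample, _ = model_volume_draws(MISO, 10_000, seed=24)
        fit = fit_mle_3p(sample)
        pd_ = qq_data(sample, fit)
        slope = np.polyfit(pd_.x, pd_.y, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_qq_invariant_under_constant_shift(self):
        sample, _ = model_volume_draws(MISO, 3000, seed=25)
        shifted = BloodLossSample("a", sample.volumes + 75.0)
        pd1 = qq_data(sample, fit_mle_3p(sample, compute_se=False))
        pd2 = qq_data(shifted, fit_mle_3p(shifted, compute_se=False))
        # threshold absorbs the shift: the plots coincide up to the shift
        np.testing.assert_allclose(pd2.y - pd1.y, 75.0)
        np.testing.assert_allclose(pd2.x - pd1.x, 75.0, atol=0.5)

    def test_heavy_tail_departs_in_upper_quantiles(self, rng):
        # Pareto-contaminated data: fitted lognormal underpredicts the
        # largest order statistics
        v = np.exp(5.3 + 0.6 * rng.standard_normal(5000))
        v[-250:] = 2000.0 * (1 + rng.pareto(1.5, 250))
        sample = BloodLossSample("a", v)
        pd_ = qq_data(sample, fit_mle_3p(sample))
        top = slice(-20, None)
        assert np.all(pd_.y[top] > pd_.x[top])

    def test_cdf_overlay_bands_and_single_point_grid(self):
        sample, shift = model_volume_draws(MISO, 9000, seed=26)
        fit = fit_mle_3p(sample)
        grid = np.linspace(400, 1400, 26) + shift
        pd_ = cdf_overlay_data(sample, fit, grid)
        assert np.all(pd_.band_lower <= pd_.band_upper)
        # lognormal band narrower than the binomial band across the window
        lw = pd_.band_upper - pd_.band_lower
        bw = pd_.extra["empirical_upper"] - pd_.extra["empirical_lower"]
        assert np.mean(lw < bw) > 0.9
        # both curves inside each other's bands for self-simulated data
        assert np.mean((pd_.y >= pd_.band_lower) & (pd_.y <= pd_.band_upper)) > 0.9
        single = cdf_overlay_data(sample, fit, [1000.0 + shift])
        assert single.x.shape == (1,)

    def test_plot_data_deterministic(self):
        sample, _ = model_volume_draws(MISO, 500, seed=27)
        fit = fit_mle_3p(sample)
        a, b = qq_data(sample, fit), qq_data(sample, fit)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_non_converged_fit_rejected(self):
        sample, _ = model_volume_draws(MISO, 500, seed=28)
        fit = fit_mle_3p(sample)
        fit.converged = False
        for fn in (probability_plot_data, qq_data):
            with pytest.raises(ValueError, match="converged"):
                fn(sample, fit)
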