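"""Maximum-likelihood and quantile-matching fits."""

import numpy as np
import pytest

from bloodloss import (
    BloodLossSample,
    LognormalParams,
    QuantileSpec,
    compare_fits,
    fit_from_quantiles,
    fit_mle_2p,
    fit_mle_3p,
    quantile,
)
from bloodloss.fitting import _profile_loglik
from bloodloss.synthetic import model_volume_draws


class TestFit2p:
    def test_constant_sample_degenerate(self):
        s = BloodLossSample("a", np.full(20, 250.0))
        res = fit_mle_2p(s)
        assert res.degenerate
        assert res.params.m == pytest.approx(np.log(250.0))

    def test_nonpositive_volume_rejected_with_index(self):
        with pytest.raises(ValueError, match="index 2"):
            BloodLossSample("a", np.array([100.0, 200.0, -5.0, 300.0]))

    def test_monte_carlo_recovery(self, rng):
        m, s_true, n = 5.5, 0.7, 10**5
        v = np.exp(m + s_true * rng.standard_normal(n))
        res = fit_mle_2p(BloodLossSample("a", v))
        assert res.params.m == pytest.approx(m, abs=3 * s_true / np.sqrt(n))
        assert res.params.s == pytest.approx(s_true, abs=3 * s_true / np.sqrt(2 * n))
        # closed forms for the sufficient statistics
        assert res.suffstats[0] == pytest.approx(np.log(v).mean())
        assert res.suffstats[1] == pytest.approx(np.log(v).var())

    def test_mle_beats_perturbed_parameters(self, rng):
        from bloodloss.distributions import logpdf

        v = np.exp(5.5 + 0.7 * rng.standard_normal(500))
        res = fit_mle_2p(BloodLossSample("a", v))
        best = res.loglik
        for dm, fs in ((0.1, 1.0), (-0.1, 1.0), (0.0, 1.1), (0.1, 1.1)):
            alt = LognormalParams(res.params.m + dm, res.params.s * fs, 0.0)
            assert np.sum(logpdf(v, alt)) < best

    def test_matches_independent_mle_oracle(self):
        # frozen cross-check: the same 25 volumes fitted with an
        # independent lognormal-MLE implementation (R fitdistrplus
        # 1.2-4, fitdist(v, "lnorm"))
        v = np.array([
            330.114, 164.09, 1568.888, 79.362, 388.853, 221.318, 190.918,
            516.178, 68.543, 122.821, 225.899, 827.899, 260.43, 458.052,
            66.399, 102.799, 482.35, 157.634, 234.136, 408.139, 52.273,
            105.55, 229.135, 82.886, 148.797,
        ])
        res = fit_mle_2p(BloodLossSample("fixture", v))
        assert res.params.m == pytest.approx(5.3345806703, abs=1e-9)
        assert res.params.s == pytest.approx(0.8245393500, abs=1e-9)
        assert res.loglik == pytest.approx(-164.0147197820, abs=1e-8)
        # R differentiates the likelihood numerically; the closed-form
        # observed-information SEs agree to ~1e-6
        assert res.se["m"] == pytest.approx(0.1649078700, abs=1e-5)
        assert res.se["s"] == pytest.approx(0.1166067013, abs=1e-5)

    def test_information_criteria_definitions(self, rng):
        v = np.exp(5.5 + 0.7 * rng.standard_normal(200))
        res = fit_mle_2p(BloodLossSample("a", v))
        assert res.aic == pytest.approx(2 * 2 - 2 * res.loglik)
        assert res.bic == pytest.approx(2 * np.log(200) - 2 * res.loglik)


class TestFit3p:
    def test_recovery_at_published_parameters(self):
        true = LognormalParams(5.63, 0.63, -47.38)
        sample, shift = model_volume_draws(true, 50_000, seed=1)
        res = fit_mle_3p(sample)
        assert res.converged
        est = (res.params.m, res.params.s, res.params.t - shift)
        for e, tr, se in zip(est, (5.63, 0.63, -47.38),
                             (res.se["m"], res.se["s"], res.se["t"])):
            assert abs(e - tr) < 3 * se
        # t is intrinsically hard: its SE dwarfs the location/scale SEs
        assert res.se["t"] > 10 * res.se["m"]

    def test_threshold_ci_covers_zero_under_plain_lognormal(self):
        # data generated with t = 0: the threshold CI should cover 0 in
        # the large majority of replicates
        true = LognormalParams(5.5, 0.7, 0.0)
        hits = total = 0
        for r in range(60):
            sample, shift = model_volume_draws(true, 10_000, seed=300 + r)
            res = fit_mle_3p(sample)
            if not np.isfinite(res.se.get("t", np.nan)):
                continue
            lo, hi = res.ci95["t"]
            total += 1
            hits += lo - shift <= 0.0 <= hi - shift
        assert total >= 50
        assert hits / total >= 0.85

    def test_3p_nests_2p(self, rng):
        v = np.exp(5.5 + 0.7 * rng.standard_normal(2000)) + 30.0
        s = BloodLossSample("a", v)
        assert fit_mle_3p(s).loglik >= fit_mle_2p(s).loglik - 1e-6

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            fit_mle_3p(BloodLossSample("a", np.arange(1.0, 9.0)))

    def test_threshold_below_minimum(self):
        true = LognormalParams(5.2, 0.8, 40.0)
        sample, _ = model_volume_draws(true, 5000, seed=7)
        res = fit_mle_3p(sample)
        assert res.params.t < sample.volumes.min()

    def test_profile_matches_brute_force_grid(self, rng):
        # the 1-d profile search lands within one 0.25 mL grid step of an
        # exhaustive scan on a small instance
        true = LognormalParams(5.4, 0.7, -20.0)
        sample, shift = model_volume_draws(true, 400, seed=11)
        v = sample.volumes
        res = fit_mle_3p(sample, compute_se=False)
        grid = np.arange(-10 * np.median(v), v.min() - 0.25, 0.25)
        ll = _profile_loglik(grid, v)
        t_grid = grid[np.argmax(ll)]
        assert abs(res.params.t - t_grid) <= 0.25 or res.loglik >= ll.max()


class TestQuantileMatching:
    def test_round_trip_from_reported_quantiles(self):
        # the observational-study fit: five published quantiles generated
        # from (m=5.47, s=0.66) are recovered essentially exactly
        true = LognormalParams(5.47, 0.66, 0.0)
        ps = (0.05, 0.25, 0.50, 0.75, 0.95)
        spec = QuantileSpec(tuple((p, float(quantile(p, true))) for p in ps))
        res = fit_from_quantiles(spec, "lognormal2p")
        assert res.params.m == pytest.approx(5.47, abs=1e-6)
        assert res.params.s == pytest.approx(0.66, abs=1e-6)
        assert np.isnan(res.loglik) and np.isnan(res.aic)

    def test_two_pairs_closed_form(self):
        # with two pairs the 2p fit solves two linear equations in (m, s)
        from scipy.stats import norm

        m, s = 5.2, 0.75
        ps = (0.25, 0.8)
        qs = tuple(float(np.exp(m + s * norm.ppf(p))) for p in ps)
        z = norm.ppf(ps)
        s_closed = (np.log(qs[1]) - np.log(qs[0])) / (z[1] - z[0])
        m_closed = np.log(qs[0]) - s_closed * z[0]
        res = fit_from_quantiles(QuantileSpec(tuple(zip(ps, qs))), "lognormal2p")
        assert res.params.m == pytest.approx(m_closed, abs=1e-8)
        assert res.params.s == pytest.approx(s_closed, abs=1e-8)

    def test_three_parameter_interpolation(self):
        true = LognormalParams(5.5, 0.7, -30.0)
        ps = (0.1, 0.5, 0.9)
        spec = QuantileSpec(tuple((p, float(quantile(p, true))) for p in ps))
        res = fit_from_quantiles(spec, "lognormal3p")
        fitted = quantile(np.array(ps), res.params)
        np.testing.assert_allclose(fitted, spec.volumes, rtol=1e-6)

    def test_perturbed_quantiles_stay_bounded(self):
        true = LognormalParams(5.47, 0.66, 0.0)
        ps = (0.05, 0.25, 0.50, 0.75, 0.95)
        base = np.array([quantile(p, true) for p in ps])
        for sign in (+1, -1):
            spec = QuantileSpec(tuple(zip(ps, base * (1 + sign * 0.01))))
            res = fit_from_quantiles(spec, "lognormal2p")
            assert abs(res.params.m - 5.47) < 0.05
            assert abs(res.params.s - 0.66) < 0.05

    def test_too_few_pairs_rejected(self):
        spec = QuantileSpec(((0.25, 150.0), (0.75, 400.0)))
        with pytest.raises(ValueError):
            fit_from_quantiles(spec, "lognormal3p")
        with pytest.raises(ValueError):
            QuantileSpec(((0.5, 200.0),))

    def test_invalid_pairs_rejected(self):
        with pytest.raises(ValueError):
            QuantileSpec(((0.5, 200.0), (0.25, 300.0)))  # p not increasing
        with pytest.raises(ValueError):
            QuantileSpec(((0.25, 300.0), (0.5, 200.0)))  # q not increasing


class TestCompareFits:
    def test_3p_wins_when_threshold_far_from_zero(self):
        # a positive threshold needs no positivity shift, so the fitted
        # data really do have t far from the 2p model's fixed t = 0
        true = LognormalParams(5.2, 0.7, 40.0)
        sample, _ = model_volume_draws(true, 20_000, seed=3)
        table = compare_fits([fit_mle_2p(sample), fit_mle_3p(sample)])
        assert table[0]["model"] == "lognormal3p"
        assert table[0]["delta_aic"] == 0.0

    def test_2p_competitive_when_threshold_zero(self):
        # with t = 0 truth the extra parameter should usually not pay
        # its BIC penalty
        wins = 0
        for r in range(10):
            sample, _ = model_volume_draws(LognormalParams(5.5, 0.7, 0.0), 3000,
                                           seed=600 + r)
            f2, f3 = fit_mle_2p(sample), fit_mle_3p(sample)
            wins += f2.bic <= f3.bic
        assert wins >= 6

    def test_single_input_passthrough(self, rng):
        v = np.exp(5.5 + 0.7 * rng.standard_normal(100))
        res = fit_mle_2p(BloodLossSample("a", v))
        table = compare_fits([res])
        assert len(table) == 1 and table[0]["delta_aic"] == 0.0

    def test_mixed_samples_rejected(self, rng):
        v1 = np.exp(5.5 + 0.7 * rng.standard_normal(100))
        v2 = np.exp(5.5 + 0.7 * rng.standard_normal(150))
        with pytest.raises(ValueError, match="different samples"):
            compare_fits([
                fit_mle_2p(BloodLossSample("a", v1)),
                fit_mle_2p(BloodLossSample("b", v2)),
            ])
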