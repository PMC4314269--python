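"""Sampler correctness, conjugate oracles and convergence diagnostics."""

import numpy as np
import pytest
from scipy.stats import f as f_dist

from kappaipm import (
    DemographicParams,
    McmcConfig,
    ModelSpec,
    SurvivalRecord,
    fit_ipm,
    log_likelihood,
    mpsrf,
    posterior_summary,
    prepare_data,
    psrf,
    run_mcmc,
)
from kappaipm.data_model import DataValidationError
from kappaipm.inference import PosteriorSamples


def _constant_hazard_records(n, h, rng, follow=3.0, censor=0.3, start=1.0):
    recs = []
    for i in range(n):
        a = start + rng.random() * 0.5
        td = a + rng.exponential(1 / h)
        tc = a + rng.exponential(1 / censor) if censor > 0 else np.inf
        end = start + follow
        b = min(td, tc, end)
        recs.append(SurvivalRecord(f"x{i}", a, b, int(td <= tc and td < end)))
    return recs


class TestSamplerContracts:
    def test_identical_seed_gives_identical_chains(self, preset_fit):
        ds, spec = preset_fit["dataset"], preset_fit["spec"]
        cfg = McmcConfig(n_chains=2, n_burnin=50, n_iter=80, seed=77)
        s1, _ = fit_ipm(ds.counts, ds.recruits, ds.records, spec, cfg)
        s2, _ = fit_ipm(ds.counts, ds.recruits, ds.records, spec, cfg)
        assert np.array_equal(s1.draws, s2.draws)
        assert np.array_equal(s1.deviance, s2.deviance)

    def test_kappa_draws_never_leave_prior_support(self, preset_fit):
        samples = preset_fit["samples"]
        for k in (1, 2, 3):
            draws = samples.pooled(f"kappa[{k}]")
            assert draws.min() > -1.0 and draws.max() < 1.0

    def test_no_nan_draws_and_finite_deviance(self, preset_fit):
        samples = preset_fit["samples"]
        assert np.all(np.isfinite(samples.draws))
        assert np.all(np.isfinite(samples.deviance))

    def test_deviance_trace_is_minus_twice_loglik_at_stored_draws(self, toy):
        spec = toy["spec"].replace(v="estimate")
        cfg = McmcConfig(
            n_chains=1, n_burnin=30, n_iter=40, seed=3, store_baseline_increments=True
        )
        data = toy["data"]
        samples = run_mcmc(data, spec, cfg)
        i = 17
        row = {n: samples.draws[0, i, j] for j, n in enumerate(samples.names)}
        params = DemographicParams(
            dL0=np.array([row[f"dL0[{j}]"] for j in range(8)]),
            kappa=np.array([row["kappa[1]"], row["kappa[2]"]]),
            v=row["v"],
            beta=np.array([row["beta0"], row["beta1"]]),
            gamma=np.array([row["gamma1"]]),
        )
        expected = -2.0 * log_likelihood(data, params, spec)
        assert samples.deviance[0, i] == pytest.approx(expected, rel=1e-10)

    def test_initialization_failure_raises_with_diagnostics(self, toy):
        # a non-positive fixed trajectory cannot yield a finite posterior
        spec = toy["spec"].replace(
            fixed_trajectory=(0.0, 100.0), components=("count",), v="estimate"
        )
        with pytest.raises(RuntimeError, match="finite-posterior"):
            run_mcmc(toy["data"], spec, McmcConfig(n_chains=1, n_burnin=5, n_iter=5, seed=0))


class TestConjugateOracles:
    def test_survival_only_posterior_matches_gamma_conjugate(self):
        """Constant hazard, no counts: the sampler is exact Gibbs and the
        posterior of each year's integrated hazard must match the
        closed-form gamma conjugate within Monte Carlo error."""
        rng = np.random.default_rng(21)
        recs = _constant_hazard_records(150, 0.3, rng)
        spec = ModelSpec(surv_form="constant", components=("survival",),
                         year_start="01-01")
        cfg = McmcConfig(n_chains=2, n_burnin=200, n_iter=1500, seed=4)
        samples, data = fit_ipm(None, None, recs, spec, cfg)
        dp = data.risk.event_count
        Yp = data.risk.at_risk_count
        shape = spec.c * spec.dL0_star + dp
        rate = spec.c + Yp
        for t, y in enumerate(data.trans_year):
            sel = data.interval_transition == t
            exact_mean = float(np.sum(shape[sel] / rate[sel]))
            exact_sd = float(np.sqrt(np.sum(shape[sel] / rate[sel] ** 2)))
            draws = samples.pooled(f"H[{y}]")
            mc_se = 3.0 * exact_sd / np.sqrt(draws.size / 10)  # generous ESS haircut
            assert draws.mean() == pytest.approx(exact_mean, abs=mc_se)

    def test_two_interval_toy_moments_match_closed_form(self):
        # two intervals, two known gamma posteriors: a 2-parameter toy with
        # closed-form moments
        recs = [
            SurvivalRecord("a", 1.0, 1.9, 1),
            SurvivalRecord("b", 1.0, 2.0 - 1e-9, 0),
            SurvivalRecord("c", 1.1, 1.6, 1),
        ]
        spec = ModelSpec(surv_form="constant", components=("survival",),
                         ds=0.5, year_start="01-01")
        cfg = McmcConfig(n_chains=3, n_burnin=100, n_iter=2000, seed=9)
        samples, data = fit_ipm(None, None, recs, spec, cfg)
        dp = data.risk.event_count
        Yp = data.risk.at_risk_count
        shape = spec.c * spec.dL0_star + dp
        rate = spec.c + Yp
        H = samples.pooled("H[2]")
        exact_mean = np.sum(shape / rate)
        exact_sd = np.sqrt(np.sum(shape / rate**2))
        n_eff = H.size / 5
        assert H.mean() == pytest.approx(exact_mean, abs=3 * exact_sd / np.sqrt(n_eff))
        assert H.std() == pytest.approx(exact_sd, rel=0.2)

    def test_count_only_v_posterior_concentrates_on_truth(self):
        """Known trajectory, estimated measurement SD: with 200 years the
        posterior of v concentrates around the generating value."""
        rng = np.random.default_rng(8)
        T, v_true = 200, 0.1
        P = 500.0 * np.exp(0.01 * np.arange(T))
        N = P * np.exp(v_true * rng.standard_normal(T))
        from kappaipm.data_model import CountSeries

        counts = CountSeries(
            np.arange(1, T + 1), N * 0.98, N * 1.02, N, v=0.01
        )
        spec = ModelSpec(
            components=("count",), v="estimate",
            fixed_trajectory=tuple(P[1:]), kappa_breaks=(),
        )
        cfg = McmcConfig(n_chains=2, n_burnin=500, n_iter=1500, seed=2)
        samples, _ = fit_ipm(counts, None, None, spec, cfg)
        assert samples.pooled("v").mean() == pytest.approx(v_true, abs=0.02)


class TestPsrf:
    @staticmethod
    def _reference_psrf(x, ci=0.975):
        """Independent recomputation of the corrected Gelman-Rubin
        statistic and its sampling-theory upper limit."""
        x = np.asarray(x, float)
        m, n = x.shape
        xbar = x.mean(1)
        s2 = x.var(1, ddof=1)
        W, B = s2.mean(), n * xbar.var(ddof=1)
        muhat = xbar.mean()
        var_w = s2.var(ddof=1) / m
        var_b = 2 * B**2 / (m - 1)
        cov_wb = (n / m) * (
            np.cov(s2, xbar**2, ddof=1)[0, 1]
            - 2 * muhat * np.cov(s2, xbar, ddof=1)[0, 1]
        )
        V = (n - 1) * W / n + (1 + 1 / m) * B / n
        var_V = (
            (n - 1) ** 2 * var_w
            + (1 + 1 / m) ** 2 * var_b
            + 2 * (n - 1) * (1 + 1 / m) * cov_wb
        ) / n**2
        df_adj = (2 * V**2 / var_V + 3) / (2 * V**2 / var_V + 1)
        R2_fixed = (n - 1) / n
        R2_rand = (1 + 1 / m) * (B / n) / W
        upper = R2_fixed + f_dist.ppf(ci, m - 1, 2 * W**2 / var_w) * R2_rand
        return np.sqrt(df_adj * (R2_fixed + R2_rand)), np.sqrt(df_adj * upper)

    def test_matches_reference_formula_on_fixture_chains(self):
        rng = np.random.default_rng(12345)
        x = rng.standard_normal((4, 250)) + 0.3 * rng.standard_normal((4, 1))
        point, upper = psrf(x)
        ref_point, ref_upper = self._reference_psrf(x)
        assert point == pytest.approx(ref_point, abs=1e-10)
        assert upper == pytest.approx(ref_upper, abs=1e-10)

    def test_exact_copy_chains(self):
        chain = np.random.default_rng(0).standard_normal(200)
        point, upper = psrf(np.stack([chain, chain]))
        n = 200
        assert point == pytest.approx(np.sqrt((n - 1) / n))
        assert upper == pytest.approx(point)
        assert point < 1.0

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(1000)
        b = rng.standard_normal(1000) + 10.0
        point, upper = psrf(np.stack([a, b]))
        assert point > 1.1 and upper > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(DataValidationError):
            psrf(np.zeros((1, 100)))


class TestMpsrf:
    def test_identical_chains_below_one(self):
        rng = np.random.default_rng(7)
        chain = rng.standard_normal((300, 3))
        val = mpsrf(np.stack([chain, chain]))
        assert val < 1.0

    def test_p_equal_one_reduces_to_univariate(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((3, 500))
        point, _ = psrf(x)
        val = mpsrf(x[:, :, None])
        assert val == pytest.approx(point, rel=0.01)

    def test_one_divergent_parameter_inflates_mpsrf(self):
        rng = np.random.default_rng(5)
        m, n = 3, 400
        good = rng.standard_normal((m, n, 3))
        bad = rng.standard_normal((m, n, 1)) + 5.0 * np.arange(m)[:, None, None]
        chains = np.concatenate([good, bad], axis=-1)
        val = mpsrf(chains)
        good_psrfs = [psrf(good[:, :, j])[0] for j in range(3)]
        assert val > max(good_psrfs)
        assert val > 1.1

    def test_singular_covariance_raises(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((2, 100, 1))
        dup = np.concatenate([base, base], axis=-1)  # perfectly collinear
        with pytest.raises(DataValidationError, match="singular"):
            mpsrf(dup)


class TestPosteriorSummary:
    def _samples(self, draws):
        draws = np.asarray(draws, float)[None, :, None]
        return PosteriorSamples(["theta"], draws, np.zeros((1, draws.shape[1])), {})

    def test_all_negative_draws(self):
        s = self._samples(-np.abs(np.random.default_rng(0).standard_normal(500)) - 0.1)
        assert posterior_summary(s, "theta")["p_negative"] == 1.0

    def test_symmetric_draws_near_half(self):
        s = self._samples(np.random.default_rng(1).standard_normal(4000))
        assert posterior_summary(s, "theta")["p_negative"] == pytest.approx(0.5, abs=0.03)

    def test_moments_match_brute_force(self):
        draws = np.random.default_rng(2).gamma(2.0, size=600)
        s = self._samples(draws)
        out = posterior_summary(s, "theta")
        assert out["mean"] == pytest.approx(draws.mean())
        assert out["sd"] == pytest.approx(draws.std(ddof=1))
        assert out["ci_low"] == pytest.approx(np.percentile(draws, 2.5))

    def test_too_few_draws_rejected(self):
        s = self._samples(np.arange(50.0))
        with pytest.raises(DataValidationError):
            posterior_summary(s, "theta")

    def test_unknown_parameter_rejected(self):
        s = self._samples(np.arange(200.0))
        with pytest.raises(KeyError):
            s.get("nope")
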