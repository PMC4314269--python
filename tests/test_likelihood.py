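"""Observation densities, process update, priors and the joint posterior."""

import numpy as np
import pytest
from scipy import integrate, stats

from kappaipm.data_model import DataValidationError, standardize_log_abundance
from kappaipm.likelihood import (
    DemographicParams,
    annual_survival,
    build_trajectory,
    count_loglik,
    joint_log_posterior,
    log_likelihood,
    log_prior,
    population_update,
    recruit_loglik,
    recruitment_rate,
    survival_covariate_multiplier,
    survival_loglik,
)


class TestCountLoglik:
    def test_closed_form_at_mode(self):
        # -log N - log v - 0.5 log(2 pi) when N = P
        assert count_loglik(100, 100, 0.1) == pytest.approx(-3.22152, abs=1e-5)

    def test_matches_scipy_lognormal(self):
        got = count_loglik(130.0, 100.0, 0.25)
        assert got == pytest.approx(stats.lognorm.logpdf(130.0, s=0.25, scale=100.0))

    def test_unimodal_decay_away_from_truth(self):
        base = count_loglik(100, 100, 0.1)
        assert count_loglik(110, 100, 0.1) < base
        assert count_loglik(90, 100, 0.1) < base

    def test_density_integrates_to_one(self):
        val, _ = integrate.quad(
            lambda n: np.exp(count_loglik(n, 80.0, 0.2)), 1e-3, 1e4, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DataValidationError):
            count_loglik(-1.0, 100.0, 0.1)
        with pytest.raises(DataValidationError):
            count_loglik(100.0, 100.0, 0.0)


class TestRecruitLoglik:
    def test_moments_and_density_at_mean(self):
        # mean 25, SD sqrt(100 * .25 * .75) = 4.3301
        sd = np.sqrt(100 * 0.25 * 0.75)
        assert sd == pytest.approx(4.3301, abs=1e-4)
        assert recruit_loglik(25, 100, 0.25) == pytest.approx(-2.38450, abs=1e-4)
        assert recruit_loglik(25, 100, 0.25) == pytest.approx(
            stats.norm.logpdf(25, 25, sd)
        )

    def test_normal_approximation_close_to_exact_binomial(self):
        n, p = 1000, 0.3
        mode = int(n * p)
        exact = stats.binom.logpmf(mode, n, p)
        approx = recruit_loglik(mode, n, p)
        assert np.exp(approx) == pytest.approx(np.exp(exact), rel=0.01)

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(DataValidationError):
            recruit_loglik(10, 100, 1.2)


class TestRecruitmentRate:
    def test_linear_at_centered_covariate(self):
        assert recruitment_rate("linear", [0.3, 0.1], 0.0) == pytest.approx(0.3)

    def test_quadratic_nests_linear(self):
        z = np.linspace(-2, 2, 9)
        lin = recruitment_rate("linear", [0.3, 0.1], z)
        quad = recruitment_rate("quadratic", [0.3, 0.1, 0.0], z)
        assert np.allclose(lin, quad)

    def test_broken_stick_continuous_at_changepoint(self):
        z = np.linspace(-1, 1, 11)
        t = np.arange(2, 13)
        rho = recruitment_rate("changepoint", [0.4, 0.1, -0.2], z, t, changepoint=7)
        z_cp = z[t == 7][0]
        # both segments evaluate to beta0 exactly at the change year
        left = 0.4 + 0.1 * (z - z_cp)
        right = 0.4 - 0.2 * (z - z_cp)
        assert rho[t == 7][0] == pytest.approx(0.4)
        assert np.allclose(rho[t <= 7], left[t <= 7])
        assert np.allclose(rho[t > 7], right[t > 7])

    def test_unknown_form_rejected(self):
        with pytest.raises(DataValidationError):
            recruitment_rate("cubic", [0.1], 0.0)


class TestSurvival:
    def _one_interval_risk(self, delta):
        from kappaipm.data_model import SurvivalRecord, expand_records

        rec = SurvivalRecord("w", 2000.0, 2000.9, delta)
        return expand_records([rec], span=(2000, 2001), ds=1.0, year_start="01-01")

    def test_single_interval_no_event(self):
        rt = self._one_interval_risk(0)
        ll = survival_loglik(rt, np.array([0.02]))
        assert ll == pytest.approx(-0.02)

    def test_single_interval_with_event(self):
        rt = self._one_interval_risk(1)
        ll = survival_loglik(rt, np.array([0.02]))
        assert ll == pytest.approx(np.log(0.02) - 0.02)
        assert ll == pytest.approx(-3.93202, abs=1e-5)

    def test_loglinear_with_zero_covariate_equals_constant(self):
        rt = self._one_interval_risk(1)
        base = survival_loglik(rt, np.array([0.05]))
        cov = survival_loglik(
            rt, np.array([0.05]), "loglinear", [0.7], z=np.array([0.0]),
            interval_transition=np.array([0]),
        )
        assert cov == pytest.approx(base)

    def test_event_in_zero_intensity_interval_is_minus_inf(self):
        rt = self._one_interval_risk(1)
        assert survival_loglik(rt, np.array([0.0])) == -np.inf

    def test_matches_exponential_likelihood_on_fine_grid(self):
        # constant hazard h: counting-process likelihood ->
        # h^deaths * exp(-h * exposure) as ds -> 0
        from kappaipm.data_model import SurvivalRecord, expand_records

        recs = [
            SurvivalRecord("a", 2000.0, 2000.7, 1),
            SurvivalRecord("b", 2000.1, 2001.6, 0),
            SurvivalRecord("c", 2000.5, 2001.9, 1),
        ]
        h = 0.3
        ds = 1 / 48
        rt = expand_records(recs, span=(2000, 2002), ds=ds, year_start="01-01")
        ll = survival_loglik(rt, np.full(rt.n_intervals, h * ds))
        deaths = sum(r.delta for r in recs)
        exposure = sum(r.b - r.a for r in recs)
        exact = deaths * np.log(h) - h * exposure
        # the grid likelihood carries a log(ds) unit per event
        assert ll - deaths * np.log(ds) == pytest.approx(exact, abs=len(recs) * 3 * ds)

    def test_annual_survival_closed_form(self):
        assert annual_survival(np.full(12, 0.02)) == pytest.approx(0.78663, abs=1e-5)
        assert annual_survival(np.zeros(12)) == 1.0

    def test_annual_survival_decreasing_in_covariate_with_positive_slope(self):
        vals = [
            annual_survival(np.full(12, 0.02), "loglinear", [0.5], z_t=z)
            for z in (-1.0, 0.0, 1.0)
        ]
        assert vals[0] > vals[1] > vals[2]


class TestPopulationUpdate:
    def test_growth_arithmetic(self):
        assert population_update(100, 0.3, 0.75, 0.0) == pytest.approx(105.0)

    def test_negative_correction_reduces_growth(self):
        # a correction of -0.042 per year trims the multiplier accordingly
        assert population_update(100, 0.3, 0.75, -0.042) == pytest.approx(100.8)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(DataValidationError):
            population_update(100, 0.3, 0.75, -1.05)


class TestLogPrior:
    def test_kappa_outside_support_is_minus_inf(self, toy):
        p = toy["params"].copy()
        p.kappa = np.array([1.5, 0.0])
        assert log_prior(p, toy["spec"]) == -np.inf

    def test_flat_beta_prior_on_rates(self, toy):
        spec = toy["spec"].replace(rho_form="yearly")
        p = toy["params"].copy()
        p.beta = None
        p.rho_t = np.array([0.2, 0.8])
        base = log_prior(p, spec)
        p2 = p.copy()
        p2.rho_t = np.array([0.5, 0.5])
        assert log_prior(p2, spec) == pytest.approx(base)  # Beta(1,1) is flat

    def test_gamma_prior_moments(self, toy):
        spec = toy["spec"]
        shape, rate = spec.c * spec.dL0_star, spec.c
        assert stats.gamma.mean(shape, scale=1 / rate) == pytest.approx(spec.dL0_star)
        assert stats.gamma.var(shape, scale=1 / rate) == pytest.approx(
            spec.dL0_star / spec.c
        )
        # our prior term matches the scipy gamma logpdf
        p = toy["params"]
        ours = log_prior(p, spec)
        alt = log_prior(p.copy(), spec)
        assert ours == alt  # deterministic
        direct = np.sum(stats.gamma.logpdf(p.dL0, shape, scale=1 / rate))
        p_nohaz = p.copy()
        p_nohaz.dL0 = np.zeros(0)
        assert ours - log_prior(p_nohaz, spec) == pytest.approx(direct)


class TestJointPosterior:
    def test_additivity_of_components(self, toy):
        data, spec, params = toy["data"], toy["spec"], toy["params"]
        total = joint_log_posterior(data, params, spec)
        parts = 0.0
        for comp in ("count", "recruit", "survival"):
            parts += log_likelihood(data, params, spec.replace(components=(comp,)))
        parts += log_prior(params, spec)
        assert total == pytest.approx(parts, abs=1e-12)

    def test_matches_independent_brute_force_sum(self, toy):
        """Re-derive every term of the joint posterior from raw scipy
        densities and compare to 1e-12."""
        counts, recruits, records = toy["counts"], toy["recruits"], toy["records"]
        spec, params = toy["spec"], toy["params"]
        N = counts.n_mid
        z = standardize_log_abundance(N[:-1])
        rho = params.beta[0] + params.beta[1] * z
        w = np.exp(params.gamma[0] * z)

        # quarterly grid over [1, 3)
        edges = 1.0 + 0.25 * np.arange(9)
        H = np.array([params.dL0[:4].sum(), params.dL0[4:].sum()])
        sigma = np.exp(-w * H)
        kappa_t = np.array([params.kappa[0], params.kappa[1]])
        P = N[:-1] * (rho + sigma + kappa_t)

        expected = 0.0
        for t in range(2):
            expected += stats.lognorm.logpdf(N[t + 1], s=spec.v, scale=P[t])
            mean = N[t] * rho[t]
            sd = np.sqrt(N[t] * rho[t] * (1 - rho[t]))
            expected += stats.norm.logpdf(recruits.r_mid[t], mean, sd)
        for rec in records:
            for j in range(8):
                s0, s1 = edges[j], edges[j + 1]
                at_risk = rec.a < s1 and rec.b > s0
                if not at_risk:
                    continue
                year_idx = 0 if s0 < 2.0 else 1
                lam = params.dL0[j] * w[year_idx]
                # the death lands in the interval containing b (left-open rule)
                dM = 1 if (rec.delta == 1 and np.ceil((rec.b - 1.0) / 0.25) - 1 == j) else 0
                expected += stats.poisson.logpmf(dM, lam)
        for b in params.beta:
            expected += stats.norm.logpdf(b, 0.0, spec.nu_beta)
        expected += stats.norm.logpdf(params.gamma[0], 0.0, spec.nu_beta)
        expected += np.sum(stats.uniform.logpdf(params.kappa, -1.0, 2.0))
        expected += np.sum(
            stats.gamma.logpdf(params.dL0, spec.c * spec.dL0_star, scale=1 / spec.c)
        )

        got = joint_log_posterior(toy["data"], params, spec)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_kappa_perturbation_inside_flat_prior_changes_only_count_term(self, toy):
        data, spec = toy["data"], toy["spec"]
        p1 = toy["params"].copy()
        p2 = toy["params"].copy()
        p2.kappa = p1.kappa + 0.005
        no_count = spec.replace(components=("recruit", "survival"))
        assert log_likelihood(data, p1, no_count) == pytest.approx(
            log_likelihood(data, p2, no_count), abs=1e-12
        )
        assert log_prior(p1, spec) == pytest.approx(log_prior(p2, spec), abs=1e-12)

    def test_invalid_point_gives_minus_inf_not_nan(self, toy):
        p = toy["params"].copy()
        p.beta = np.array([1.5, 0.0])  # rho outside (0, 1)
        val = joint_log_posterior(toy["data"], p, toy["spec"])
        assert val == -np.inf and not np.isnan(val)

    def test_deterministic_recursion_reproduced_when_noise_free(self):
        """With kappa = 0 and tiny v, the process recursion reproduces the
        counts that were generated from it exactly."""
        from kappaipm.simulate import SimulationScenario, true_trajectory

        sc = SimulationScenario(
            T=6, P1=100.0, rho_form="constant", rho_beta=(0.3,),
            kappa_breaks=(), kappa_values=(0.0,), annual_hazard=-np.log(0.75),
            v=0.0, seed=1,
        )
        tr = true_trajectory(sc)
        expected = 100.0 * 1.05 ** np.arange(6)
        assert np.allclose(tr["P"], expected)

    def test_latent_mode_matches_deterministic_recursion(self, toy):
        from kappaipm.likelihood import prepare_data

        spec = toy["spec"].replace(condition_on_observed=False)
        data = prepare_data(toy["counts"], toy["recruits"], toy["records"], spec)
        p = toy["params"].copy()
        p.logP1 = np.log(102.0)
        traj = build_trajectory(data, p, spec)
        P_prev = 102.0
        for j in range(2):
            z = (np.log(P_prev) - data.z_center) / data.z_scale
            rho = p.beta[0] + p.beta[1] * z
            w = np.exp(p.gamma[0] * z)
            H = p.dL0[4 * j : 4 * j + 4].sum()
            sigma = np.exp(-w * H)
            P_prev *= rho + sigma + p.kappa[j]
            assert traj.P[j] == pytest.approx(P_prev, rel=1e-12)
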