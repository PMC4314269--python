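"""Functional-form selection by BIC and the proportional-hazards check.

Candidate density-dependence forms for each demographic process -- no
relationship, linear, quadratic, and a broken stick changing at year t for
every t in the scan grid -- are fitted to that process's own data with
short MCMC runs; BIC = deviance + k log(n) ranks them, and candidates
within 2 units of the minimum are reported as equivalent winners.

Deviance is the plug-in value at posterior means by default (``method=
"mean"`` uses the average of the deviance trace instead).  Parameter and
observation counts follow explicit conventions, reported with every
result: the baseline-hazard increments count as one effective block, a
scanned change-point adds one parameter, and n is the number of recruit
observations or of at-risk record-intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import DataValidationError
from .inference import McmcConfig, run_mcmc
from .likelihood import (
    DemographicParams,
    ModelSpec,
    log_likelihood,
    prepare_data,
)

__all__ = [
    "CandidateResult",
    "PhCheckResult",
    "compute_bic",
    "scan_functional_forms",
    "ph_check",
    "scan_report",
]


@dataclass(frozen=True)
class CandidateResult:
    """One fitted candidate in a functional-form scan."""

    process: str
    form: str
    changepoint: Optional[int]
    k: int
    n: int
    deviance: float
    bic: float
    winner: bool = False

    def label(self) -> str:
        if self.form == "changepoint":
            return f"{self.form}@{self.changepoint}"
        return self.form


@dataclass(frozen=True)
class PhCheckResult:
    """Posterior of the predictor-by-log-time interaction coefficient."""

    applicable: bool
    mean: Optional[float] = None
    sd: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_positive: Optional[float] = None
    excludes_zero: Optional[bool] = None
    reason: str = ""


def compute_bic(deviance_hat: float, k: int, n: int) -> float:
    """BIC = deviance + k log(n)."""
    if n < 1 or k < 1:
        raise DataValidationError("BIC needs n >= 1 and k >= 1")
    return float(deviance_hat) + k * np.log(n)


def _recruit_candidates(T: int, grid=None):
    cands = [("constant", None), ("linear", None), ("quadratic", None)]
    grid = range(3, T - 2) if grid is None else grid
    cands += [("changepoint", int(t)) for t in grid]
    return cands


def _surv_candidates(T: int, grid=None):
    cands = [("constant", None), ("loglinear", None), ("logquadratic", None)]
    grid = range(3, T - 2) if grid is None else grid
    cands += [("changepoint", int(t)) for t in grid]
    return cands


def _k_of(process: str, form: str, scanned_cp: bool) -> int:
    if process == "recruitment":
        base = {"constant": 1, "linear": 2, "quadratic": 3, "changepoint": 3}[form]
    else:
        base = 1 + {"constant": 0, "loglinear": 1, "logquadratic": 2, "changepoint": 2}[form]
    return base + (1 if scanned_cp else 0)


def _posterior_mean_params(samples, data, spec) -> DemographicParams:
    means = samples.posterior_mean_params()
    beta = None
    if spec.rho_form in ("constant", "linear", "quadratic", "changepoint"):
        idx = 1 if spec.rho_form == "constant" else spec.n_rho_coef
        beta = np.array([means.get(f"beta{i}", means.get("beta0", 0.3)) for i in range(idx)])
    gamma = (
        np.array([means[f"gamma{i + 1}"] for i in range(spec.n_gamma)])
        if spec.n_gamma
        else None
    )
    dL0 = (
        samples.dL0_mean
        if samples.dL0_mean is not None
        else np.zeros(0 if data.risk is None else data.risk.n_intervals)
    )
    K = data.n_periods
    kappa = np.array([means.get(f"kappa[{k + 1}]", 0.0) for k in range(K)])
    v = means.get("v", spec.v if not isinstance(spec.v, str) else 0.1)
    rho_t = None
    if spec.rho_form == "yearly":
        rho_t = np.array([means[f"rho[{y}]"] for y in data.trans_year])
    return DemographicParams(
        dL0=np.asarray(dL0, float), kappa=kappa, v=float(v), beta=beta,
        rho_t=rho_t, gamma=gamma,
    )


def candidate_deviance(samples, data, spec, method: str = "plugin") -> float:
    """Deviance estimate for one fitted candidate."""
    if method == "mean":
        return float(samples.deviance.mean())
    params = _posterior_mean_params(samples, data, spec)
    return -2.0 * log_likelihood(data, params, spec)


def scan_functional_forms(
    counts,
    recruits,
    records,
    process: str,
    spec_base: ModelSpec,
    config: McmcConfig,
    changepoint_grid=None,
    method: str = "plugin",
) -> list[CandidateResult]:
    """Fit the candidate grid for one process and rank by BIC.

    ``process`` is ``"recruitment"`` (recruit counts against standardized
    log previous-year abundance) or ``"survival"`` (telemetry records
    against the same covariate).  Winners are every candidate within 2 BIC
    units of the minimum.  Deterministic given the config seed.
    """
    if process == "recruitment":
        if counts is None or recruits is None:
            raise DataValidationError("recruitment scan needs counts and recruits")
        T = counts.n_years
        if T < 6:
            raise DataValidationError("changepoint scan needs at least 6 years")
        cands = _recruit_candidates(T, changepoint_grid)
        comp = ("recruit",)
    elif process == "survival":
        if counts is None or records is None:
            raise DataValidationError("survival scan needs counts and telemetry")
        T = counts.n_years
        if T < 6:
            raise DataValidationError("changepoint scan needs at least 6 years")
        cands = _surv_candidates(T, changepoint_grid)
        comp = ("survival",)
    else:
        raise DataValidationError("process must be 'recruitment' or 'survival'")

    results = []
    for form, cp in cands:
        if process == "recruitment":
            spec = spec_base.replace(
                rho_form=form, rho_changepoint=cp, components=comp,
                surv_form="constant", surv_changepoint=None,
            )
            data = prepare_data(counts, recruits, None, spec)
            n = int(np.sum(data.has_recruit))
        else:
            spec = spec_base.replace(
                surv_form=form, surv_changepoint=cp, components=comp,
                rho_form="constant", rho_changepoint=None,
            )
            data = prepare_data(counts, None, records, spec)
            n = int(data.risk.Y.sum())
        samples = run_mcmc(data, spec, config)
        dev = candidate_deviance(samples, data, spec, method)
        k = _k_of(process, form, scanned_cp=cp is not None)
        results.append(
            CandidateResult(process, form, cp, k, n, dev, compute_bic(dev, k, n))
        )

    best = min(r.bic for r in results)
    ranked = sorted(results, key=lambda r: r.bic)
    return [
        CandidateResult(
            r.process, r.form, r.changepoint, r.k, r.n, r.deviance, r.bic,
            winner=bool(r.bic <= best + 2.0),
        )
        for r in ranked
    ]


def scan_report(results: list[CandidateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "process": r.process,
                "form": r.form,
                "changepoint": r.changepoint,
                "k": r.k,
                "n": r.n,
                "deviance": r.deviance,
                "bic": r.bic,
                "winner": r.winner,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# proportional-hazards check
# ---------------------------------------------------------------------------


def ph_check(
    counts,
    records,
    best_surv_form: str,
    spec_base: ModelSpec,
    config: McmcConfig,
    changepoint: Optional[int] = None,
) -> PhCheckResult:
    """Test proportionality of the selected survival covariate effect.

    Augments the best covariate model's log hazard with ``z * log(time
    since record entry)`` and samples the interaction coefficient at the
    record-interval level; a 95% interval away from zero flags a hazard
    ratio that drifts over follow-up time.  With a constant (covariate-
    free) best model the check does not apply and a structured
    not-applicable result is returned.
    """
    if best_surv_form == "constant":
        return PhCheckResult(
            applicable=False, reason="best survival model has no covariate"
        )
    spec = spec_base.replace(
        surv_form=best_surv_form, surv_changepoint=changepoint, components=("survival",),
        rho_form="constant", rho_changepoint=None,
    )
    data = prepare_data(counts, None, records, spec)
    risk = data.risk
    rows, cols = np.nonzero(risk.Y)
    mid = risk.grid[:-1] + risk.ds / 2.0
    tau = np.maximum(mid[cols] - risk.entry[rows], risk.ds / 2.0)
    log_tau = np.log(tau)
    z_cell = data.z[data.interval_transition[cols]]
    dM_cell = risk.dM[rows, cols].astype(float)
    S = risk.n_intervals
    dp = risk.event_count
    prior_shape = spec.c * spec.dL0_star + dp

    n_gamma = spec.n_gamma
    rng = np.random.default_rng(config.seed)
    gamma = np.zeros(n_gamma + 1)  # last entry: interaction coefficient
    dL0 = (spec.c * spec.dL0_star + dp) / (spec.c + risk.at_risk_count)
    dL0 = np.maximum(dL0, 1e-10)

    def eta_of(g):
        if best_surv_form == "loglinear":
            base = g[0] * z_cell
        elif best_surv_form == "logquadratic":
            base = g[0] * z_cell + g[1] * z_cell**2
        else:  # changepoint
            from .likelihood import _z_at_changepoint

            z_cp = _z_at_changepoint(data.z, data.t_number, changepoint)
            t_cell = data.t_number[data.interval_transition[cols]]
            slope = np.where(t_cell <= changepoint, g[0], g[1])
            base = slope * (z_cell - z_cp)
        return base + g[-1] * z_cell * log_tau

    def cell_loglik(g, d):
        eta = eta_of(g)
        lam = d[cols] * np.exp(eta)
        with np.errstate(divide="ignore"):
            ev = np.sum(dM_cell * np.log(lam, where=lam > 0, out=np.full_like(lam, -np.inf)))
        if not np.isfinite(ev):
            return float("-inf")
        return float(ev - lam.sum())

    scale = 0.1
    ll = cell_loglik(gamma, dL0)
    n_total = config.n_burnin + config.n_iter
    draws = np.empty((config.n_chains, config.n_iter))
    for c in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(config.n_chains)[c])
        g = gamma + 0.05 * rng.standard_normal(gamma.size)
        d = dL0.copy()
        ll = cell_loglik(g, d)
        acc = 0
        for i in range(n_total):
            # conjugate Gibbs for the baseline increments
            exp_eta = np.exp(eta_of(g))
            expo = np.bincount(cols, weights=exp_eta, minlength=S)
            d = rng.gamma(prior_shape) / (spec.c + expo)
            np.maximum(d, 1e-300, out=d)
            ll = cell_loglik(g, d)
            # joint RW on covariate + interaction coefficients
            gp = g + scale * rng.standard_normal(g.size)
            llp = cell_loglik(gp, d)
            pr = float(np.sum(g**2 - gp**2) / (2.0 * spec.nu_beta**2))
            if np.log(rng.random()) < llp - ll + pr:
                g, ll = gp, llp
                acc += 1
            if i < config.n_burnin and (i + 1) % 50 == 0:
                scale *= float(np.exp(np.clip(acc / 50 - 0.3, -0.5, 0.5)))
                acc = 0
            if i >= config.n_burnin:
                draws[c, i - config.n_burnin] = g[-1]
    pooled = draws.reshape(-1)
    lo, hi = np.percentile(pooled, [2.5, 97.5])
    return PhCheckResult(
        applicable=True,
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        p_positive=float(np.mean(pooled > 0)),
        excludes_zero=bool(lo > 0 or hi < 0),
    )
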