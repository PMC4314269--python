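"""Joint model: observation densities, process update, priors.

The integrated population model ties three data streams to one latent
abundance trajectory ``P_t``:

* counts      ``N_t ~ lognormal(log P_t, v^2)``
* recruits    ``R_t ~ Normal(P_{t-1} rho_t, sqrt(P_{t-1} rho_t (1 - rho_t)))``
  (normal approximation to a binomial draw from the previous year's
  population)
* telemetry   counting-process increments ``dM_i(s) ~ Poisson(Y_i(s)
  dLambda_0(s) exp(f(z_t)))`` with a gamma-process prior on the baseline
  hazard increments.

The process update is multiplicative with additive demographic rates,

    P_t = P_{t-1} (rho_t + sigma_t + kappa_t),

where ``sigma_t = exp(-exp(f(z_t)) * sum_{s in t} dLambda_0(s))`` is the
annual survival implied by the hazard and ``kappa_t`` is a per-period
correction factor in (-1, 1) absorbing unobserved additions (positive) or
removals (negative).  Density dependence enters through ``z_t``, the
standardized log abundance of the previous year, with constant, linear,
quadratic or broken-stick (change-point) functional forms for recruitment
and constant, log-linear, log-quadratic or broken-stick forms for the
hazard multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.special import gammaln

from .data_model import (
    CountSeries,
    DataValidationError,
    PeriodMap,
    RecruitSeries,
    RiskTable,
    SurvivalRecord,
    expand_records,
    standardize_log_abundance,
)

__all__ = [
    "ModelSpec",
    "DemographicParams",
    "LatentTrajectory",
    "IpmData",
    "prepare_data",
    "count_loglik",
    "recruit_loglik",
    "recruitment_rate",
    "survival_covariate_multiplier",
    "survival_loglik",
    "annual_survival",
    "population_update",
    "log_prior",
    "log_likelihood",
    "joint_log_posterior",
    "build_trajectory",
]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)

RHO_FORMS = ("constant", "yearly", "linear", "quadratic", "changepoint")
SURV_FORMS = ("constant", "loglinear", "logquadratic", "changepoint")


@dataclass(frozen=True)
class ModelSpec:
    """Functional-form choices, period map and prior hyperparameters.

    ``v`` is either a fixed log-scale measurement SD (case-study mode,
    usually the quarter-range value carried by the count series) or the
    string ``"estimate"`` for a uniform(0, v_max) prior.  With
    ``condition_on_observed`` the previous year's *observed* count stands
    in for the latent abundance in the process and recruitment means and in
    the density-dependence covariate, which removes the latent trajectory
    from the sampler entirely; otherwise the trajectory is deterministic
    given the initial abundance and the rates, and ``log P_1`` is sampled.
    """

    rho_form: str = "yearly"
    rho_changepoint: Optional[int] = None
    surv_form: str = "constant"
    surv_changepoint: Optional[int] = None
    kappa_breaks: tuple = ()
    condition_on_observed: bool = True
    v: float | str = "estimate"
    ds: float = 1.0 / 12.0
    # prior hyperparameters
    alpha1: float = 1.0
    alpha2: float = 1.0
    mu_beta: float = 0.0
    nu_beta: float = 100.0
    c: float = 1e-3
    hazard_guess: float = 0.25   # prior guess at the *annual* hazard; dL0* = guess * ds
    kappa_low: float = -1.0
    kappa_high: float = 1.0
    v_max: float = 100.0
    continuous_changepoint: bool = True
    components: tuple = ("count", "recruit", "survival")
    fixed_trajectory: Optional[tuple] = None
    year_start: str = "01-01"

    def __post_init__(self) -> None:
        if self.rho_form not in RHO_FORMS:
            raise DataValidationError(f"unknown recruitment form {self.rho_form!r}")
        if self.surv_form not in SURV_FORMS:
            raise DataValidationError(f"unknown survival form {self.surv_form!r}")
        if self.rho_form == "changepoint" and self.rho_changepoint is None:
            raise DataValidationError("changepoint recruitment form needs rho_changepoint")
        if self.surv_form == "changepoint" and self.surv_changepoint is None:
            raise DataValidationError("changepoint survival form needs surv_changepoint")
        if not self.kappa_low < self.kappa_high:
            raise DataValidationError("kappa bounds must be ordered")
        unknown = set(self.components) - {"count", "recruit", "survival"}
        if unknown:
            raise DataValidationError(f"unknown model components {sorted(unknown)}")

    @property
    def dL0_star(self) -> float:
        """Prior mean of one baseline-hazard increment."""
        return self.hazard_guess * self.ds

    @property
    def n_rho_coef(self) -> int:
        if self.rho_form in ("constant", "yearly"):
            return 0
        if self.rho_form == "linear":
            return 2
        if self.rho_form == "quadratic":
            return 3
        return 3 if self.continuous_changepoint else 4

    @property
    def n_gamma(self) -> int:
        if self.surv_form == "constant":
            return 0
        if self.surv_form == "loglinear":
            return 1
        return 2

    def period_map(self) -> PeriodMap:
        return PeriodMap(self.kappa_breaks)

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["kappa_breaks"] = list(self.kappa_breaks)
        d["components"] = list(self.components)
        if d["fixed_trajectory"] is not None:
            d["fixed_trajectory"] = [float(x) for x in d["fixed_trajectory"]]
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ModelSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        if "kappa_breaks" in d:
            d["kappa_breaks"] = tuple(d["kappa_breaks"])
        if "components" in d:
            d["components"] = tuple(d["components"])
        if d.get("fixed_trajectory") is not None:
            d["fixed_trajectory"] = tuple(d["fixed_trajectory"])
        return cls(**d)

    def replace(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


@dataclass
class DemographicParams:
    """One point in parameter space.

    ``beta`` holds recruitment coefficients under covariate forms, or the
    single shared rate under the ``constant`` form; ``rho_t`` holds per-year
    rates under the exchangeable ``yearly`` form.  ``dL0`` are the
    baseline-hazard increments per grid interval, ``kappa`` the per-period
    correction factors, ``v`` the count log-SD, and ``logP1`` the latent
    initial log abundance (latent mode only).
    """

    dL0: np.ndarray
    kappa: np.ndarray
    v: float
    beta: Optional[np.ndarray] = None
    rho_t: Optional[np.ndarray] = None
    gamma: Optional[np.ndarray] = None
    logP1: Optional[float] = None

    def copy(self) -> "DemographicParams":
        return DemographicParams(
            dL0=self.dL0.copy(),
            kappa=self.kappa.copy(),
            v=self.v,
            beta=None if self.beta is None else np.array(self.beta, float),
            rho_t=None if self.rho_t is None else self.rho_t.copy(),
            gamma=None if self.gamma is None else np.array(self.gamma, float),
            logP1=self.logP1,
        )


@dataclass(frozen=True)
class LatentTrajectory:
    """Realized trajectory and per-transition rates for one parameter point."""

    P: np.ndarray        # abundance at each transition's destination year
    mu: np.ndarray       # log P
    z: np.ndarray        # covariate actually used per transition
    rho: np.ndarray
    sigma: np.ndarray
    kappa_t: np.ndarray
    P_prev: np.ndarray   # abundance (or observed count) feeding each transition


# ---------------------------------------------------------------------------
# prepared data container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IpmData:
    """Inputs aligned on a common transition index.

    Transition ``j`` carries the population from ``years[j]`` to
    ``years[j + 1]``; its "year number" ``t = j + 2`` matches the 1-based
    year indexing used for change-point scans.  Forecast transitions (used
    by hold-out prediction) have survival data but no count or recruit
    likelihood contribution.
    """

    counts: Optional[CountSeries]
    recruits: Optional[RecruitSeries]
    risk: Optional[RiskTable]
    trans_year: np.ndarray          # destination year label per transition
    t_number: np.ndarray            # 2, 3, ... per transition
    has_count: np.ndarray           # bool per transition
    logN_dest: np.ndarray           # log observed count at destination (nan if none)
    N_prev: np.ndarray              # observed count feeding the transition
    R_obs: np.ndarray               # observed recruits at destination (nan if none)
    has_recruit: np.ndarray
    z: np.ndarray                   # standardized log N_prev per transition
    z_center: float
    z_scale: float
    period: np.ndarray              # kappa period index per transition
    interval_transition: Optional[np.ndarray]  # transition index per grid interval
    per_year: int

    @property
    def n_transitions(self) -> int:
        return len(self.trans_year)

    @property
    def n_periods(self) -> int:
        return int(self.period.max()) + 1

    def events_by_transition(self) -> np.ndarray:
        D = np.zeros(self.n_transitions)
        if self.risk is not None:
            np.add.at(D, self.interval_transition, self.risk.event_count)
        return D


def prepare_data(
    counts: Optional[CountSeries],
    recruits: Optional[RecruitSeries],
    records: Optional[list[SurvivalRecord]],
    spec: ModelSpec,
    n_forecast_years: int = 0,
) -> IpmData:
    """Align counts, recruits and the expanded risk table on transitions."""
    if counts is None and records is None:
        raise DataValidationError("need at least counts or survival records")
    if n_forecast_years not in (0, 1):
        raise DataValidationError("at most one forecast year is supported")

    if counts is not None:
        years = counts.year
        first, last = int(years[0]), int(years[-1]) + n_forecast_years
    else:
        a_min = min(r.a for r in records)
        b_max = max(r.b for r in records)
        first, last = int(np.floor(a_min)), int(np.ceil(b_max))
    trans_year = np.arange(first + 1, last + 1)
    n_trans = len(trans_year)
    if n_trans < 1:
        raise DataValidationError("need at least two model years")
    t_number = np.arange(2, 2 + n_trans)

    has_count = np.zeros(n_trans, bool)
    logN_dest = np.full(n_trans, np.nan)
    N_prev = np.full(n_trans, np.nan)
    R_obs = np.full(n_trans, np.nan)
    has_recruit = np.zeros(n_trans, bool)
    z = np.zeros(n_trans)
    z_center = 0.0
    z_scale = 1.0

    if counts is not None:
        n_obs_trans = counts.n_years - 1
        has_count[:n_obs_trans] = True
        logN_dest[:n_obs_trans] = np.log(counts.n_mid[1:])
        N_prev[:n_obs_trans] = counts.n_mid[:-1]
        if n_forecast_years:
            N_prev[-1] = counts.n_mid[-1]
        predictors = counts.n_mid[:-1] if n_obs_trans >= 2 else counts.n_mid
        lx = np.log(predictors)
        z_center = float(np.mean(lx))
        sd = float(np.std(lx))
        if sd <= 0:
            raise DataValidationError("cannot standardize a constant count series")
        z_scale = sd
        z = (np.log(N_prev) - z_center) / z_scale
        if recruits is not None:
            if not np.all(np.isin(recruits.year, counts.year[1:])):
                raise DataValidationError(
                    "recruit years must be a subset of count years minus the first"
                )
            idx = np.searchsorted(trans_year, recruits.year)
            R_obs[idx] = recruits.r_mid
            has_recruit[idx] = True
    elif recruits is not None:
        raise DataValidationError("recruit data require a count series for alignment")

    risk = None
    interval_transition = None
    per_year = int(round(1.0 / spec.ds))
    if records:
        risk = expand_records(records, (first, last), ds=spec.ds, year_start=spec.year_start)
        interval_transition = np.searchsorted(trans_year, risk.year_of_interval + 1)

    period = spec.period_map().period_of_year(trans_year)
    return IpmData(
        counts=counts,
        recruits=recruits,
        risk=risk,
        trans_year=trans_year,
        t_number=t_number,
        has_count=has_count,
        logN_dest=logN_dest,
        N_prev=N_prev,
        R_obs=R_obs,
        has_recruit=has_recruit,
        z=z,
        z_center=z_center,
        z_scale=z_scale,
        period=period,
        interval_transition=interval_transition,
        per_year=per_year,
    )


# ---------------------------------------------------------------------------
# observation densities
# ---------------------------------------------------------------------------


def count_loglik(N_t, P_t, v):
    """Lognormal log density of an observed count given true abundance.

    ``log N_t ~ Normal(log P_t, v^2)`` plus the 1/N Jacobian.
    """
    N_t = np.asarray(N_t, float)
    P_t = np.asarray(P_t, float)
    if np.any(N_t <= 0) or np.any(P_t <= 0) or not v > 0:
        raise DataValidationError("count_loglik requires N > 0, P > 0, v > 0")
    resid = np.log(N_t) - np.log(P_t)
    out = -np.log(N_t) - np.log(v) - _HALF_LOG_2PI - resid**2 / (2.0 * v**2)
    return float(out) if out.ndim == 0 else out


def recruit_loglik(R_t, P_prev, rho_t):
    """Normal-approximation log density of a recruit count.

    Mean ``P_prev * rho_t`` and SD ``sqrt(P_prev * rho_t * (1 - rho_t))``,
    the first two binomial moments.
    """
    R_t = np.asarray(R_t, float)
    P_prev = np.asarray(P_prev, float)
    rho_t = np.asarray(rho_t, float)
    if np.any(P_prev <= 0):
        raise DataValidationError("recruit_loglik requires P_prev > 0")
    if np.any(rho_t <= 0) or np.any(rho_t >= 1):
        raise DataValidationError("recruitment rate must lie in (0, 1)")
    mean = P_prev * rho_t
    var = P_prev * rho_t * (1.0 - rho_t)
    out = -0.5 * np.log(var) - _HALF_LOG_2PI - (R_t - mean) ** 2 / (2.0 * var)
    return float(out) if out.ndim == 0 else out


def _z_at_changepoint(z, t_number, changepoint):
    hit = np.asarray(t_number) == changepoint
    if not np.any(hit):
        raise DataValidationError(f"changepoint year {changepoint} outside the series")
    return float(np.asarray(z)[hit][0])


def recruitment_rate(
    form: str,
    beta,
    z,
    t_number=None,
    changepoint: Optional[int] = None,
    continuous: bool = True,
    z_cp: Optional[float] = None,
):
    """Evaluate the recruitment functional form at covariate values ``z``.

    ``constant`` broadcasts the sampled rate; ``linear``/``quadratic``
    evaluate the polynomial; ``changepoint`` is a broken stick joined at the
    change year (two slopes around a shared value ``beta[0]`` there) or,
    with ``continuous=False``, two unconstrained lines.  ``z_cp`` is the
    covariate value at the change year; when omitted it is looked up from
    ``z``/``t_number``.  Values outside (0, 1) are returned as-is for the
    caller to flag invalid.
    """
    z = np.asarray(z, float)
    beta = np.atleast_1d(np.asarray(beta, float))
    if form == "constant":
        return np.broadcast_to(beta[0], z.shape).copy()
    if form == "linear":
        return beta[0] + beta[1] * z
    if form == "quadratic":
        return beta[0] + beta[1] * z + beta[2] * z**2
    if form == "changepoint":
        if t_number is None or changepoint is None:
            raise DataValidationError("changepoint form needs year numbers and a changepoint")
        t_number = np.asarray(t_number)
        left = t_number <= changepoint
        if continuous:
            if z_cp is None:
                z_cp = _z_at_changepoint(z, t_number, changepoint)
            slope = np.where(left, beta[1], beta[2])
            return beta[0] + slope * (z - z_cp)
        return np.where(left, beta[0] + beta[1] * z, beta[2] + beta[3] * z)
    raise DataValidationError(f"unknown recruitment form {form!r}")


def survival_covariate_multiplier(
    form: str,
    gamma,
    z,
    t_number=None,
    changepoint: Optional[int] = None,
    z_cp: Optional[float] = None,
):
    """Hazard multiplier ``exp(f(z))`` per transition for the survival forms."""
    z = np.asarray(z, float)
    if form == "constant":
        return np.ones_like(z)
    gamma = np.atleast_1d(np.asarray(gamma, float))
    if form == "loglinear":
        f = gamma[0] * z
    elif form == "logquadratic":
        f = gamma[0] * z + gamma[1] * z**2
    elif form == "changepoint":
        if t_number is None or changepoint is None:
            raise DataValidationError("changepoint form needs year numbers and a changepoint")
        if z_cp is None:
            z_cp = _z_at_changepoint(z, t_number, changepoint)
        slope = np.where(np.asarray(t_number) <= changepoint, gamma[0], gamma[1])
        f = slope * (z - z_cp)
    else:
        raise DataValidationError(f"unknown survival form {form!r}")
    return np.exp(f)


def survival_loglik(
    risk: RiskTable,
    dL0,
    surv_form: str = "constant",
    gamma=None,
    z=None,
    interval_transition=None,
    t_number=None,
    changepoint: Optional[int] = None,
) -> float:
    """Poisson counting-process log likelihood of all survival records.

    Each at-risk record-interval contributes a Poisson term with mean
    ``dLambda_0(s) * exp(f(z_t))``; intervals where a record is not at risk
    contribute nothing.  An event in an interval with zero intensity yields
    ``-inf`` (not an exception), signalling an impossible parameter point.
    """
    dL0 = np.asarray(dL0, float)
    if np.any(dL0 < 0):
        raise DataValidationError("baseline-hazard increments must be >= 0")
    if dL0.shape != (risk.n_intervals,):
        raise DataValidationError("dL0 must have one increment per grid interval")
    dp = risk.event_count
    Yp = risk.at_risk_count
    if surv_form == "constant":
        w_interval = np.ones(risk.n_intervals)
    else:
        if z is None or interval_transition is None:
            raise DataValidationError("covariate survival forms need z and an interval map")
        w = survival_covariate_multiplier(surv_form, gamma, z, t_number, changepoint)
        w_interval = w[interval_transition]
    intensity = dL0 * w_interval
    has_event = dp > 0
    if np.any(intensity[has_event] <= 0):
        return float("-inf")
    with np.errstate(divide="ignore"):
        event_term = float(np.sum(dp[has_event] * np.log(intensity[has_event])))
    exposure_term = float(np.sum(intensity * Yp))
    return event_term - exposure_term


def annual_survival(dL0, surv_form="constant", gamma=None, z_t=0.0, intervals=None):
    """Annual survival implied by the hazard increments of one model year.

    ``sigma_t = exp(-exp(f(z_t)) * sum dLambda_0(s))`` over the year's grid
    intervals (all of ``dL0`` if ``intervals`` is None).
    """
    dL0 = np.asarray(dL0, float)
    sel = dL0 if intervals is None else dL0[intervals]
    if sel.size == 0:
        raise DataValidationError("a model year must contain at least one grid interval")
    w = survival_covariate_multiplier(surv_form, gamma, np.asarray([z_t]))
    # changepoint form is year-resolved upstream; here z_t is a single year's value
    return float(np.exp(-float(w[0]) * sel.sum()))


def population_update(P_prev, rho_t, sigma_t, kappa_t):
    """Multiplicative process update ``P_t = P_prev (rho + sigma + kappa)``."""
    if not P_prev > 0:
        raise DataValidationError("P_prev must be positive")
    mult = rho_t + sigma_t + kappa_t
    if not mult > 0:
        raise DataValidationError(
            f"non-positive growth multiplier rho+sigma+kappa = {mult:.4f}"
        )
    return P_prev * mult


# ---------------------------------------------------------------------------
# priors and the joint posterior
# ---------------------------------------------------------------------------


def _gamma_logpdf(x, shape, rate):
    x = np.asarray(x, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (shape - 1.0) * np.log(x) - rate * x + shape * np.log(rate) - gammaln(shape)
    return out


def log_prior(params: DemographicParams, spec: ModelSpec) -> float:
    """Sum of the stated prior log densities; -inf outside support.

    v ~ U(0, v_max); kappa ~ U(kappa_low, kappa_high); per-year rho_t ~
    Beta(alpha1, alpha2); coefficients ~ Normal(mu_beta, nu_beta^2);
    dLambda_0(s) ~ Gamma(c * dL0*, rate c) independently per interval.
    """
    lp = 0.0
    kap = np.asarray(params.kappa, float)
    if np.any(kap <= spec.kappa_low) or np.any(kap >= spec.kappa_high):
        return float("-inf")
    lp += -len(kap) * np.log(spec.kappa_high - spec.kappa_low)

    if isinstance(spec.v, str):
        if not (0.0 < params.v < spec.v_max):
            return float("-inf")
        lp += -np.log(spec.v_max)

    rates = []
    if params.rho_t is not None:
        rates.append(np.asarray(params.rho_t, float))
    normal_coefs = [params.gamma]
    if spec.rho_form == "constant":
        # the single shared rate is itself a probability: Beta prior
        if params.beta is not None:
            rates.append(np.atleast_1d(np.asarray(params.beta, float))[:1])
    else:
        normal_coefs.append(params.beta)
    for r in rates:
        if np.any(r <= 0) or np.any(r >= 1):
            return float("-inf")
        from scipy.stats import beta as beta_dist

        lp += float(np.sum(beta_dist.logpdf(r, spec.alpha1, spec.alpha2)))

    for coefs in normal_coefs:
        if coefs is not None and len(np.atleast_1d(coefs)):
            co = np.atleast_1d(np.asarray(coefs, float))
            lp += float(
                np.sum(
                    -np.log(spec.nu_beta)
                    - _HALF_LOG_2PI
                    - (co - spec.mu_beta) ** 2 / (2.0 * spec.nu_beta**2)
                )
            )

    if params.dL0 is not None and params.dL0.size:
        if np.any(params.dL0 < 0):
            return float("-inf")
        shape = spec.c * spec.dL0_star
        vals = _gamma_logpdf(params.dL0, shape, spec.c)
        if np.any(np.isneginf(vals)):
            return float("-inf")
        lp += float(np.sum(vals))

    if params.logP1 is not None and not np.isfinite(params.logP1):
        return float("-inf")
    return float(lp)


def build_trajectory(
    data: IpmData, params: DemographicParams, spec: ModelSpec
) -> Optional[LatentTrajectory]:
    """Realize rates and the trajectory at one parameter point.

    Returns None when the point is invalid (a rate outside (0, 1) or a
    non-positive growth multiplier), which callers map to -inf.
    """
    n = data.n_transitions
    kappa_t = np.asarray(params.kappa, float)[data.period]

    # per-transition hazard sums
    if data.risk is not None:
        H = np.zeros(n)
        np.add.at(H, data.interval_transition, params.dL0)
    else:
        H = np.zeros(n)

    if spec.fixed_trajectory is not None:
        P = np.asarray(spec.fixed_trajectory, float)
        if P.shape != (n,) or np.any(P <= 0):
            return None
        rho = np.full(n, np.nan)
        sigma = np.full(n, np.nan)
        return LatentTrajectory(P, np.log(P), data.z, rho, sigma, kappa_t, data.N_prev)

    # changepoint centering is taken from the observed-count covariate in
    # both modes: in latent mode the change year's own z is not available
    # until the recursion reaches it, and a fixed centering constant keeps
    # the broken stick a pure reparametrization.
    z_cp_rho = z_cp_surv = None
    if spec.rho_form == "changepoint" and spec.continuous_changepoint:
        z_cp_rho = _z_at_changepoint(data.z, data.t_number, spec.rho_changepoint)
    if spec.surv_form == "changepoint":
        z_cp_surv = _z_at_changepoint(data.z, data.t_number, spec.surv_changepoint)

    if spec.condition_on_observed:
        z = data.z
        rho = _rho_from_params(spec, params, z, data.t_number, z_cp_rho)
        if rho is None or np.any(rho <= 0) or np.any(rho >= 1):
            return None
        w = survival_covariate_multiplier(
            spec.surv_form, params.gamma, z, data.t_number, spec.surv_changepoint, z_cp_surv
        )
        sigma = np.exp(-w * H)
        mult = rho + sigma + kappa_t
        if np.any(mult <= 0):
            return None
        P = data.N_prev * mult
        return LatentTrajectory(P, np.log(P), z, rho, sigma, kappa_t, data.N_prev)

    # latent mode: deterministic recursion from P_1 with fixed standardization
    if params.logP1 is None:
        return None
    P_prev = float(np.exp(params.logP1))
    P = np.empty(n)
    rho = np.empty(n)
    sigma = np.empty(n)
    z = np.empty(n)
    P_prev_seq = np.empty(n)
    for j in range(n):
        z[j] = (np.log(P_prev) - data.z_center) / data.z_scale
        rj = _rho_from_params(
            spec, params, z[j : j + 1], data.t_number[j : j + 1], z_cp_rho, j
        )
        if rj is None:
            return None
        r = float(rj[0])
        if not (0.0 < r < 1.0):
            return None
        w = survival_covariate_multiplier(
            spec.surv_form,
            params.gamma,
            z[j : j + 1],
            data.t_number[j : j + 1],
            spec.surv_changepoint,
            z_cp_surv,
        )
        s = float(np.exp(-w[0] * H[j]))
        mult = r + s + kappa_t[j]
        if mult <= 0:
            return None
        P_prev_seq[j] = P_prev
        P_prev = P_prev * mult
        P[j], rho[j], sigma[j] = P_prev, r, s
    return LatentTrajectory(P, np.log(P), z, rho, sigma, kappa_t, P_prev_seq)


def _rho_from_params(spec, params, z, t_number, z_cp=None, offset=None):
    if spec.rho_form == "yearly":
        if params.rho_t is None:
            return None
        r = np.asarray(params.rho_t, float)
        if offset is not None:
            return r[offset : offset + 1]
        return r[: len(np.atleast_1d(z))]
    if spec.rho_form == "constant":
        if params.beta is None:
            return None
        return np.broadcast_to(float(np.atleast_1d(params.beta)[0]), np.shape(z)).copy()
    if params.beta is None:
        return None
    try:
        return recruitment_rate(
            spec.rho_form,
            params.beta,
            z,
            t_number,
            spec.rho_changepoint,
            spec.continuous_changepoint,
            z_cp,
        )
    except DataValidationError:
        return None


def log_likelihood(data: IpmData, params: DemographicParams, spec: ModelSpec) -> float:
    """Total data log likelihood (count + recruit + survival), without priors.

    This is the quantity whose ``-2x`` forms the deviance trace.
    Propagates -inf for invalid parameter points and never returns NaN.
    """
    traj = build_trajectory(data, params, spec)
    if traj is None:
        return float("-inf")
    v = params.v if isinstance(spec.v, str) else float(spec.v)
    total = 0.0

    if "count" in spec.components and data.counts is not None:
        m = data.has_count
        total += float(
            np.sum(count_loglik(np.exp(data.logN_dest[m]), traj.P[m], v))
        )
        if not spec.condition_on_observed and spec.fixed_trajectory is None:
            # initial-year count observes P_1 directly
            total += float(
                count_loglik(data.counts.n_mid[0], np.exp(params.logP1), v)
            )

    if "recruit" in spec.components and data.recruits is not None:
        m = data.has_recruit
        if np.any(m):
            P_prev = data.N_prev[m] if spec.condition_on_observed else traj.P_prev[m]
            total += float(np.sum(recruit_loglik(data.R_obs[m], P_prev, traj.rho[m])))

    if "survival" in spec.components and data.risk is not None:
        total += survival_loglik(
            data.risk,
            params.dL0,
            spec.surv_form,
            params.gamma,
            traj.z,
            data.interval_transition,
            data.t_number,
            spec.surv_changepoint,
        )

    if not np.isfinite(total):
        return float("-inf")
    return float(total)


def joint_log_posterior(data: IpmData, params: DemographicParams, spec: ModelSpec) -> float:
    """Joint log posterior: count + recruit + survival log likelihoods + prior.

    Propagates -inf for invalid parameter points and never returns NaN.
    """
    lp = log_prior(params, spec)
    if not np.isfinite(lp):
        return float("-inf")
    ll = log_likelihood(data, params, spec)
    if not np.isfinite(ll):
        return float("-inf")
    return float(lp + ll)
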