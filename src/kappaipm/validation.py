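"""Model assessment: hold-out prediction, posterior-predictive coverage,
residual diagnostics, prior sensitivity, and the end-to-end correction-
factor recovery harness.

The hold-out check refits the model without the final year's count and
recruit observations (telemetry is kept, since it covers the final
transition) and pushes posterior draws through the process equation plus a
lognormal observation draw; the model passes if the predictive mean falls
inside the held-out year's observed count range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .data_model import CountSeries, DataValidationError, RecruitSeries
from .inference import McmcConfig, PosteriorSamples, fit_ipm
from .likelihood import IpmData, ModelSpec

__all__ = [
    "PredictiveResult",
    "CoverageReport",
    "split_final_year",
    "holdout_predict",
    "ppc_coverage",
    "prior_sensitivity",
    "kappa_recovery_study",
]


@dataclass(frozen=True)
class PredictiveResult:
    """Posterior predictive distribution for a held-out count year."""

    year: int
    mean: float
    ci_low: float
    ci_high: float
    observed_low: Optional[float] = None
    observed_high: Optional[float] = None
    inside: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise DataValidationError("predictive interval must bracket its mean")


@dataclass(frozen=True)
class CoverageReport:
    """Per-year posterior-interval coverage of the observed counts."""

    table: pd.DataFrame
    coverage: float
    n_positive_resid: int
    n_negative_resid: int
    sign_test_p: float


def split_final_year(
    counts: CountSeries, recruits: Optional[RecruitSeries] = None
):
    """Drop the final count year (and its recruit entry) for hold-out use.

    Returns ``(counts_head, recruits_head, (year, low, high))`` where the
    last element is the held-out observed range.
    """
    if counts.n_years < 11:
        raise DataValidationError("hold-out validation needs >= 10 remaining years")
    held = (
        int(counts.year[-1]),
        float(counts.n_low[-1]),
        float(counts.n_high[-1]),
    )
    head = counts.drop_last(1)
    rec_head = recruits
    if recruits is not None:
        keep = recruits.year < counts.year[-1]
        if not keep.all():
            rec_head = RecruitSeries(
                recruits.year[keep], recruits.r_low[keep],
                recruits.r_high[keep], recruits.r_mid[keep],
            )
    return head, rec_head, held


def holdout_predict(
    counts: CountSeries,
    recruits: Optional[RecruitSeries],
    records,
    spec: ModelSpec,
    config: McmcConfig,
    observed_range: Optional[tuple] = None,
) -> PredictiveResult:
    """Posterior predictive for the year after the last supplied count.

    ``counts``/``recruits`` must already exclude the held-out year.  The
    predictive count is ``lognormal(log P_T, v)`` with ``P_T`` built from
    each posterior draw's rates for the forecast transition.
    """
    samples, data = fit_ipm(counts, recruits, records, spec, config, n_forecast_years=1)
    year_f = int(data.trans_year[-1])
    P_draws = samples.pooled(f"P[{year_f}]")
    v_draws = samples.pooled("v")
    rng = np.random.default_rng(config.seed + 202_177)
    pred = np.exp(np.log(P_draws) + v_draws * rng.standard_normal(P_draws.size))
    lo, hi = np.percentile(pred, [2.5, 97.5])
    mean = float(pred.mean())
    obs_lo = obs_hi = None
    inside = None
    if observed_range is not None:
        obs_lo, obs_hi = float(observed_range[0]), float(observed_range[1])
        inside = bool(obs_lo <= mean <= obs_hi)
    return PredictiveResult(year_f, mean, float(lo), float(hi), obs_lo, obs_hi, inside)


def ppc_coverage(samples: PosteriorSamples, data: IpmData) -> CoverageReport:
    """Fraction of years whose observed count lies in the 95% posterior
    interval of the modeled abundance, plus standardized log-scale
    residuals and a sign-balance test."""
    rows = []
    v_mean = float(samples.pooled("v").mean())
    for j, y in enumerate(data.trans_year):
        if not data.has_count[j]:
            continue
        P = samples.pooled(f"P[{y}]")
        lo, hi = np.percentile(P, [2.5, 97.5])
        obs = float(np.exp(data.logN_dest[j]))
        mu_hat = float(np.mean(np.log(P)))
        resid = (data.logN_dest[j] - mu_hat) / v_mean
        rows.append(
            {
                "year": int(y),
                "observed": obs,
                "P_mean": float(P.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "inside": bool(lo <= obs <= hi),
                "resid": float(resid),
            }
        )
    table = pd.DataFrame(rows)
    n_pos = int((table["resid"] > 0).sum())
    n_neg = int((table["resid"] < 0).sum())
    p = binomtest(n_pos, n_pos + n_neg, 0.5).pvalue if (n_pos + n_neg) else 1.0
    return CoverageReport(
        table=table,
        coverage=float(table["inside"].mean()),
        n_positive_resid=n_pos,
        n_negative_resid=n_neg,
        sign_test_p=float(p),
    )


def prior_sensitivity(
    counts,
    recruits,
    records,
    spec: ModelSpec,
    config: McmcConfig,
    perturbations: dict[str, dict],
    parameters: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Refit under perturbed priors and report posterior shifts.

    ``perturbations`` maps a variant name to ModelSpec field overrides
    (e.g. ``{"wide_beta": {"nu_beta": 1000.0}}``).  Shifts are reported in
    units of the baseline posterior SD.
    """
    samples0, data0 = fit_ipm(counts, recruits, records, spec, config)
    if parameters is None:
        parameters = [
            n
            for n in samples0.names
            if n.startswith(("beta", "gamma", "kappa")) or n == "v"
        ]
        parameters = [n for n in parameters if samples0.pooled(n).std() > 1e-12]
    rows = []
    base = {n: samples0.summary(n) for n in parameters}
    for n in parameters:
        rows.append(
            {
                "variant": "baseline", "parameter": n,
                "mean": base[n]["mean"], "sd": base[n]["sd"], "shift_sd": 0.0,
            }
        )
    for name, overrides in perturbations.items():
        vspec = spec.replace(**overrides)
        samples, _ = fit_ipm(counts, recruits, records, vspec, config)
        for n in parameters:
            s = samples.summary(n)
            rows.append(
                {
                    "variant": name, "parameter": n,
                    "mean": s["mean"], "sd": s["sd"],
                    "shift_sd": (s["mean"] - base[n]["mean"]) / base[n]["sd"],
                }
            )
    return pd.DataFrame(rows)


def kappa_recovery_study(
    scenario,
    spec: ModelSpec,
    config: McmcConfig,
    n_replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate-and-refit study of correction-factor recovery.

    Each replicate draws a dataset from ``scenario`` (reseeded), fits the
    model, and records for every period the posterior mean, 95% interval,
    whether the interval contains the generating value, and the posterior
    probability of a negative correction.
    """
    from .simulate import simulate_dataset

    rows = []
    for r in range(n_replicates):
        sc = scenario.replace(seed=seed + 7919 * r)
        ds = simulate_dataset(sc)
        rspec = spec if isinstance(spec.v, str) else spec.replace(v=float(ds.counts.v))
        samples, _ = fit_ipm(
            ds.counts, ds.recruits, ds.records, rspec,
            config.replace(seed=seed + 104_729 * r),
        )
        for k, kappa_true in enumerate(sc.kappa_values):
            s = samples.summary(f"kappa[{k + 1}]")
            rows.append(
                {
                    "replicate": r,
                    "period": k + 1,
                    "kappa_true": float(kappa_true),
                    "mean": s["mean"],
                    "sd": s["sd"],
                    "ci_low": s["ci_low"],
                    "ci_high": s["ci_high"],
                    "inside": bool(s["ci_low"] <= kappa_true <= s["ci_high"]),
                    "p_negative": s["p_negative"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------


def plot_trajectory(samples: PosteriorSamples, data: IpmData, ax=None):
    """Observed counts with the posterior abundance ribbon."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    years, med, lo, hi, obs = [], [], [], [], []
    for j, y in enumerate(data.trans_year):
        if not data.has_count[j]:
            continue
        P = samples.pooled(f"P[{y}]")
        years.append(int(y))
        med.append(np.median(P))
        q = np.percentile(P, [2.5, 97.5])
        lo.append(q[0])
        hi.append(q[1])
        obs.append(np.exp(data.logN_dest[j]))
    ax.fill_between(years, lo, hi, alpha=0.3, label="95% posterior interval")
    ax.plot(years, med, label="posterior median abundance")
    ax.plot(years, obs, "ko", ms=3, label="observed count")
    ax.set_xlabel("year")
    ax.set_ylabel("animals")
    ax.legend()
    return ax


def plot_residuals(report: CoverageReport, ax=None):
    """Standardized log-scale residuals by year."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.plot(report.table["year"], report.table["resid"], "o-")
    ax.set_xlabel("year")
    ax.set_ylabel("standardized residual")
    return ax
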