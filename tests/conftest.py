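"""Shared fixtures: a hand-built 3-year toy dataset and small simulated
datasets reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

from kappaipm import (
    CountSeries,
    DemographicParams,
    McmcConfig,
    ModelSpec,
    RecruitSeries,
    SurvivalRecord,
    prepare_data,
)
from kappaipm.simulate import preset_wolf_like_scenario, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy():
    """Three count years, two recruit years, three telemetry records on a
    quarterly grid -- small enough to verify the joint posterior by hand."""
    counts = CountSeries(
        year=np.array([1, 2, 3]),
        n_low=np.array([95.0, 118.0, 140.0]),
        n_high=np.array([105.0, 130.0, 152.0]),
        n_mid=np.array([100.0, 124.0, 146.0]),
        v=0.08,
    )
    recruits = RecruitSeries(
        year=np.array([2, 3]),
        r_low=np.array([28.0, 33.0]),
        r_high=np.array([32.0, 37.0]),
        r_mid=np.array([30.0, 35.0]),
    )
    records = [
        SurvivalRecord("a1", 1.2, 2.4, 1),
        SurvivalRecord("a2", 1.5, 3.0, 0),
        SurvivalRecord("a3", 2.1, 2.9, 1),
    ]
    spec = ModelSpec(
        rho_form="linear",
        surv_form="loglinear",
        kappa_breaks=(3,),
        v=0.08,
        ds=0.25,
        year_start="01-01",
    )
    params = DemographicParams(
        dL0=np.array([0.010, 0.015, 0.020, 0.025, 0.030, 0.028, 0.022, 0.018]),
        kappa=np.array([0.01, -0.02]),
        v=0.08,
        beta=np.array([0.30, 0.05]),
        gamma=np.array([0.20]),
    )
    data = prepare_data(counts, recruits, records, spec)
    return dict(
        counts=counts, recruits=recruits, records=records,
        spec=spec, params=params, data=data,
    )


@pytest.fixture(scope="session")
def preset_fit():
    """One preset-scenario dataset with a short full-model fit."""
    from kappaipm import fit_ipm

    sc = preset_wolf_like_scenario(seed=314)
    ds = simulate_dataset(sc)
    spec = ModelSpec(
        rho_form="changepoint", rho_changepoint=18, surv_form="constant",
        kappa_breaks=(17, 24), v=float(ds.counts.v),
    )
    config = McmcConfig(n_chains=2, n_burnin=600, n_iter=800, seed=11)
    samples, data = fit_ipm(ds.counts, ds.recruits, ds.records, spec, config)
    return dict(scenario=sc, dataset=ds, spec=spec, config=config,
                samples=samples, data=data)
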