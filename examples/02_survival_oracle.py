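"""Counting-process survival model against its closed-form oracles.

Fits the gamma-process baseline hazard to a one-year cohort of 200
telemetry records with constant hazard and compares the posterior with
the exponential maximum-likelihood estimate and the Nelson-Aalen
cumulative hazard.  With no count data the baseline-hazard update is
exact conjugate Gibbs, so agreement here checks the survival likelihood
end to end.
"""

import numpy as np

from kappaipm import McmcConfig, ModelSpec, SurvivalRecord, fit_ipm

rng = np.random.default_rng(7)
hazard = 0.26
records = []
for i in range(200):
    a = 1.0
    t_death = a + rng.exponential(1 / hazard)
    t_cens = a + rng.exponential(1 / 0.1)
    b = min(t_death, t_cens, a + 1.0)
    records.append(SurvivalRecord(f"w{i}", a, b, int(t_death <= t_cens and t_death < a + 1.0)))

deaths = sum(r.delta for r in records)
exposure = sum(r.b - r.a for r in records)
print(f"{deaths} deaths over {exposure:.1f} animal-years "
      f"(true hazard {hazard}/yr, true annual survival {np.exp(-hazard):.3f})")

spec = ModelSpec(surv_form="constant", components=("survival",),
                 year_start="01-01", ds=1 / 48)
samples, data = fit_ipm(None, None, records, spec,
                        McmcConfig(n_chains=3, n_burnin=300, n_iter=1500, seed=2))

H = sum(samples.pooled(f"H[{y}]") for y in data.trans_year)
print(f"posterior mean annual survival: {np.mean(np.exp(-H)):.4f}")
print(f"exponential MLE exp(-D/E):      {np.exp(-deaths / exposure):.4f}")
print(f"posterior mean cumulative hazard: {H.mean():.4f} "
      f"(occurrence/exposure estimate {deaths / exposure:.4f})")
print("close agreement means the Poisson-increment likelihood and the "
      "vague gamma prior reproduce classical survival estimates.")
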