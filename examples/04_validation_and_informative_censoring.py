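"""Hold-out prediction, coverage checks, and the discrepancy mechanism.

First validates a well-specified fit: predicts the final year's count
from a model fitted without it and reports posterior-interval coverage
of the observed series.  Then hides 25% of deaths in the final period as
censorings -- informative censoring, which biases naive survival high --
and shows the correction factor absorbing the unobserved removals as a
negative value.
"""

from kappaipm import McmcConfig, ModelSpec, fit_ipm
from kappaipm.simulate import preset_wolf_like_scenario, simulate_dataset
from kappaipm.validation import holdout_predict, ppc_coverage, split_final_year

scenario = preset_wolf_like_scenario(seed=8)
dataset = simulate_dataset(scenario)
spec = ModelSpec(rho_form="changepoint", rho_changepoint=18, surv_form="constant",
                 kappa_breaks=(17, 24), v=float(dataset.counts.v))
config = McmcConfig(n_chains=2, n_burnin=1000, n_iter=1500, seed=4)

head, rec_head, held = split_final_year(dataset.counts, dataset.recruits)
pred = holdout_predict(head, rec_head, dataset.records, spec, config, held[1:])
print(f"held-out year {pred.year}: predictive mean {pred.mean:.0f}, "
      f"95% PI ({pred.ci_low:.0f}, {pred.ci_high:.0f}); "
      f"observed range ({pred.observed_low:.0f}, {pred.observed_high:.0f}); "
      f"mean inside range: {pred.inside}")

samples, data = fit_ipm(dataset.counts, dataset.recruits, dataset.records, spec, config)
report = ppc_coverage(samples, data)
print(f"posterior 95% intervals cover the observed counts in "
      f"{100 * report.coverage:.0f}% of years; residual signs "
      f"{report.n_positive_resid}+/{report.n_negative_resid}- "
      f"(sign-test p = {report.sign_test_p:.2f}) -- no systematic bias")

# same population, but a quarter of final-period deaths go unobserved
biased = simulate_dataset(
    scenario.replace(informative_fraction=0.25, informative_periods=(2,),
                     kappa_values=(0.0, 0.0, 0.0))
)
samples2, _ = fit_ipm(biased.counts, biased.recruits, biased.records,
                      spec.replace(v=float(biased.counts.v)), config)
s3 = samples2.summary("kappa[3]")
print(f"\nwith informative censoring (25% of final-period deaths hidden):")
print(f"kappa[3] posterior mean {s3['mean']:+.4f}, Pr(<0) = {s3['p_negative']:.2f}")
print("the negative correction quantifies removals the telemetry no longer "
      "shows -- the model's discrepancy-detection mechanism.")
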