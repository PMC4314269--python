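# kappaipm

**Are the counts adding up?** `kappaipm` is a Bayesian integrated
population model (IPM) for wildlife monitoring programs that collect three
overlapping data streams — annual population counts, annual counts of new
recruits, and radiotelemetry survival records — and want to know whether
they tell the same story.  The model reconciles all three through one
latent abundance trajectory and estimates, per management period, a
*correction factor* κ: the additive rate of unobserved additions (κ > 0)
or removals (κ < 0) needed to make the demographic rates explain the
observed growth.  A persistently negative κ is evidence of an unobserved
loss process — classically, informative censoring in the telemetry data,
where animals lost to follow-up were in fact dying (e.g. cryptic
poaching).

It is written for quantitative ecologists and biometricians analysing
recovering or managed populations (the motivating scale is a gray-wolf
recovery: ~20 animals growing to several hundred over three decades).

## The model

With P_t the true abundance in year t and μ_t = log P_t:

* counts: N_t ~ lognormal(μ_t, v²), v the log-scale measurement SD
  (quarter of the reported count range by default, or estimated);
* recruits: R_t ~ Binomial(P_{t−1}, ρ_t), fitted via its normal
  approximation N(P_{t−1}ρ_t, P_{t−1}ρ_t(1−ρ_t));
* survival records {a, b, δ} expanded to counting-process form,
  dM_i(s) ~ Poisson(Y_i(s) · dΛ₀(s) · e^{f(z_t)}), with gamma-process
  priors on the baseline-hazard increments dΛ₀(s) and annual survival
  σ_t = exp(−e^{f(z_t)} Σ_{s∈t} dΛ₀(s));
* process: **P_t = P_{t−1}(ρ_t + σ_t + κ_t)**, closed population, with
  κ_t ~ U(−1, 1) constant within analyst-defined periods.

Density dependence in ρ_t and in the hazard enters through z_t, the
standardized log abundance of the previous year, with constant, linear,
quadratic, or change-point (broken-stick) functional forms chosen by BIC
with a 2-unit equivalence rule.  Inference is Metropolis-within-Gibbs
with conjugate baseline-hazard proposals; convergence is judged by
Gelman–Rubin PSRF and the Brooks–Gelman multivariate PSRF (upper limits
< 1.1).  See `docs/methods.md` for the full account.

No real dataset ships with the package: a first-class synthetic-data
generator (`kappaipm.simulate`) emulates the whole generative process —
including informative censoring — so every capability is testable end to
end.

## Worked example

`examples/01_simulate_and_fit.py` simulates a 32-year wolf-like program
(survival ≈ 0.77, broken-stick recruitment, three periods with
κ = 0, +0.02, −0.04) and refits it:

```
simulated 32 years, 465 telemetry records, quarter-range measurement SD v = 0.0498

fit finished in 11.899 s; multivariate PSRF = 1.041 (convergence rule: < 1.1)
kappa[1]: posterior mean -0.0083 (SD 0.0276), 95% CrI (-0.064, +0.047), Pr(<0) = 0.62   [generating value +0.000]
kappa[2]: posterior mean +0.0425 (SD 0.0359), 95% CrI (-0.028, +0.114), Pr(<0) = 0.12   [generating value +0.020]
kappa[3]: posterior mean -0.0632 (SD 0.0267), 95% CrI (-0.114, -0.008), Pr(<0) = 0.99   [generating value -0.040]
mean annual survival across years: 0.787 [generating value 0.771]
```

Each 95% credible interval covers its generating value; the final
period's negative correction — unobserved removals of ~4% of the
population per year — is detected with Pr(κ < 0) = 0.99.  The other
examples demonstrate the survival-likelihood oracles (`02`), BIC form
selection and the proportional-hazards check (`03`), and hold-out
validation plus the informative-censoring mechanism (`04`).

A thin CLI wraps the same functions for shell use:

```bash
kappaipm simulate --out data/ --seed 1
kappaipm fit --counts data/counts.csv --recruits data/recruits.csv \
             --telemetry data/telemetry.csv --out fit/
kappaipm select --counts ... --out scan/     # BIC form scan
kappaipm validate --counts ... --out val/    # hold-out + coverage
kappaipm recover --replicates 20 --out rec/  # simulate-and-refit study
```

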