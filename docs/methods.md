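# Methods

## The model

`kappaipm` implements a Bayesian hierarchical integrated population model
(IPM) for three data streams collected by a long-running wildlife
monitoring program:

* annual population counts, reported as low–high ranges;
* annual counts of new recruits, also reported as ranges;
* individual telemetry survival records, each a triplet {a, b, δ} of
  entry time, exit time, and a death/censoring indicator.

One latent abundance trajectory ties the streams together.  Writing
P_t for the true abundance in year t and μ_t = log P_t,

* **Counts.**  N_t ~ lognormal(μ_t, v²), with v the measurement SD on the
  log scale.  v may be fixed in advance (by default from the quarter-range
  rule: one quarter of the reported range width, expressed relative to the
  midpoint so it lives on the log scale) or estimated under a U(0, 100)
  prior.
* **Recruits.**  R_t is binomial from the previous year's population with
  recruitment rate ρ_t; the model uses the normal approximation with mean
  P_{t−1}ρ_t and SD sqrt(P_{t−1}ρ_t(1−ρ_t)).  The synthetic-data generator
  draws the exact binomial, so the fitted approximation is genuinely
  exercised.
* **Survival.**  Records are expanded onto a fine time grid in counting-
  process form: at-risk indicators Y_i(s) and event increments dM_i(s)
  over intervals [s, s+ds), with dM_i(s) ~ Poisson(Y_i(s) · dΛ₀(s) ·
  exp(f(z_t))).  The integrated baseline-hazard increments dΛ₀(s) are
  constant within each interval and carry independent Gamma(c·dΛ₀*, c)
  priors — a vague gamma-process prior (c = 0.001) centred on a guessed
  annual hazard spread evenly over the grid.  The annual survival implied
  by the hazard is σ_t = exp(−exp(f(z_t)) Σ_{s∈t} dΛ₀(s)).
* **Process.**  P_t = P_{t−1}(ρ_t + σ_t + κ_t).  The population is closed:
  immigration and emigration are assumed to cancel.  κ_t is the
  *correction factor* — an additive rate on the growth multiplier,
  uniform(−1, 1) a priori, constant within analyst-defined periods (e.g.
  management regimes).  A negative κ means unobserved removals were needed
  to reconcile the counts with the demographic rates; a positive κ,
  unobserved additions.

Density dependence enters through z_t, the standardized log abundance of
the previous year (log, centre, scale; the population SD convention,
configurable to n−1).  Recruitment can be constant (a single shared
rate), exchangeable per-year rates with a Beta(α₁, α₂) prior, linear or
quadratic in z_t, or a broken stick — two slopes joined at a change year,
sharing the value β₀ there.  Continuity at the change year is our
parameterization choice, made for identifiability; a discontinuous
variant (separate intercepts) is available via
`continuous_changepoint=False`.  The survival hazard multiplier exp(f(z))
supports constant, log-linear, log-quadratic and broken-stick forms.

By default the model conditions on the previous year's *observed* count
wherever the previous abundance appears (process mean, recruitment mean,
covariate).  This removes the latent trajectory from the sampler and
greatly improves mixing.  Without it, the process recursion is
deterministic given the rates, so the only extra unknown is the initial
abundance log P₁; that "latent" mode is implemented and tested but slower.
In latent mode the covariate standardization constants are taken from the
observed counts rather than the latent trajectory, to avoid a circular
definition.

The observation symbols are kept dimensionally strict: P_t is an
abundance, μ_t its log, and the lognormal count density is parameterized
by (μ_t, v).

## Sampling

Metropolis-within-Gibbs with a fixed block order per sweep: recruitment
parameters → baseline-hazard increments → hazard coefficients →
correction factors → (ridge move) → measurement SD.  Proposal scales
adapt during burn-in only (every 50 sweeps, toward ~0.3 acceptance) and
freeze afterwards, keeping the retained chain Markovian.  All randomness
flows from a single seed; identical seed, config and data give bitwise-
identical chains.

Two blocks deserve note:

* **Baseline hazard.**  The survival-data conditional of dΛ₀ given the
  covariate coefficients is a product of independent Gammas with shape
  c·dΛ₀* + events(s) and rate c + at-risk(s)·exp(f).  We use it as an
  independence proposal; its survival-likelihood and prior terms cancel
  exactly in the Hastings ratio, leaving only the count-likelihood ratio
  of the affected year (pure Gibbs when the model has no count data).
  Per-year blocks accept or reject independently because the conditioned
  likelihood factorizes over years.
* **Ridge move.**  ρ-level and κ are confounded through the growth
  multiplier: raising recruitment by δ and lowering every κ by δ leaves
  ρ+σ+κ — and hence the count likelihood — exactly invariant.  A
  dedicated joint move along this ridge (accepted on the recruit
  likelihood and priors alone) removes the slow diffusion that
  single-parameter walks exhibit along it.

Default run lengths are 3 chains with 10,000 burn-in and 10,000 retained
iterations.  Convergence is declared when the upper 97.5% confidence
limits of all univariate potential scale reduction factors (PSRF) and the
multivariate PSRF are below 1.1.  We implement the corrected Gelman–Rubin
statistic with the sampling-theory upper limit (degrees-of-freedom
adjustment (d+3)/(d+1) and an F-quantile on the between/within ratio) and
the Brooks–Gelman multivariate statistic in its largest-generalized-
eigenvalue form, reported as sqrt((n−1)/n + (m+1)/m · λ₁).  The interval
construction behind the "upper limit" is the standard sampling-theory
one; other software may differ in small samples.

Posterior storage keeps the scalar parameters plus the derived per-year
quantities (ρ_t, σ_t, P_t, and the per-year integrated hazard H_t); the
per-interval baseline increments are summarized by their running
posterior mean, with a flag to store them in full.  The deviance trace is
−2 × (count + recruit + survival log-likelihood), priors excluded.

## Model selection

The candidate forms for each process — constant, linear, quadratic, and
broken sticks changing at every year t in 3..T−3 — are fitted to that
process's own data with short runs, ranked by BIC = deviance + k·log(n),
and everything within 2 BIC units of the minimum is reported as an
equivalent winner.  Deviance is the plug-in value at posterior means
(`method="mean"` switches to the average of the deviance trace).
Parameter counting is explicit and reported with every result: the
baseline-hazard increments count as one effective block, each regression
coefficient as one, and a scanned change-point adds one.  n is the number
of recruit observations (T−1) or of at-risk record-intervals (ΣY).  The
scan's "constant" recruitment candidate is a single shared rate (k = 1);
the full IPM's no-relationship option is the per-year exchangeable form.

The proportional-hazards check augments the selected covariate model's
log hazard with z · log(time since record entry) at the record-interval
level and samples the interaction coefficient; a 95% interval away from
zero flags a hazard ratio that drifts over follow-up.  With a
covariate-free best model the check returns a structured not-applicable
result.

## Validation

* **Hold-out.**  The final year's count and recruit observations are
  dropped (telemetry is kept; it covers the final transition), the model
  is refitted, and the held-out count is predicted through the process
  equation plus a lognormal observation draw.  The check passes when the
  predictive mean falls inside the held-out year's observed range.  The
  prediction provably uses no information from the held-out value.
* **Coverage.**  Per-year flags for whether the observed count lies in
  the 95% posterior interval of P_t, standardized log-scale residuals
  (log N_t − mean μ_t)/v, and a two-sided sign test for systematic over-
  or under-estimation.
* **Prior sensitivity.**  Refits under perturbed hyperparameters (e.g.
  ν_β ∈ {10, 100, 1000}, c ∈ {10⁻⁴, 10⁻³, 10⁻²}, narrowed κ support),
  reporting posterior shifts in units of the baseline posterior SD.

## The synthetic-data generator

The generator is first-class code and defines the study conditions for
every end-to-end test.  Its default (`preset_wolf_like_scenario`) mimics a
recovering large-carnivore population: 32 years from P₁ = 22 animals,
annual survival exp(−0.26) ≈ 0.771, broken-stick recruitment anchored at
0.49 with slopes +0.12/−0.10 per z-unit changing at year 18 (realized
rates ≈ 0.28–0.48, final abundance ≈ 980), three correction periods
(breaks at years 17 and 24) with κ = (0, +0.02, −0.04), count log-SD
v = 0.05 (reported ranges mid·e^{∓2v}, so the log-scale quarter-range
rule recovers ≈ v; exactly sinh(2v)/2), 15 newly collared animals per
year entering at uniform times, random censoring at 0.15/yr, and
administrative censoring at the study end.  Animals' death times follow
the piecewise-constant annual hazards; splitting their records across
years reproduces the 1–10 yearly-records-per-animal structure of real
telemetry programs.

The generator's broken stick anchors both slopes at z = 0, i.e. β₀ is the
recruitment rate at abundance e^{z_center}; z_center = 5 puts that
abundance (~148) where the default trajectory crosses its change year, so
the generating curve is effectively continuous there, in the same family
the model fits.

Informative censoring — the survival-analysis failure mode the correction
factor is designed to expose — is simulated by recording a death as a
censoring at the death time with probability `informative_fraction`,
optionally restricted to chosen periods.  Exposure is preserved and only
the event is hidden, which biases naive survival estimators high and
forces a negative κ in the affected period.

What the generator does *not* emulate: spatial or pack structure, age
structure, inter-annual environmental variation in survival, correlated
measurement errors between the count and recruit streams, and collar
failure as a distinct censoring cause.  Passing tests therefore show the
method's internal consistency and its power against the modeled
mechanisms, not robustness to these unmodeled features of real data.

## Numerical choices and edge cases

* Grid width ds defaults to 1/12 year.  A record at risk for part of an
  interval contributes the full interval's exposure; total exposure is
  correct to O(n_records · ds), so oracles that compare against
  occurrence/exposure estimators use ds = 1/48.  The model-year boundary
  defaults to 1 September (the entry criterion for young-of-year animals)
  and is configurable; the simulator uses calendar-aligned years.
* Rates outside (0, 1) and non-positive growth multipliers are handled by
  proposal rejection (posterior −∞), never clamping, preserving the
  stated prior supports.
* An event in a zero-intensity interval yields −∞, not an exception.
* Conjugate gamma draws are floored at 1e−300 to avoid log(0) in
  downstream prior evaluations; intervals with no events have shapes
  ≈ c·dΛ₀* and draw essentially zero hazard.
* Initialization is data-driven with per-chain jitter: rates from
  observed recruit/count ratios (least squares on the form's design for
  covariate models), baseline increments at their prior-smoothed
  occurrence/exposure values, κ near 0, latent log P₁ at the first
  observed count.  Twenty jittered retries precede a hard failure.
* Degenerate inputs are rejected with structured errors: non-contiguous
  count years, low > high ranges, all-degenerate ranges (v = 0), constant
  series in standardization, records outside the grid span, b = a.

## Problem sizes in the test suite

End-to-end checks run at sizes chosen for a single CPU: recovery and
calibration studies use 20 replicates of the preset scenario with 3×(2000
+2000) or 2×(~1000+1500) MCMC sweeps per fit (a few seconds each), and
form scans use 1 chain with 400+800 sweeps per candidate.  The survival
oracle uses a 200-record, one-year cohort where the exponential MLE and
Nelson–Aalen references coincide.  Longer default run lengths (10,000+
10,000) remain the recommendation for real analyses.

## Known limitations

* The conditioned-likelihood mode treats the previous observed count as
  error-free where it stands in for P_{t−1}; this matches the case-study
  design choice but slightly understates uncertainty in the rates.
* Per-year posterior survival summaries inherit Jensen inflation from
  exp(−H_t) at small risk sets.
* BIC's parameter count for a semiparametric baseline hazard is a
  convention (one effective block here), not a theorem; the conventions
  are switchable and always reported.
* The sampler is a random-walk scheme; posteriors with strong curvature
  (e.g. very small v) would mix poorly compared to gradient-based
  samplers, which are out of scope.
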