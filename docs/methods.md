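# Methods

## Time-response regression

For each reference species the model is a Gaussian generalized linear
model with identity link on the natural logs of both variables,
`ln EC = α + β ln ED + ε` — equivalently ordinary least squares on the
log pairs, and exactly equal to the normal-equations solution (tested
to 1e-10). The intercept α is always included: a pure
proportional-hazard power law without an intercept cannot represent the
observed absolute toxicity levels, and published coefficient tables for
this kind of model report a y-intercept. β < 0 is expected for
time-cumulative toxicants; a non-negative slope triggers a warning, not
an error, since the regression itself is still valid.

Diagnostics: D² (explained deviance; identical to R² under the
Gaussian identity model, and tested equal to the squared correlation of
observed and fitted logs), leave-one-out cross-validated MSE on the ln
scale (computed by literal refits; n is small), and coefficient
standard errors / covariance from the GLM.

**Influential points.** Observations with Cook's distance above a
threshold (default 1.0, configurable, `None` disables) are removed in
at most one re-fit pass, and every removal is recorded on the fitted
model and in the run log. The threshold of 1.0 is the conservative
classical rule; lower values remove more aggressively. The influence
pass is skipped when the fit is numerically exact (residual deviance
below 1e-10 of the null deviance), where Cook's distance degenerates.

**Prediction intervals.** Daily point estimates are
`exp(α + β ln d)`. 95% intervals come from a parametric bootstrap
(default 1000 draws) of (α, β) from their estimated Gaussian sampling
distribution; with n as small as 5–8 this is more stable than
residual resampling, which is still offered (`method="residuals"`).
Predictions past day 100, or past the model's inflection day if that is
smaller, are flagged as extrapolations.

**Inflection day.** The usable window is bounded by the first whole day
at which the relative decline between successive modelled daily
estimates, `1 − ((d+1)/d)^β`, falls below a threshold (default 0.05).
For β = −1.827 this gives day 36 and for β = −3.892 day 76 (verified
against a brute-force scan of the modelled EC sequence). The rule is
deliberately pluggable: "the change becomes negligible" admits several
formalizations (e.g. the continuous rate |β|/d < t gives days 37 and
78 for the same slopes), and the surface's 100-day cap is a
configuration default, not derived from the inflection rule.

## SSD fitting and selection

Five unimodal candidate families are fitted by maximum likelihood:
log-normal, log-logistic and log-Gumbel as location–scale families on
ln(concentration) (log-Gumbel, the type-I extreme-value distribution on
logs, is the inverse Weibull / Fréchet on the raw scale), and gamma and
Weibull on the raw scale with location pinned at zero. The log-normal
MLE is closed-form (mean and RMS deviation of logs, 1/n denominator);
the others are numerical with deterministic moment-based starting
values. Gamma and Weibull optimizations run on data normalized by the
geometric mean, so fits are scale-equivariant to high precision — a
property the whole pipeline inherits (rescaling all concentrations by k
rescales every PC by k, tested at 1e-9 for the forced log-normal path
and 1e-6 per family).

Selection is by minimum AICc (k = 2 for all families, so this is AIC
ordering plus the small-sample correction), with ties broken by a fixed
family order and Anderson–Darling / Kolmogorov–Smirnov statistics
reported for transparency. Goodness-of-fit in guideline practice is
partly a visual judgement; an information criterion is the reproducible
stand-in, and a per-day `forced_family` override exists for replicating
an externally made family choice. Samples below n = 8 (configurable)
are refused; with n = 3 the AICc correction is undefined and such fits
never win selection.

PCx is the (100−x)th percentile of the selected distribution; PAF at a
concentration is 100 × CDF. The round trip `PAF(PC(p)) = 100 − p` holds
to 1e-9 across all families (tested over fuzzed parameters).

**Bootstrap intervals.** Parametric: each replicate draws n values from
the original-data fit, refits the same family, recomputes each PC; the
CI is the 2.5/97.5 percentile across replicates (default 10,000 for PC
CIs, scaled down in tests). The point estimate is taken from the
original-data fit — deterministic and standard — with
`pc_point="bootstrap_median"` as an alternative. Replicate RNG streams
are split from the run seed by replicate index (SeedSequence spawning),
so results are independent of execution order; more than 20% replicate
non-convergence raises a bootstrap-instability error. Simulated
coverage of the nominal 95% PC95 interval at n = 32 from a log-normal
truth is verified to lie within 92–98% over 300 repetitions.

## TAFs and the surface

`TAF(d) = EC_modelled(d) / EC_measured` with the adjustment applied
multiplicatively, `EC_adj(d) = EC · TAF(d)`. This orientation makes
adjusted values decline with duration for β < 0 and is algebraically
the same as dividing by the ACR-like ratio
`EC_measured / EC_modelled(d)`. `EC_measured` — the reference species'
observed acute effect concentration at its standard test duration — is
always supplied explicitly in configuration, never inferred, so the
calibration is auditable; when it equals the model's own prediction at
the measured day, TAF(measured day) = 1 exactly.

One TAF per taxonomic class per day is applied to every species of
that class regardless of the species' own test duration (the shared
within-class-slope assumption). Classes without a reference model must
be mapped to one or explicitly marked `exclude` in the class map; an
unmapped class is an error listing the affected species, never a
silent drop. The acute LC50/EC50 → LC10/EC10 division by 5 happens
before TAF adjustment, so a day-d adjusted value is an estimated
chronic EC10 at that duration. Because the geometric mean commutes with
constant divisors, aggregating species before or after the division is
immaterial; the pipeline divides first, then geomeans.

Days run 1..100 by default; each day's slice is adjust → fit all
candidate families → select → PCs (+ bootstrap CIs when configured).
Per-day bootstrap seeds are spawned from the run seed, making exports
byte-identical across reruns with the same config + seed (tested).
Within a constant selected family every PC level is non-increasing in
day; family switches can introduce a small discontinuity at the switch
day, which is why monotonicity is only asserted under a forced family.

## ACR scenarios

Acute values are divided by a scalar ACR (defaults 10, 50, 100) or a
per-class table (class, geomean, min, max; geomeans computed from raw
per-species ratios when given), then pooled with observed chronic
values — chronic data pass through bit-identically and take precedence
on overlap — and an SSD is fitted with the same engine. For a scalar
ACR a on an acute-only set every PC scales by exactly 1/a; min/max
per-class ratios give the high/low comparison bands.

## Synthetic data

The generator defines the study conditions the tests and the
acceptance script run under:

* Community: 32 arthropod species, class mix Insecta 0.5 /
  Malacostraca 0.3 / Branchiopoda 0.2 (largest-remainder allocation →
  16/10/6), acute values log-normal with ln-scale location ln(100)
  µg/L and scale 2.3 (≈4 orders of magnitude across the set —
  daphnids are orders of magnitude more tolerant of neonicotinoids
  than mayflies), optional extra ln-scale measurement noise, standard
  acute windows of 2 d (Branchiopoda) and 4 d (others), purity 99% and
  quality 90% so screening keeps everything.
* Reference series: 7 durations per species within realistic test
  windows (1–9 d for the daphnid-like reference, 2–28 d otherwise),
  true coefficients (α, β) = (18.92, −3.892), (4.646, −1.827),
  (6.881, −0.737) spanning the observed slope range, multiplicative
  ln-scale noise sd 0.15.

What this emulates — and what it does not: real toxicity compilations
have heterogeneous endpoints, correlated sensitivities within genera,
reporting censoring, and class-specific SSD shape; the generator draws
i.i.d. log-normal values with clean power-law time series. Passing
tests therefore demonstrate the estimators and the pipeline's
statistical correctness under the stated model, not the biological
adequacy of the model for any particular chemical.

## Numerical choices and problem sizes

Tolerances: closed-form identities at 1e-10, quantile/CDF round trips
at 1e-9, the end-to-end analytic surface check at 1e-6 relative (it
accumulates a regression fit, a power-law rescale and a distribution
fit). Test simulations use 200 regression replicates, 300 coverage
repetitions × 500 bootstrap replicates, and surface bootstraps of
25–1000; these sizes give stable verdicts for the properties checked
while keeping the default suite quick to run. The acceptance script
uses the full day 1–100 surface, n_boot = 2000 for its interval, and
seeds derived from `--seed` via SeedSequence spawning (all < 2³¹).

## Known limitations

* No censored-data support; toxicity values are point estimates.
* No model averaging across families; one family per day.
* The within-class shared-slope assumption is structural; an optional
  `per_species_duration` rescaling is not implemented beyond the
  class-level TAF (classes without reference models must be excluded
  or mapped).
* The inflection rule is a heuristic bound on extrapolation, not an
  estimate of a biological change point.
* Mixture toxicity, exposure-pulse landscapes, and multi-stressor
  regressions are out of scope.
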