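# Methods

## The modelling problem

Momentary states (emotions, fatigue, intention, self-efficacy) vary
within a person over the day, and the question of interest is
prospective and *within-person*: when someone scores higher than their
own typical level right now, how does their activity in the following
minutes change?  The data structure is prompts nested in participants,
outcomes are minutes of light (LPA), moderate-to-vigorous (MVPA) and
total (TPA) activity in the 15/30/60/120-minute windows after each
prompt, and a large share of windows contain no activity at all.

## Two-part (hurdle) mixed model

Each determinant × intensity × window cell is modelled in two parts.

**Part 1 (occurrence).**  The dichotomised outcome (0 vs ≥ 1 active
minute) follows a logistic random-intercept model

    logit P(y_ij ≥ 1 | a_i) = α0 + β_w (x_ij − x̄_i) + β_b x̄_i + a_i,
    a_i ~ N(0, ω_a²).

**Part 2 (amount).**  On the observations with y ≥ 1, candidate
Gaussian, Poisson and NB2 random-intercept models are fitted and the
lowest AIC wins (AIC = 2k − 2ℓ with k the number of estimated
parameters; ties go to NB, then Poisson, then Gaussian, with a warning;
non-converged candidates are excluded).  NB2 uses a log link and
variance μ + μ²/θ.

The predictor is split into a between-person mean x̄_i and the
within-person deviation x_ij − x̄_i ("hybrid" or person-mean centering);
both enter every model, but only the within-person effect is surfaced in
the main report, as an exponentiated coefficient (OR for part 1, expB
for part 2) with a 95% Wald CI and a two-sided normal p-value at
α = .05.  No multiple-testing correction is applied across the 84 cells
of the default grid; a Benjamini–Hochberg column is included as
supplementary output only.

**Truncation.**  Fitting an *untruncated* NB to the positive subset is
the classical two-step reading of a hurdle model and is the pipeline
default.  It is not the exact likelihood of a process whose positives
come from a zero-truncated NB; the `truncated=True` option fits the
zero-truncated NB2 likelihood instead and is used for the
parameter-recovery tests, where generation and fitting must match for
the estimator to be unbiased.

## Estimation: adaptive Gauss–Hermite quadrature

The marginal likelihood integrates the random intercept out per cluster:

    L_i = ∫ ∏_j f(y_ij | η_ij + u) φ(u; 0, σ_u²) du.

For the non-Gaussian families the integral is evaluated by adaptive
Gauss–Hermite quadrature: a vectorised Newton iteration (analytic first
and second η-derivatives of each family's log-density) locates each
cluster's integrand mode û_i and curvature, and the Hermite nodes
(default 15) are re-centred at û_i and re-scaled by 1/√(−h″(û_i)).  The
Gaussian family uses the closed-form linear-mixed-model likelihood
(compound symmetry, Sherman–Morrison).  Optimisation is bounded
L-BFGS-B on (β, log σ_u, log θ or log σ_e), started at plain-GLM
estimates with σ_u = 0.5; standard errors come from the inverse observed
information (numerical Hessian) on the working scale.  A fitted σ_u
below 1e−3 is treated as a boundary solution: the model is refitted with
σ_u = 0 (the plain GLM) and flagged.

Accuracy anchors (all in the test suite): the quadrature matches dense
trapezoid integration to 1e−6 on small binary problems; σ_u = 0 fits
match statsmodels' IRLS GLM to 1e−6; the Gaussian path matches
statsmodels MixedLM (ML) to 1e−4; NB2 at θ = 10⁶ matches Poisson to
1e−3; the log-likelihood changes by < 1e−4 from 15 to 31 nodes (5-node
quadrature is ~2e−3 off on Bernoulli clusters, which is why 15 is the
default); row order is irrelevant to 1e−10.

## Accelerometry and linkage conventions

* ENMO = max(0, ‖(x,y,z)‖ − 1)·1000 mg, clamped before averaging, then
  1-s and 1-min clock-aligned epoch means.  Minutes without samples are
  *missing*, never zero; no non-wear detection is applied.
* Cut points: ≤ 57 mg sedentary, ≥ 104 mg MVPA, LPA in between.  The
  boundary values follow the explicit inequalities (57 → sedentary,
  104 → MVPA).
* Window origin: the first full minute boundary strictly after the
  trigger; the trigger's own in-progress minute is excluded because
  minute epochs cannot be split and it partially precedes the prompt.
* Coverage: a window's outcome is missing when the fraction of
  non-missing minutes falls below `coverage_min` (default 1.0,
  configurable); nothing is imputed.
* Overlapping windows of prompts less than 120 min apart are kept.

## EMA protocol conventions

Six 60-minute frames span 09:00–22:00; since no published frame layout
exists, the default places the first frame at the window start, the
last flush with the window end, and equal 84-minute gaps between frames
(start-to-start spacing 144 min); an explicit frame list can be
supplied.  Triggers are uniform inside their frame.  Reminders (+5,
+10 min) are metadata only — activity windows are anchored at the
trigger, which is also why the trigger (not the response completion)
is the window origin.  Validity: triggers outside every frame, or
beyond the sixth of a day, are invalid.  Compliance: a participant is
retained with ≥ ⌈scheduled/3⌉ completed prompts (14 of 42 at the
default scale).  Rates print with 2 decimals, means with 1.

## The synthetic-data generator

The generator is a first-class module, not a fixture: it encodes the
study design (64 participants × 7 days × 6 prompts, ~77% response) and
a fully parametric data-generating process so that every estimator can
be validated by recovery of known parameters.

* **Items**: x_ijk = μ_k + u_ik + e_ijk with u_ik ~ N(0, τ_k²),
  e_ijk ~ N(0, σ_k²).  The default 7-item panel uses plausible grand
  means for this population and splits each item's total SD so that 60%
  of variance is within-person — every default item passes the > 50%
  within-variance selection rule.  `likert_mode="discrete"` rounds and
  clamps to 1–7; recovery tests use `"continuous"` because
  discretisation is a measurement-coarsening bias that would otherwise
  be confounded with estimator error.
* **Activity**: a hurdle process per intensity for the *longest* window,
  driven by one configurable item (default: intention) through exactly
  the within/between decomposition the pipeline refits.  Positive draws
  are zero-truncated NB2 by rejection (default) or untruncated with
  0 → 1 replacement (a small documented bias).  Counts are capped at the
  window length with a logged warning; default intercepts keep caps
  rare (≲ 0.1%).
* **Nesting**: active minutes are placed uniformly at random among the
  longest window's minute slots, so the 15/30/60/120 counts are nested
  thinnings of one latent trace and count monotonicity holds by
  construction, as physics requires of real data.
* **Minute trace and raw signal**: the minute-level mode writes a
  continuous classified ENMO trace (class-conditional ENMO bands:
  sedentary U[0,57), LPA U(57,104), MVPA 104 + lognormal); where
  consecutive 120-min windows overlap, earlier windows keep their
  minutes and the *realized* counts read back off the trace become the
  authoritative ground truth, so linkage extraction always reproduces
  the observation table exactly.  The raw mode emits triaxial samples
  (unit gravity plus a horizontal circular oscillation of amplitude
  √((1+e/1000)² − 1)) whose vector norm is constant within the minute,
  so the processing chain recovers each minute's target ENMO to
  floating-point accuracy.
* **What it does not emulate**: circadian or weekday structure,
  autocorrelated item dynamics, informative missingness, device noise
  or calibration error.  Passing recovery tests therefore demonstrate
  estimator correctness under the stated model, not robustness to those
  real-data features.

## Validation sizes and expected behaviour

The statistical guarantee tests use: 200 replicates of 150 clusters ×
30 prompts for bias (|mean bias| < 0.05 on the link scale) and 95% CI
coverage (within [0.92, 0.98]) of the within-effect in both hurdle
parts; 500 replicates of 64 × 30 for type-I error ([0.03, 0.07] at a
null within-effect); and 100 replicates for the AIC comparison, where
NB2 data with θ = 1.5 should select the negative binomial in ≥ 90% of
runs.  These sizes complete in a few minutes on one CPU; the
acceptance script uses a single study-scale run plus a 20-replicate
family-selection check for the same reasons.

## Known limitations

* Random intercepts only; no random slopes, no autocorrelation, no
  crossed structures.
* Wald inference throughout (no likelihood-ratio or bootstrap CIs);
  coverage is slightly liberal for σ_u near zero.
* The default count-part likelihood ignores zero-truncation (see
  above); the option exists but is not the default, to mirror the
  two-step procedure the pipeline reproduces.
* Whether the count-family AIC comparison should use all observations
  or positives only is ambiguous in the classical description;
  positives-only is implemented (consistent with the hurdle's second
  part).
* No covariates beyond the determinant's within/between split (no time
  of day, day of week).
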