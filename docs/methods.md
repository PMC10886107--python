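# Methods

## Stabilometric variables

A trial is a uniformly sampled planar COP displacement (AP, ML, in mm).
All variables are computed after subtracting the trial-mean COP — the
"central point of the stabilogram", the standard posturographic
convention (not the first sample or the platform origin) — which makes
every feature invariant to stance location. With r[n] the planar distance
of sample n from the central point, N samples, and T = (N−1)·Δt the
analysed interval:

| family | resultant (COP) | 1-D components (AP, ML) | units |
|---|---|---|---|
| mean distance | MD_COP = ⟨r⟩ | MD_x = ⟨\|x_c\|⟩ | mm |
| RMS distance | RMS_COP = √⟨r²⟩ | RMS_x = √⟨x_c²⟩ | mm |
| excursion | ESC_COP = Σ‖Δ(ap,ml)‖ | ESC_x = Σ\|Δx\| | mm |
| velocity | VEL = ESC / T | same | mm/s |
| sway area rate | SWAY = (1/2T)·Σ\|ap[n+1]·ml[n] − ap[n]·ml[n+1]\| | — | mm²/s |
| mean frequency | FREQ_COP = VEL_COP/(2π·MD_COP) | FREQ_x = VEL_x/(4·MD_x) | Hz |

The sway area rate is the summed area of triangles formed by consecutive
centered samples and the origin (the rectified shoelace sum), i.e. the
area swept about the central point per unit time. The resultant mean
frequency is the rotation rate of a point circling the central point at
mean distance with mean velocity; the 1-D form divides by 4 because a
sinusoid of amplitude MD travelled at VEL completes VEL/(4·MD) cycles per
second. An alternative rotational 1-D form VEL/(2π·MD) is available via
`freq_component_form="rotational"`; the 4-based form is the default
because it is the established convention for component frequencies.

Exact identities used as test invariants: RMS_x ≥ MD_x (Jensen),
RMS_COP² = RMS_AP² + RMS_ML², max(ESC_AP, ESC_ML) ≤ ESC_COP ≤ ESC_AP +
ESC_ML (triangle inequality per step), translation invariance, scale
equivariance (linear features ∝ c, SWAY ∝ c², FREQ invariant), and
time-reversal invariance.

Conventions and degenerate cases:

- Any uniform sampling rate is accepted; fs is recorded in the output.
  Fixtures default to 50 Hz (platform documentation for the emulated
  device does not state its rate).
- T is computed from the data; a deviation of more than 1 s from the 60 s
  protocol is logged, not rejected.
- No filtering or detrending beyond mean-centering. An optional 4th-order
  zero-phase Butterworth low-pass (`lowpass_hz`) exists, off by default.
- A motionless trial or component yields zero distance/path metrics and
  NaN frequencies flagged in `undefined_freqs`; batch extraction never
  aborts on degenerate input.
- Fewer than 2 samples, non-finite values, non-monotone time or a
  non-uniform step (beyond 1e-9 relative) raise `InvalidTrajectoryError`.

On the analytic circle oracle (r = 10 mm, f = 0.5 Hz, 100 Hz, integer
cycles) all 16 features agree with their closed forms to < 0.1%.
Discretization errors shrink as O(Δt²) for the directly computed
features; the 1-D frequency ratios converge non-monotonically below the
~1e-4 level because numerator and denominator errors can cancel.

## Synthetic cohort generator

The generator produces trial trajectories with the statistical structure
the downstream model assumes, not biomechanically realistic
inverted-pendulum dynamics. Each axis is

    x(t) = s_i · [ OU(θ, σ) + A·sin(2π f_osc t + φ) + jerks ]

- **OU drift** — exact discretization x[n+1] = x[n]·e^(−θΔt) +
  ξ·√(σ²/(2θ)(1 − e^(−2θΔt))), the mean-reverting wander of the postural
  control loop; stationary sd σ/√(2θ). Exact discretization makes the
  sampled law independent of fs.
- **Oscillation** — amplitude A, frequency drawn per trial and axis
  uniformly from the phenotype's band, random phase; stands in for
  rhythmic involuntary movement.
- **Jerk train** — Poisson events (rate per second) of half-sine pulses,
  150 ms wide, height ±jerk_amp; stands in for abrupt excursions. The
  pulse shape is fixed; only rate and height are phenotype parameters.

The three phenotype parameter sets live in `src/copsway/defaults.yaml`.
They were calibrated by simulation so the group orderings of the
extracted features reproduce the qualitative contrasts the analysis
should detect: chorea < dystonia on MD_AP, RMS_AP and VEL_AP; chorea >
dystonia on FREQ_COP and FREQ_ML; chorea–dystonia > dystonia on VEL_AP
and FREQ_ML. Only orderings are calibrated — absolute levels are
unconstrained by any published per-group magnitudes — and with the
defaults the orderings separate by tens of pooled standard errors at 200
trials per group. Note that the excursion of a diffusion path grows with
√fs, so VEL levels are meaningful only at a fixed sampling rate (50 Hz
for all shipped defaults).

Cohort structure (defaults = the emulated study): 6/5/5 subjects in
dystonia/chorea/chorea–dystonia, 6 trials × 60 s; ages truncated normal
10.68 ± 3.62 years on [4.29, 18.22]; per-group therapy probabilities
1/3, 4/5, 2/5 (the observed fractions). Subject heterogeneity is
multiplicative on amplitude: scale_i = exp(b_i + β_age,g·(age_i − 10.68)
+ β_rx,g·therapy_i), b_i ~ N(0, σ_s²) with σ_s = 0.2 (a ±20% typical
amplitude spread, enough to make the random intercept clearly
identifiable at 6 trials without drowning the group signal); β_age =
−0.02/yr (sway amplitude declines modestly as postural control matures)
and β_rx = −0.15 (therapy damps involuntary movement) unless overridden,
both optionally per group to plant interactions. The log-linear form is
chosen deliberately: it is the simplest structure a linear mixed model
with a subject intercept can recover. FREQ features are scale-invariant,
so covariates and the random intercept planted this way do not move
them — their group differences come entirely from the phenotype dynamics.

Determinism: one `SeedSequence(design.seed)` spawns an independent child
stream for the subject draw and for every trial, so a design reproduces
its cohort bit-for-bit regardless of extraction order.

What the generator does **not** emulate: measurement noise and platform
filtering, non-stationarity within a trial (fatigue, attention), foot
repositioning between trials, floor/ceiling effects of severity scales,
and any dependence of dynamics (rather than amplitude) on age or therapy.
Passing recovery tests therefore show that the pipeline is correct and
well calibrated *for data satisfying its own assumptions*, not that the
emulated clinical effects are real.

## Outlier screening

Per outcome, the squared robust distance d² = ((x − median)/(1.4826·MAD))²
is compared to χ²(1, 0.975); flagged trials are excluded from that
outcome's model only. The robust location/scale makes the screen itself
resistant to the outliers it hunts; 1.4826 makes the MAD unbiased for the
sd under normality, giving a ~2.5% nominal flag rate on clean data. If
the MAD degenerates (more than half the values tied) the scale falls back
to IQR/1.349, then to flagging nothing, with a logged warning.

Within `analyze_all` the distances are referenced to each *group's* own
median and MAD. A pooled screen on strongly group-separated outcomes
mistakes entire groups for outliers (on the default cohort it would flag
~35 of 96 FREQ_COP trials); group-referenced screening instead yields the
few isolated exclusions per outcome the procedure intends. Pooled and
classical bivariate (outcome, age) variants remain available via the
`screen` option. Groups with fewer than 5 observations are left
unscreened (no robust scale is estimable), logged. Heavy-tailed outcomes
(the FREQ family, whose per-trial oscillation frequency draws widen the
within-group spread) legitimately exceed the nominal rate.

## Mixed model

Per outcome: y ~ group + age_c + therapy + group:age_c + group:therapy +
age_c:therapy with a per-subject random intercept, REML estimation
(statsmodels MixedLM), Wald z tests, α = 0.05, no multiplicity correction
across the 16 outcomes. The observation unit is the trial (6 per
subject) — repeated observations are what make the random intercept
meaningful. Age is centered at the full-cohort mean (one convention
across outcomes, recorded in the result). Dystonia is the reference
level, so the group coefficients are the chorea-vs-dystonia and
chorea–dystonia-vs-dystonia contrasts; relabelling the reference changes
contrast names and signs but not fitted values or likelihood (tested).

Numerical conventions:

- The design matrix is built explicitly (dummy coding, centered-age
  products). Rank deficiency — e.g. therapy constant within a group — is
  resolved by a greedy QR-rank filter; dropped coefficients are reported
  as *not-estimable* rows so every result always carries the full 10-term
  set (intercept, 2 group contrasts, age, therapy, 2 group×age,
  2 group×therapy, age×therapy).
- A random-intercept variance below 1% of the residual variance is
  flagged `singular` (the optimizer rarely lands exactly on the
  boundary); singular or non-converged fits are returned and flagged,
  never raised.
- Wald z (no degrees-of-freedom correction) is used deliberately and
  recorded in the result metadata. At 60 subjects all covariates are
  between-subject with ~50 effective degrees of freedom, so the realized
  type-I error runs slightly above nominal (≈5.5% rather than 5%) and
  95% interval coverage slightly below (≈94%) — the measured values sit
  at 5.1% and 95.0% in the acceptance run. Satterthwaite/Kenward–Roger
  corrections are out of scope.

## Validation performed

The test suite computes, rather than asserts from memory: hand-arithmetic
examples for every formula; the circle closed forms at 0.5% tolerance; a
naive loop reimplementation agreeing to 1e-9 on random trajectories; the
metric invariants above on 100 random paths; OU stationary variance and
seed-distribution checks; planted-ordering separation; screen calibration
on 10⁴ normal draws; noiseless coefficient recovery to 1e-4; Wald
coverage within [90%, 98%] over 200 replicates and per-term null
rejection within [3%, 7%] over 1500 replicates at 60 subjects × 6 trials
(replicate count sized so the binomial Monte-Carlo error is small against
the band width); full-pipeline sign-pattern recovery in ≥95% of 200
replicates at 60 subjects; and the structural contract of the default
16-subject study (96 trials, 16 outcomes × 10 terms). Simulation sizes
(60 subjects for the statistical-validity studies, 200 replicates) were
chosen as the smallest giving stable Monte-Carlo estimates.

## Known limitations

- Group inference at the emulated study's true size (16 subjects) is
  fragile by construction: with 5–6 subjects per group a single subject
  dominates its group mean, and interaction terms are frequently
  non-identifiable in a given draw. The validity studies therefore run at
  60 subjects; the 16-subject default demonstrates structure, not power.
- Raw-scale outcomes from a multiplicative generator are heteroscedastic
  across groups; the LMM's homoscedastic residual is then an
  approximation (sign recovery is unaffected; standard errors on the
  amplitude features are mildly optimistic for the wider groups).
- The jerk process adds heavy tails that the Gaussian residual does not
  model; the outlier screen absorbs the worst of it.
- VEL/ESC of the OU component scale with √fs; comparisons across
  sampling rates require either a fixed fs or the low-pass option.
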