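# Methods

`puptrack` reimplements, as one tested pipeline, the computational analysis
of movement ontogeny in naive grey seal (*Halichoerus grypus*) pups tracked
by Fastloc GPS from a sandbar breeding colony on a continental shelf. The
raw telemetry of the original deployment was never deposited, so the
package pairs the analysis chain with a synthetic world that emulates the
study's tags, habitat and behaviour; every stage is validated against that
world, against brute-force oracles, and against the arithmetic of the
published summary tables.

## The movement model

Displacements between regularly spaced locations follow a first-difference
correlated random walk in local planar kilometre coordinates:

    d_t = gamma_t * d_{t-1} + eps_t,     eps_t ~ N(0, diag(sx^2, sy^2))

`d_t` is the displacement over one time step (default 6 h) and
`gamma_t` in (0, 1) is the *move persistence* — the autocorrelation of
successive displacements in both speed and direction. High values
(conventionally > 0.70) indicate directed travel; low values (< 0.30)
indicate area-restricted search; the band between is ambiguous.
Persistence is linked to covariates on the logit scale with a Gaussian
random intercept per animal:

    logit(gamma_t) = x_t' beta + b_i,    b_i ~ N(0, sigma_b^2)

The design matrix holds an intercept plus up to seven covariates: sex
(female indicator), weaning mass (kg), weaning length (cm), post-weaning
fast duration (d), week at sea (integer from the first at-sea fix),
distance to the 0 m isobath (km), and ln water-column depth (m, floored at
1 m over land). Covariates enter on their natural scales; the optimizer
rescales internally for conditioning only.

Assumptions worth stating plainly: locations are treated as error-free
(Fastloc precision at the reported filter settings); the innovation
covariance is diagonal with no x–y correlation (an extension point); the
persistence recursion restarts at each track boundary using the track's
own first displacement, sharing nothing across gaps; random slopes and
fixed-effect interactions are not supported.

### Estimation

The marginal likelihood integrates the random intercepts out with a
per-animal Laplace approximation. Because each animal contributes a single
scalar `b_i`, the inner problem is one-dimensional: a damped Newton
iteration on the analytic first and second derivatives of the conditional
log-likelihood finds the mode for all animals simultaneously (vectorised
with index sums), and the log-determinant correction is a scalar per
animal. Against an adaptive 21-node Gauss–Hermite oracle the approximation
agrees to ~1e-8 near the generating parameters on small instances; the
error grows for large `sigma_b` (>= 0.5) on short series, a regime the
study design does not approach (its scale is `sigma_b` ≈ 0.2).

Fitting is by maximum likelihood in two stages — a bounded Nelder–Mead
pass from moment-based starting values (the pooled regression of `d_t` on
`d_{t-1}` sets the intercept; residual standard deviations set the
innovation scales), then L-BFGS-B polishing. Variance parameters are
optimised on the log scale with a floor of 1e-3; a random-intercept
standard deviation stuck at the floor is reported as zero and held fixed
when the observed information is inverted for Wald standard errors. The
boundary case is real, not an artifact: with ~22 animals and four
between-animal covariates, the maximum of the marginal likelihood sits at
`sigma_b = 0` in a nontrivial fraction of replicates (verified against the
quadrature oracle), the same singularity the trip-characteristic mixed
models exhibit.

Model selection uses AICc = −2LL + 2k + 2k(k+1)/(n−k−1) with
k = (fixed effects) + (random-intercept sd, if present) + 2 innovation
sds, and n = the number of likelihood-contributing steps; candidates are
ranked by ΔAICc with Akaike weights. One-step-ahead residuals
(d_t − γ̂_t d_{t−1})/σ̂ per axis, with plug-in random effects, check
whiteness; variance inflation factors screen multicollinearity;
leave-one-animal-out refits report per-coefficient 5%/95% quantiles and
the percentage of refits falling inside the full model's 95% Wald
interval.

## The analysis chain around the model

**Quality control.** Three filters per animal, in order: fewer than five
satellites; Fastloc residual strictly greater than 30 (a residual of
exactly 30 is kept); then a single forward sweep removing any fix whose
great-circle speed from the last retained fix exceeds 10 km/h. The sweep
is deliberately simple and auditable; tests confirm its output is a
maximal feasible subset (no removed fix could be restored without
violating the threshold). Each removed fix carries exactly one reason —
the first failing filter — and the audit satisfies
n_input = n_kept + Σ removals.

**Haulout and trips.** A fix is hauled out if (i) the tag's wet/dry logic
flagged it, (ii) the water column at the nearest grid cell is <= 5 m, or
(iii) it lies within 10 km of the colony, measured to the nearest point of
a polyline along the 43-km island axis rather than to the centre point
(a centre-point radius would misclassify the island's ends). Runs of
consecutive at-sea fixes bounded by haulout fixes become trips when their
span exceeds 24 h; shorter bouts are logged and excluded; a bout truncated
by the end of the record is an incomplete trip, excluded from trip
statistics. Trip metrics are fix-to-fix: duration from first to last
at-sea fix (a lower bound), cumulative haversine distance, mean speed,
and the following haulout duration from the first hauled-out fix to the
next trip's first at-sea fix. Types: A = both endpoints at the colony,
B = exactly one, C = neither.

**Regularization.** Filtered streams split at every haulout bout and at
every transmission gap strictly over 48 h; segments with fewer than 50
fixes are dropped. Surviving segments are linearly interpolated
coordinate-wise onto an exact Δ-grid starting at the first fix (default
Δ = 6 h; 3/4/6/8 h supported through a diagnostic loop that fits the null
model per Δ and reports persistence standard errors and residual
autocorrelation — selection is left to the user). Each interpolated
location gets depth (nearest cell, >= 1 m), ln-depth, distance to the
0 m isobath derived from the same grid, and week at sea.

**Trip models.** Trip frequency (complete trips / deployment days, one row
per animal) is an ordinary linear model; ln trip distance, ln trip
duration and ln haulout duration (one row per complete trip) carry a pup
random intercept, fitted by ML through `statsmodels.MixedLM` so that AICc
and likelihood-ratio comparisons across fixed-effect structures are valid.
When the profiled likelihood degenerates at the zero-variance boundary the
fit falls back to its OLS limit with the singular flag set (df still
counts the attempted variance). Marginal and conditional R² use the
variance-partition formulas R²m = σ²f/(σ²f+σ²re+σ²res) and
R²c = (σ²f+σ²re)/(σ²f+σ²re+σ²res).

## The synthetic world

The generator supplies the study conditions: a 6°×5° shelf grid (0.02°
cells) with an island whose crest stands ~3 m above sea level, a shallow
apron, three offshore banks (crests 35–55 m), two basins (220–260 m), two
exposed skerries that provide non-colony haulout substrate, and a shelf
break beyond which depth exceeds 1000 m. Cohorts draw per-sex biometrics
at the deployment's scale (males 55.7 ± 4.74 kg, 112.0 ± 3.38 cm; females
54.5 ± 6.31 kg, 111.2 ± 2.37 cm; mass–length correlation 0.55; post-
weaning fasts 23.9 ± 4.25 / 19.1 ± 6.56 d; deployments 82.7 ± 46.38 d
truncated to 10–175 d).

Latent movement runs the persistence process forward at a 90-minute step
with the published coefficient magnitudes as generative defaults
(intercept 11.747, sex −0.452, mass 0.0151, length −0.105, postwean
−0.0507, week −0.0355, distance-to-shore −0.00525, ln-depth 0.502;
`sigma_b` 0.2) and innovation sd 2 km per axis, giving realistic ~2 km/h
surface speeds. Trips alternate with haulout windows (lognormal durations
moment-matched to 8 ± 6 d at sea and 33.6 ± 29 h ashore); after a trip's
scheduled end the walk acquires a homing drift of magnitude
(1−γ)·cruise·Δt toward the chosen haulout site — colony with probability
0.6, otherwise a skerry — so arrival is continuous while the innovation
autocorrelation structure stays intact. Haulouts pin the animal to a
shore cell (depth <= 5 m).

The tag emulator attempts a fix every 15 minutes, thinned by a surfacing
Bernoulli (p = 0.6), suppresses fixes once the tag has been hauled out for
20 minutes (the entry-boundary fix carries the haulout flag), draws
satellite counts from a categorical on 4–11 with 8% mass at 4 and
residuals from an exponential with mean 8, and displaces a configurable
fraction of at-sea fixes (default 2%) far enough to violate the 10 km/h
filter over the realised gap to their neighbours. Which fixes are
corrupted is recorded, so filter recall and false-removal rates are
measurable exactly.

What the generator does not emulate: dive behaviour, tides, measurement
error on retained fixes, site fidelity beyond a colony/skerry dichotomy,
and any dependence of trip scheduling on sex or body size. Passing tests
therefore demonstrate that the pipeline recovers what its assumptions
encode, not that those assumptions hold for real seals.

## Validation design and known scale effects

Estimator validation uses cohorts generated *at the model's own time
step* (22 animals × 260 six-hour steps, the study's scale) with realistic
covariate structure: habitat covariates follow mean-reverting AR(1)
excursions (φ = 0.9 at 6 h, i.e. decorrelation over a few days, matching
movement across banks and basins) around modest animal-level offsets.
Under that design all six identifiable coefficients recover their signs in
every converged replicate, median relative bias of the week and ln-depth
effects is under 25%, and pooled 95% Wald coverage is ≈ 92%. The weaning-
mass effect (0.0151) is smaller than its own sampling error at this design
— as in the source fit, where it was non-significant — so its sign cannot
recover deterministically; it is checked through interval coverage.

The full pipeline (snapshot tags → QC → interpolation → 6-h fitting of a
90-minute latent process) attenuates logit-scale coefficients: temporal
aggregation and resampling smooth the displacement series, a scale effect
this family of analyses is known to exhibit (fitting at too fine a step
drives all persistence estimates toward 1). End-to-end tests therefore
assert structural recovery — outlier recall, haulout/trip boundaries
within one fix interval, model convergence, persistence in range — while
quantitative recovery claims live at the model scale.

## Numerical choices and degenerate inputs

Logits are clipped at ±30 before the sigmoid; variance floors are 1e-3
(optimizer bounds) and 1e-12 (Laplace denominator); the inner Newton caps
steps at |2| and stops at gradient 1e-9 or 50 iterations; observed
information uses central differences with relative step 1e-4. Empty fix
streams yield empty outputs and zero-count reports; single-fix trips have
distance 0 and undefined speed; coincident timestamps in the speed sweep
are dropped unless the position is identical; off-grid locations skip the
depth rule (haulout) or flag the step (covariates). All timestamps are
UTC; intervals are half-open [start, end); distances use a spherical
Earth of radius 6371 km.

## Problem sizes

Test and acceptance runs are scaled to desk hardware as the package's own
choice of problem size: recovery uses 22 × 260-step cohorts (a few seconds
per fit), leave-one-out stability 10 animals × 150 steps, and the
end-to-end pipeline 12 pups; the analysis drivers under `analysis/` run
the full 22-pup scenario in about a minute.
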