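# puptrack

Movement ontogeny of naive grey seal (*Halichoerus grypus*) pups on a
continental shelf, rebuilt as a tested Python pipeline. Newly weaned pups
leave their natal sandbar colony with no parental guidance; how their
at-sea behaviour develops over the first months of life is read from
satellite-tag tracks through two complementary analyses:

1. **Trip characteristics** — Fastloc GPS fixes are quality-controlled,
   hauled-out periods detected (tag wet/dry flag, water column <= 5 m, or
   within 10 km of the colony), at-sea bouts longer than 24 h become
   trips, and linear (mixed) models relate trip frequency, distance,
   duration and post-trip haulout duration to sex, weaning size and weeks
   of experience.
2. **Move persistence** — tracks regularized to a 6-h step are fitted
   with a move-persistence mixed-effects model: displacements follow a
   first-difference correlated random walk
   `d_t = γ_t d_{t−1} + ε_t`, with the behavioural index `γ_t ∈ (0, 1)`
   (directed travel near 1, area-restricted search near 0) linked to
   covariates by `logit(γ_t) = x_tᵀβ + b_i`, `b_i ~ N(0, σ_b²)` a pup
   random intercept. The marginal likelihood is maximised with a
   per-animal Laplace approximation; models are ranked by AICc and the
   winner is stress-tested with one-step-ahead residuals, VIFs and
   leave-one-animal-out refits.

The original telemetry was never deposited, so the package includes a
first-class synthetic world — bank-and-basin bathymetry around a sandbar
island, pup cohorts at the deployment's biometric scale, latent tracks
with known persistence dynamics, and a Fastloc tag emulator with haulout
suppression, quality artifacts and injected outliers — against which every
stage is validated with known ground truth. The per-animal deployment
summary and the published model-ranking rows ship as fixtures so all
arithmetic derivable from them is recomputed, not copied.

## Worked example

Fit the persistence model to a synthetic cohort generated at the study's
scale (22 pups, ~260 six-hour steps each) with the published coefficient
magnitudes as ground truth:

```python
from puptrack.simulate import simulate_model_cohort
from puptrack.mpmm import fit_mpmm, classify_gamma

md, truth = simulate_model_cohort(n_animals=22, n_steps=260, seed=7)
fit = fit_mpmm(md)
print(fit.formula)
print(fit.beta.round(4))
```

```
~ sex_female + mass + length + postwean + week + dist_shore + ln_depth + (1 | id)
            estimate      se       z       p
intercept     8.4396  2.7362  3.0844  0.0020
sex_female   -0.3770  0.1212 -3.1098  0.0019
mass          0.0080  0.0102  0.7899  0.4296
length       -0.0670  0.0274 -2.4440  0.0145
postwean     -0.0742  0.0108 -6.8778  0.0000
week         -0.0335  0.0131 -2.5489  0.0108
dist_shore   -0.0068  0.0007 -9.2607  0.0000
ln_depth      0.5309  0.0640  8.2966  0.0000
```

Every identifiable effect recovers its generative sign and magnitude
(truth: sex −0.452, length −0.105, postwean −0.0507, week −0.0355,
dist_shore −0.00525, ln_depth 0.502): pups lose persistence with
experience (week), over shallower water and farther from shore, and
females travel less persistently than males; the weaning-mass effect is
tiny by construction and, as in the field data, not distinguishable from
zero. `fit.gamma` carries the per-step behavioural index
(`classify_gamma(fit.gamma)` tallies directed travel / intermediate /
area-restricted search), and `fit.aicc` feeds model ranking.

## Full synthetic study

The numbered drivers under `analysis/` run the whole chain on a 22-pup
synthetic deployment and write tables under `results/analysis/`:

```bash
python analysis/01_simulate_study.py     # world, cohort, tag streams
python analysis/02_quality_control.py    # satellite/residual/speed filters
python analysis/03_trips.py              # haulouts, trips, trip types
python analysis/04_regularize.py         # 6-h tracks with covariates
python analysis/05_persistence_model.py  # mpmm selection, residuals, LOO
python analysis/06_trip_models.py        # trip-characteristic (mixed) models
python analysis/07_published_arithmetic.py  # deployment-table + AICc checks
```

The same chain is available as a library call
(`puptrack.pipeline.run_pipeline`) or a CLI (`puptrack simulate | qc |
trips | regularize | mpmm | tripmodels | run --config run.yaml`).

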