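# msdom — multi-state diel occupancy models for camera-trap communities

Wildlife occupancy analyses usually ask *where* a species occurs. Camera
traps also record *when*, and many mammals shift the diel timing of their
site use in response to development, season and risk. `msdom` implements the
multi-state diel occupancy model (MSDOM): each site-season is in one of four
mutually exclusive latent states —

| state | meaning |
|---|---|
| 1 | site not used |
| 2 | used in the day only |
| 3 | used at night only |
| 4 | used both day and night |

with state-occupancy probabilities ψ¹…ψ⁴ linked to site covariates and an
imperfect, state- and season-dependent observation process. The package
covers the complete workflow for a community camera-trap study:

- **detection processing** — merge paired cameras, keep independent
  detections (>20 min apart, or multiple individuals in frame), classify
  day/night from sunrise/sunset (NOAA solar routine or a supplied table),
  anchor 24-h occasions at the species-season hour with fewest detections,
  and code occasions to states 1–4;
- **covariates** — PC1 of four correlated landscape variables in a 1-km
  buffer (forest cover, residential cover, road density, housing density),
  oriented so positive = more forest; a prey index (independent prey
  detections per trap-night, split by diel period); stacked two-season
  designs with a winter indicator (summer = reference);
- **the model** — full parameterization (multinomial logit over states 2–4,
  state 1 reference) or reduced parameterization (independent day-use and
  night-use propensities θ_D, θ_N, so ψ⁴ = (ψ²+ψ⁴)(ψ³+ψ⁴)); marginal
  likelihood over the latent state in log space;
- **inference** — Logistic(0, 1) priors on coefficients (flat
  Beta/Dirichlet on intercept-only probability parameters), MCMC with
  Laplace-initialized adaptive Metropolis plus Student-t independence
  proposals, Gelman–Rubin convergence checks (<1.1), conditional predictive
  ordinate (CPO) model ranking over the per-species model set
  ({full, reduced} × {null, season, pca, season+pca, season×pca}, plus prey
  forms for mesocarnivores), and effect probabilities η = Pr(β > 0);
- **prediction** — posterior median and 95% credible envelopes for state and
  marginal occupancy (ψ²+ψ³+ψ⁴) along the development–forest gradient;
- **synthetic data** — a generator that emulates the 240-site two-season
  study design with known truth, down to raw timestamped records that
  round-trip exactly through the processing chain.

## Worked example

Simulate data at the emulated study scale and fit the full season+pca model:

```python
import numpy as np
from msdom import simulate as sim
from msdom.model import MSDOM

truth = sim.default_truth("season+pca", "full", seed=5)
cfg = sim.ScenarioConfig(n_sites=240, n_occasions=42, truth=truth, seed=7)
history, latent, design = sim.simulate_state_history(cfg)

model = MSDOM(history, design, parameterization="full")
res = model.fit(draws=2000, warmup=1000, chains=3, seed=1)
print(res.summary().round(3))
```

```
                           mean     sd   lo95  median   hi95    eta   rhat
occ[day]:intercept       -0.506  0.200 -0.900  -0.498 -0.108  0.007  1.003
occ[day]:winter          -1.622  0.396 -2.444  -1.627 -0.831  0.000  1.002
occ[day]:pca              1.145  0.219  0.730   1.138  1.563  1.000  1.001
...
det4[daynight]:winter     0.357  0.085  0.182   0.361  0.530  1.000  1.000
```

`occ[day]:pca` is the development–forest effect on day use (generating value
0.92): its mean is 1.145, the 95% credible interval [0.73, 1.56] covers the
truth, and η = 1.000 is strong evidence of a positive effect — day use rises
with forest cover. All R̂ < 1.1, so the chains agree
(`res.converged → True`), and `res.cpo_score` (12350.3 here) is the model's
CPO ranking score (lower = better predictive support).

Seasonal detection shifts and occupancy predictions:

```python
print(res.detection_summary().round(3))
#            mean   lo95   hi95  eta         evidence
# day      -0.560 -0.791 -0.332  0.0  strong negative   (winter lowers day detection)
# night     0.457  0.322  0.600  1.0  strong positive
# daynight  0.357  0.182  0.530  1.0  strong positive

res.predict_states(season="winter", grid=np.array([-2, 0, 2]))
# e.g. marginal occupancy rises from 0.244 (developed, pca=-2)
#      to 0.962 (forested, pca=+2), median with 95% envelope
```

The same pipeline runs from the shell: `msdom simulate | process | fit |
predict`, each taking a YAML config, a seed and an output directory, and
writing a manifest (config hash, seed, versions) beside its artifacts.

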