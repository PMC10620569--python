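# Methods

## Model

Each stacked site-season row *i* carries a latent diel-use state
s_i ∈ {1: none, 2: day, 3: night, 4: day-and-night}, fixed for the whole
season (closure); a site's summer and winter rows are separate stacked rows.
Each 24-h occasion *j* yields an observed state y_ij from a row-stochastic
matrix Θ[s, o] = Pr(observe o | true state s) with the structural zeros the
state definitions imply: row 1 is (1,0,0,0); a day-use site can only be
observed as state 1 or 2; a night-use site as 1 or 3; a day-and-night site
as any state. The marginal likelihood of a row sums the latent state out:

L_i = Σ_s ψ_s(x_i) Π_j Θ_w(i)[s, y_ij],

with missing occasions contributing a factor 1. Because Θ is constant within
a row (it depends only on the row's season w), the per-row counts of
observed states 1–4 are sufficient, and the row likelihood is computed as a
4-vector log-sum-exp over states. All likelihood work is in log space:
with ~42 occasions raw products underflow. Structurally zero observation
cells are floored at 1e-300 inside the sampler's objective so impossible
combinations contribute ≈ −690 per occasion instead of NaN; the user-facing
`site_loglik` takes exact logs and returns −inf for impossible histories.

**Occupancy links.** Full parameterization: multinomial logit over states
2–4 with state 1 the reference, ψ_s = exp(x·β_s)/(1 + Σ_t exp(x·β_t)); the
day-and-night state is free. Reduced parameterization: two latent use
propensities θ_D = logit⁻¹(x·β_D), θ_N = logit⁻¹(x·β_N) combined as
independent Bernoullis, so ψ⁴ = θ_D θ_N equals the product of the marginal
day-use and night-use probabilities (ψ²+ψ⁴)(ψ³+ψ⁴). This propensity
formulation is the coherent reading of "ψ⁴ derived from ψ² and ψ³":
multiplying the exclusive-state probabilities themselves cannot produce a
simplex.

**Detection.** Every model lets detection vary by state and season:
p^D and p^N are logit-linear in (intercept, winter) for true states 2 and 3.
Given true state 4, the full parameterization uses a 4-category multinomial
logit (observed 1 as reference) with an intercept and a winter effect per
observed category; the reported day/night season effect α^DN is the winter
coefficient of the observed-state-4 category. A switch
(`shared_state4_season`) collapses the three winter effects to one shared
coefficient; the three-coefficient form is the default because the
state-4 observation distribution has three free categories and there is no
a-priori reason their seasonal shifts coincide. The reduced parameterization
instead composes row 4 from independent day and night detection,
(p^D p^N etc.), so it has no separate α^DN — reduced-model detection
summaries therefore omit the day/night row.

## Priors and sampling

Coefficients (occupancy and detection) get diffuse Logistic(0, 1) priors.
For intercept-only probability parameters this is exactly a flat Beta(1, 1)
on the probability scale (the logit of a Beta(1,1) variate is standard
logistic), so no special casing is needed for reduced null models; the full
null model's occupancy intercepts get a flat Dirichlet(1,1,1,1) on the
4-simplex via the softmax Jacobian (log-prior Σ_s log ψ_s). Because
detection always carries a winter effect, the state-4 observation simplex is
never a plain probability parameter and its coefficients use Logistic(0, 1).

Posteriors are low-dimensional (6–20 parameters) and smooth, so sampling
uses a Metropolis scheme built for that regime: an L-BFGS search finds the
posterior mode, a finite-difference Hessian gives a Laplace covariance, and
each chain starts from a draw of that Gaussian. The kernel mixes (50/50) a
Gaussian random walk — covariance seeded with the Laplace matrix, adapted
Haario-style during warmup with a Robbins–Monro step-size targeting 0.234
acceptance — and Metropolized independence proposals from a Student-t (df 4,
Laplace covariance × 1.3) at the mode. Independence moves decorrelate the
chain when the posterior is near-Gaussian; the random walk guarantees local
exploration where it is not. Adaptation freezes after warmup. Defaults:
3 chains, 2,000 warmup + 2,000 kept draws (chain settings are a package
choice). Convergence requires Gelman–Rubin PSRF < 1.1 for every parameter
(classic between/within ratio, floored at 1); non-converged fits warn and
are excluded from model ranking.

**Model comparison.** CPO_i is the harmonic mean of per-draw site
likelihoods (computed on up to 1,000 evenly thinned draws); the model score
is −Σ_i log CPO_i, lower better. A zero likelihood for any draw makes CPO_i
undefined and the score +inf, with a warning. Scores within 0.01 are treated
as ties and the reduced (more parsimonious) parameterization wins.
η = Pr(β > 0) is the fraction of draws strictly positive; η ≥ 0.90 / ≤ 0.10
is read as strong positive / negative evidence.

## Processing conventions

- Independence gap: strictly more than 20 min since the immediately
  preceding **raw** record of the site × species (chained gaps), matching
  the literal rule and making the filter idempotent; >1 individual in frame
  is always independent.
- Day is the open interval (sunrise, sunset); timestamps exactly at either
  boundary are night.
- Occasion anchor: argmin over the 24 raw hourly counts of independent
  detections (no circular-kernel smoothing, which would introduce an
  unspecified bandwidth); ties break to the smallest hour; no detections at
  all → hour 0 with a warning.
- An occasion counts as observed if a camera was active during any part of
  it; it is missing only when no deployment interval overlaps it at all.
- Sun times come from a supplied per-date table or from the NOAA sunrise
  equation (zenith 90.833°), accurate to a couple of minutes at
  mid-latitudes; a single fixed study UTC offset is assumed.
- Prey index: independent prey-species detections per **trap-night** (the
  standard effort unit), split by diel period, per site-season; standardized
  jointly over day and night values (mean 0, sd 1) before entering the
  model. Prey is matched to diel state: the day-use predictor uses the day
  index, night-use the night index, and the day-and-night state their mean.
- PC1 is computed on centered, unit-variance variables; its sign is forced
  so the forest-cover loading is positive.

## Synthetic-data generator

The generator emulates the target study design: 240 sites × 2 seasons ×
42 daily occasions, a standardized development–forest score per site
(N(0,1), shared across seasons), 5% missing occasions by default, constant
within-season day windows (05:30–19:30 summer, 07:00–16:45 winter), and
default effect magnitudes |β| ∈ [0.3, 1.5] with moderate intercepts — the
signal-to-noise regime such designs actually resolve. Raw-record simulation
places events ≥ 30 min apart, ≥ 15 min inside the diel windows, and keeps
night events within the occasion's calendar day, so the processing chain
reproduces the generated history exactly (the round-trip oracle used in
tests). It does **not** simulate spatial autocorrelation between sites,
animal movement, inter-species interactions, or seasonal drift in sun
times within a season — passing tests show the estimator and pipeline are
correct under the model's own assumptions, not that real communities meet
them.

## Validation studies and problem sizes

Two replicate studies (run by both the test suite and the acceptance
script): (1) recovery — 20 replicates of the full season+pca model at
240 × 2 × 42 with a fixed truth; checked that 95% credible intervals cover
the truth for ≥ 80% of parameter-replicates and intercept posterior-mean
bias < 0.15 on the logit scale; fits use 2 chains × (800 warmup + 1,000
draws), enough given the independence-proposal mixing (R̂ ≈ 1.01).
(2) selection — 20 replicates per regime at 240 × 2 × 21 occasions,
intercept-only truths: a full-model truth with ψ⁴ = 0.55 where independent
use would give 0.36, and a reduced truth (θ_D = θ_N = 0.5); checked that
CPO prefers the generating parameterization in the majority of replicates.

## Known limitations

- The sampler is designed for the model family's small parameter counts; it
  is not suitable for high-dimensional random-effect extensions.
- CPO uses the harmonic-mean identity, which has heavy-tailed Monte-Carlo
  error; with the draw counts used here rankings are stable in the studies
  above, but scores between near-equivalent models should not be
  over-interpreted (hence the tie rule).
- Credible-envelope widths from thinned draws are empirical percentiles and
  wobble rather than widen monotonically at small draw counts; envelope
  ordering (lower ≤ median ≤ upper) is what the tests assert.
- No dynamic (colonization/extinction) occupancy, no spatial random
  effects, no state spaces beyond the four diel states.
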