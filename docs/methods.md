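# Methods

## Spatial support

The areal units are Voronoi cells of tower locations, clipped to the study
boundary — a standard proxy for tower coverage areas. Coordinates are
assumed planar; geographic (lon/lat) boundaries wider than 6° are refused
unless explicitly allowed, since Voronoi geometry and areas are meaningless
on raw degrees at country scale. Degenerate seed configurations (exact
collinearity) are retried with a seeded jitter of ~1e-9 of the boundary
diameter.

Adjacency is **rook**: two cells are neighbours iff they share a boundary
segment of positive length. Corner contacts are measure-zero artifacts of
clipping and do not count. The structure matrix is the graph Laplacian
R = D − A. Disconnected supports are allowed: each connected component gets
its own sum-to-zero constraint, and no edges are ever added silently.
Isolated cells are constrained to zero field.

**Variance scaling** (on by default, recorded in `PolygonSupport.scaled`):
each component's block of R is multiplied by the geometric mean of the
constrained marginal variances (diagonal of the Moore–Penrose pseudo-inverse
of the block), so that at τ = 1 the ICAR field has unit generalized
variance. This makes the loggamma hyperprior comparable across graphs of
different density. The geometric-mean convention is one of several in use;
it is switchable by building the matrix unscaled. Singleton components have
no defined variance and are left unscaled with a warning.

## Aggregation

Survey points are mean-aggregated per polygon; a point on a shared edge goes
to the lower polygon index (deterministic, measure-zero tie). Rasters are
summarized by mean/sum/mode over cells whose **centres** fall in the polygon
— simpler and deterministic compared with area-weighting, and adequate at
~1 km grain relative to cell sizes; mode ties break toward the smaller class
id. Log transforms use x → log(x + δ) with δ = 0 for strictly positive
features, else half the smallest positive value, recorded per feature.
An all-zero feature is an error, not a silent drop.

## Covariate selection

Pairs with |Pearson r| > 0.70 (pairwise-complete) are pruned in descending
|r|, dropping the feature with the larger generalizability rank (user
metadata; e.g. population layers travel better than birth registries, call
volumes better than tariff-specific charges). Already-dropped features
cannot trigger further drops; missing or tied ranks fall back to name order.
Large feature sets are pre-reduced by bidirectional stepwise selection on
partial t-test p-values at α = 0.05 (add most significant below α, then
drop any at/above α, iterate; alphabetical tie-break), capped at 30.
The survivors (≤ 20; 2^20 is the hard cap) are searched exhaustively with
Gaussian linear fits on a seeded random 80% training split.

AIC is computed in closed form from the residual sum of squares,
AIC = n log(2π RSS/n) + n + 2k, with k counting intercept, slopes and the
residual variance. "Near-identical" AIC is quantified as ΔAIC ≤ 2 (the
conventional support window, configurable); within the window the model with
fewest covariates wins, then the alphabetically first feature set. Multi-model
averaging is deliberately out of scope — downstream consumes a single design.

## The Bayesian spatial model

Gaussian likelihood with identity link for all three outcome flavours: the
modelled quantity is a polygon *mean*, and bounded outcomes (percentages,
bin-midpoint incomes) are not link-transformed. This is a documented
limitation: predictions for percentage outcomes can leave [0, 100] in
extreme extrapolation.

Priors: β ~ N(0, 10⁶) per coefficient after internal standardization of the
covariates (coefficients are reported back on the original scale);
loggamma(1, 5·10⁻⁵) on each log-precision, i.e. Gamma(1, 5·10⁻⁵) on the
precision itself — the long-standing default of the Bayesian
spatial-modelling ecosystem this model family comes from, and reported in
every output's metadata. The ICAR prior is intrinsic; identifiability comes
from one sum-to-zero constraint per connected component.

### Sampler

The posterior is explored by MCMC (default 4 chains × 5000 iterations, half
burn-in; split-chain R-hat and bulk ESS reported per scalar parameter,
R-hat ≲ 1.01 expected of an accepted fit). The design exploits the fact
that conditional on the two precisions the model is jointly Gaussian:

1. **Precisions.** (log τ_spatial, log τ_noise) take a joint random-walk
   Metropolis step targeting their *marginal* posterior, with the whole
   (β, u) block integrated out analytically (one Cholesky factorization per
   proposal). Updating the precisions conditionally on the field instead is
   an absorbing trap: once a chain visits a state with a collapsed field,
   the conditional for τ_spatial concentrates at ever larger values and the
   field can never re-inflate. The marginal walk sees the true ridge between
   the "smooth field" and "iid noise" explanations and crosses it.
2. **Gaussian block.** (β, u) is drawn exactly from its full conditional.
   The sum-to-zero constraints are enforced by sampling on an orthonormal
   basis of the constraint null space, so every draw satisfies them to
   machine precision; this is distributionally identical to sampling
   unconstrained and correcting by conditioning, without the correction
   step.

Chains initialize both precisions at the OLS residual precision — an even
prior split of residual variation between field and noise. This matters:
with spatially independent data a chain started at small τ_spatial begins
inside the basin of a metastable interpolating mode (field ≈ noise) that is
~e¹² times lighter than the dominant mode but slow to leave.

A structural caveat inherited from the Besag model itself: with one areal
observation per polygon, the split between field and observation noise is
only weakly identified. τ_noise posteriors are accordingly wide and
slow-mixing; β and the latent surface η = Xβ + u, which are what the maps
and validation consume, mix well regardless.

### DIC and prediction

DIC = D̄ + p_D with p_D = D̄ − D(θ̄), the plug-in deviance evaluated at the
posterior means of β, u and τ_noise. The non-spatial comparison model drops
u (plain Bayesian linear regression, conjugate Gibbs). Predictions are
per-polygon posterior mean and sd of either the latent surface η
("latent_mean") or a new areal observation ("replicate"), for every polygon
including unobserved ones.

## Validation

Hold-out metrics on a seeded 20% test split: RMSE, MAE, Pearson's r
(Spearman's ρ replaces it as the headline metric when the test set has
fewer than 100 polygons), and r² defined as the squared Pearson correlation
of observed vs predicted — not 1 − SSE/SST; the two differ for biased
predictions, and the explained-variance form is available by flag. The
stratum comparison uses the pooled-variance two-sample t (df = n_A+n_B−2),
not Welch: the pooled form is what classical df arithmetic such as "617
observations → 615 df" implies. Admin-level re-aggregation takes
intersection-area-weighted (optionally population-weighted) means of
polygon predictions and correlates them against supplied reference tables;
when the reference measures the share of people *below* a poverty line and
the outcome measures wealth, the expected correlations are negative.

## Synthetic studies

The generator emulates the study conditions end to end and is the main test
surface, because the real survey, tower and call-record data such analyses
use are proprietary. Defaults: 300 towers (100 urban in Gaussian clusters
of sd 0.04 around 3 centres, 200 rural uniform) on the unit square — urban
cells are then ~an order of magnitude smaller than rural ones, reproducing
the urban/rural resolution asymmetry; two smooth positive "RS-like"
covariates (low-frequency random surfaces, light noise) and one noisy
"CDR-like" covariate (weak spatial signal under heavy lognormal noise);
linear predictor β = (0.5, 0.8, −0.6, 0.4) on log-covariates; ICAR field at
τ_spatial = 4 on the scaled graph (field sd ≈ 0.5); observation noise at
τ_noise = 25 (sd 0.2); 85% of polygons observed. Outcome flavours: an
unbounded score (asset-index-like, values roughly −1.5 to 3.5 under a
suitable intercept), a percentage clamped to [0, 100] with the clamp
fraction reported, and a latent USD income reported through ascending bins
and re-expanded by bin midpoints. Bin edges are configurable (defaults span
0–1285 USD with roughly geometric spacing) because real income
questionnaires publish ranges, not edges. The field is drawn constructively
from the pseudo-inverse covariance restricted to the sum-to-zero subspace —
the standard sampler for intrinsic fields.

What the generator does *not* emulate: raw call detail records and their
feature engineering, actual satellite imagery, survey design effects
(cluster sampling, weighting), and measurement error in geolocation.
Passing tests therefore demonstrate that the pipeline recovers what it
assumes — correct geometry, selection optimality, calibrated posteriors,
DIC preferring the spatial model exactly when spatial correlation exists —
not that any particular real-world dataset satisfies those assumptions.

## Problem sizes and numerics

Test and acceptance runs use ~100–1000 polygons with short, well-mixed
chains (hundreds of iterations; the blocked sampler's β draws decorrelate
in a handful of iterations), 50 replicates for interval-coverage checks and
20 for DIC comparisons — sizes chosen so the whole suite runs on a laptop
core in minutes while keeping Monte-Carlo error well inside the asserted
tolerances. Dense Cholesky factorizations are used throughout (the supports
of interest are ≤ a few thousand cells); eigendecompositions for field
simulation and variance scaling are per-component. Degenerate inputs are
errors, not warnings: duplicate towers, towers outside the boundary,
rank-deficient designs on observed rows, non-finite outcomes, all-zero
features for log transform.

## Known limitations

- Gaussian identity-link likelihood for bounded outcomes (see above).
- Field/noise precision split weakly identified from single areal means.
- Cell-centre zonal statistics ignore partial raster-cell coverage.
- Voronoi cells are a coverage proxy; no antenna azimuth/power modelling.
- Single-best-model selection; no model averaging.
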