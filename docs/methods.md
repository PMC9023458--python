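# Methods

`corax` detects coupled bursts of species, phenotypic and climatic-niche
diversification on a time-calibrated phylogeny: the pattern in which a
nested clade (a radiating genus inside its family) speciates faster than
its background clade, expands in morphospace, and broadens its climatic
niche, all starting at roughly the same time. This note documents the
models, the estimators, the synthetic-data generator that the test suite
exercises them on, and the numerical and design choices a user should know
about.

## Trait models and likelihoods

Continuous traits evolve on a rooted tree with branch lengths in time
units. All rate parameters carry the variance units (trait-units²/time);
branch lengths are never rescaled to absorb rates. Under each model the tip
vector is multivariate normal, `x ~ N(z0 · 1, sigma2 · V(theta))`, with

- **BM**: `V_ij` = shared root-to-MRCA path length.
- **EB** (early burst): the per-branch integrals of `exp(r t)` telescope
  along root-to-MRCA paths, so `V_ij = (exp(r t_mrca) − 1)/r` with decay
  `r ≤ 0`. This closed form (rather than per-branch transformation) is what
  makes repeated likelihood evaluations cheap.
- **Pagel's lambda**: off-diagonal entries of the BM matrix times
  `lambda ∈ [0, 1]`.
- **OU, fixed root**: `V_ij = exp(−alpha d_ij)(1 − exp(−2 alpha t_mrca))
  / (2 alpha)` with `d_ij` the patristic distance.
- **OU, stationary root**: `V_ij = exp(−alpha d_ij) / (2 alpha)`
  (ultrametric trees only).

`z0` and `sigma2` are profiled in closed form (GLS mean;
`sigma2_hat = quadratic form / n`), leaving a 1-D search over the shape
parameter, run from a multistart grid plus bounded refinement. Bounds:
`alpha ∈ [1e-6/T, 50/T]`, `r ∈ [−10/T, 0]`, `lambda ∈ [0, 1]`, with `T`
the root age. EB, lambda and fixed-root OU contain BM on their boundary
(`r = 0`, `lambda = 1`, `alpha = 0`), and the optimizer always evaluates
that boundary, so their ML likelihood can never fall below BM's. The
stationary-root OU does *not* nest BM (its `alpha → 0` limit has divergent
stationary variance); no dominance guarantee is made for it. All fits are
ML, not REML, so AIC comparisons across models are valid; parameter counts
are BM 2, EB/OU/lambda 3.

Multivariate model choice for the phylogenetic PCA uses summed per-trait
AIC under a shared model — a deliberate simplification of a joint
multivariate criterion, adequate for picking one covariance structure.
Measurement error can be supplied as a per-species variance added to the
covariance diagonal (default 0); it is folded in through an inner 1-D
optimization and is an approximation, not a full errors-in-variables fit.

## Regression, ANOVA, ancestral states

PGLS profiles the coefficient vector by GLS under the chosen error model
(BM, or lambda with ML-optimized `lambda`); coefficient tests are t-tests
with `n − p` degrees of freedom using the unbiased variance rescaling.
Relative brain size is the residual of `log brain volume ~ log femur
length` under the lambda model, following the usual encephalization
workflow; the phylogenetic ANOVA is PGLS on a clade-membership dummy. Note
that a single-origin clade effect is statistically confounded with
phylogeny — such ANOVAs have low power by construction, which is the
expected behaviour, not a defect.

Ancestral states are joint GLS/ML reconstructions under BM: with `C` the
all-node shared-path matrix, internal states are
`z0 + C_nt C_tt^{-1} (x − z0)` and reported variances are the conditional
variances scaled by `sigma2_hat`; tip entries are the observations with
variance 0. Time-slice means interpolate states linearly along every branch
crossing a slice and average over the crossing lineages, optionally
restricted to or excluding a focal clade. Phenogram coordinates are one
`(time, state)` segment per branch.

## Rate-shift detection

**Two-rate Brownian (Brownie-style).** The covariance decomposes as
`C = C_bg + q · C_focal` over the painted branch sets (focal clade plus its
stem vs the rest); `q` is the focal/background rate ratio, optimized on the
log scale with the mean and overall scale profiled out. The LRT against the
single-rate model uses `chi²(1)`; a numerical guard enforces the nested
dominance `loglik_two ≥ loglik_single`.

**Stepwise trait-shift search (MOTMOT-style).** Greedy: every internal
clade with at least 5 tips on each side of the split is offered a
rate-multiplier regime; the best candidate is accepted if AIC improves by
at least 4 (each accepted shift costs 2 parameters: multiplier and
location); the search stops at 4 regimes. Defaults mirror the conventional
settings (minimum clade 5, maximum regimes 4, threshold 4).

**Stepwise diversification-shift search (MEDUSA-style).** Birth–death
likelihoods are the Nee reconstructed-process forms on branching times
(ages `x`, `r = λ − μ`, `a = μ/λ`):

- crown, conditioned on survival of both root lineages:
  `(n−2)ln r + n ln(1−a) + r Σ_{i≥2} x_i − 2 Σ_i ln(e^{r x_i} − a)`
- stem, conditioned on survival of the origin lineage at age `x0`:
  `(n−1)ln r + n ln(1−a) + r Σ x_i − ln(e^{r x0} − a) − 2 Σ ln(e^{r x_i} − a)`

(labelled-history constants dropped; they cancel within a search). Both
reduce to the textbook conditional Yule MLEs (`(n−2)/total length` crown,
`(n−1)/total length` stem), which the tests verify, and the BD MLE matches
ape's `birthdeath` on the same tree. Each candidate shift (node or stem,
clade of ≥ 5 tips) splits the branching times into the subclade partition
and the backbone with the clade collapsed to a stub; each partition takes
the better of Yule/BD by AIC; each shift costs one extra location
parameter. The acceptance threshold defaults to ΔAIC ≥ 7: with ~100
candidate positions examined per step, a threshold of 4 accepts spurious
shifts on roughly a fifth of homogeneous 100-tip trees, while true 2–3×
shifts improve AIC by 12+; 7 is the conventional "strong support" cutoff.
The partition-independence assumption after collapsing clades is the same
approximation the classic implementation makes.

**Pulled speciation rate.** The PSR curve is estimated as the slope of the
log lineage-through-time curve, by local-linear Gaussian-kernel regression
(bandwidth `T/6`) of log lineage count on event time, evaluated on an even
8-point grid and clipped to `[0, 5]`. This is a documented approximation to
grid-likelihood fitting of homogeneous birth–death models: the PSR is the
quantity all congruent BD models share, and for `μ = 0` it equals `λ`
exactly, which is the calibration the tests check (grid mean within
`[0.16, 0.24]` for pure-birth trees with `λ = 0.2`). Grid points avoid the
outer `1/(grid+1)` margins where the kernel has one-sided support.

## Disparity through time

Disparity is the mean squared Euclidean distance over unordered pairs
(`n(n−1)/2` denominator). The DTT curve records, at each internal-node age
from the root down, the mean relative disparity of the *internal* lineages
alive just after that branching — single-tip lineages carry no pairwise
disparity and are not averaged in, matching the classic implementation's
behaviour — normalized by the whole-tree disparity; the curve starts at
`(0, 1)` and a final `(1, 0)` point is appended at the present. Null
envelopes simulate BM tip data on the same tree (vectorized through a
tips × branches incidence matrix), each trait with its own single-rate ML
`sigma2`, or with an explicit rate map for the rate-informed null;
pointwise median and outward-rounded 2.5/97.5 order statistics form the
95% envelope. MDI is the trapezoid-rule integral of observed minus null
median over relative time (positive = more disparity late than expected).
Because the relative-disparity statistic is scale-free, the null curves do
not actually depend on the fitted `sigma2` for a single trait; the fit
matters only through cross-trait weighting.

Whole-curve envelope coverage is intrinsically clumpy: excursions are
strongly autocorrelated along the curve, so the probability that a matched
null curve stays inside the 95% envelope at ≥ 90% of points is about
0.85–0.94 depending on tree size and trait count (it is ~0.94 at 120 tips
and 8 traits, the configuration the acceptance tests use). Detecting an 8×
clade burst against the single-rate null likewise depends on clade
geometry: it is near-certain for a clade of ~10% of tips originating at
mid-depth, but a large or near-root accelerated clade inflates the
normalizing total disparity and hides itself — a property of the statistic,
not of this implementation.

## Geometric morphometrics

GPA centers each configuration, scales to unit centroid size, and
iteratively rotates to the running mean shape (SVD rotations with
reflections forbidden) until the mean changes by < 1e-8. The aligned set is
then put in a canonical orientation (principal axes of the mean shape,
first landmark's x non-negative), which makes the output exactly invariant
to arbitrary similarity transforms of the input. Centroid size is computed
before scaling. Semilandmarks are treated as fixed landmarks: no
bending-energy sliding, which biases shape distances slightly upward for
outline points; this is a known simplification.

The phylogenetic PCA estimates the evolutionary covariance as
`R = Xcᵀ C(θ)^{-1} Xc / (n−1)` with `Xc` the phylo-mean-centered data,
converts it to a correlation matrix, eigen-decomposes, and scores the
standardized data on the eigenvectors; percent variance sums to 100 by
trace conservation, and signs are fixed deterministically. The penalized
multivariate GLS of the inspiration workflow is replaced by these
unpenalized cross-products with an explicit guard (more traits than species
is an error advising dimension reduction) — a documented simplification.
Extreme shapes along an axis are `mean + score · (sd ⊙ eigenvector)`,
folded back to k × 2 coordinates; projecting them back returns the score
exactly.

The allometry test is a phylogenetic MANOVA of species mean shape on log
centroid size: Pillai's trace of the size term in whitened space (the
whitening uses an EB covariance with decay `−1/T` by default, a fixed
moderate value rather than a per-coordinate ML fit), with the p-value from
permuting the whitened residuals of the intercept-only model. GPA-aligned
coordinates are rank-deficient (4 similarity degrees of freedom removed),
so Pillai is computed on the non-degenerate eigen-subspace of `H + E`.
Size-free residuals are the GLS residuals of shape on log size and feed
directly into the pPCA.

Alpha-hull areas keep Delaunay triangles with circumradius ≤ alpha and take
the union area; as alpha grows this converges to the convex hull, and
collinear point sets get area 0 with a warning. Alpha is a required
argument (scores from different PCAs live on different scales); the
pipeline defaults to 2× the mean nearest-neighbour distance of the pooled
scores so that focal and background clades are compared with a common,
scale-appropriate alpha.

## Niche and geography

Occurrence thinning keeps one record per species per cell of a plain
degree grid with `cell_km/111` degree sides (no latitude correction —
"approximately 11 km"), the survivor being first in deterministic
(species, lon, lat) order, which makes thinning idempotent. The climate
PCA is a correlation-matrix PCA over all pooled records (eigenvalues sum
to the number of variables; exact invariance to record duplication);
species positions are mean scores on the first two axes (CLIM1,
temperature-like; CLIM2, precipitation-like in the synthetic data).
Presence grids index cells by `floor(coord/resolution)` (boundary records
go to the floor cell); range areas sum spherical cell areas
`(R Δlat)(R Δlon cos lat_c)` with `R = 6371 km` — a documented substitute
for an equal-area projection. Sympatric assemblages are the distinct
maximal per-cell sets of congeners of size ≥ 2 (counting co-occurring
pairs instead is available by flag).

## The synthetic radiation

The generator's defaults are the study-shaped conditions every test runs
under: a family crown age of 20 time units (origin window 18–22), a focal
clade activated exactly 10 units before present (window 8.8–11.3 scaled),
background speciation `λ0 = 0.2`, extinction `μ0 = 0.02`, focal
`λ1 = 0.4` — double the background, so the expected focal richness over 10
units is `e^{3.8} ≈ 45` species, the size of the radiating genus —
conditioned by rejection on 70–180 surviving family tips and ≥ 25 focal
tips. Tree simulation is forward Gillespie from two crown lineages with
the focal regime painted onto one surviving lineage at the origin time and
extinct lineages pruned.

Traits: a latent body-size trait (BM, `sigma2 = 0.02` log-units²/time, 4×
focal multiplier, +0.4 focal offset) read out by six log-linear
measurements with allometric slope 0.75 and independent BM residuals
(`sigma2 = 0.004`); an HWI-like dispersal trait (+0.3 focal offset); a
brain trait = 0.6 × femur + BM residual (+0.2 focal offset). Landmarks: a
23-point beak template (3 landmarks, 11 + 9 semilandmarks) plus three
tree-evolved latent shape factors, an allometric displacement, specimen
noise, and random similarity transforms so GPA has work to do.
Occurrences: two latent climate axes evolved by BM with the focal clade
shifted (−1, +0.5) and widened 1.5×, read out by three temperature-like
and three precipitation-like columns with independent noise; 60 records
per species around random geographic centroids.

What the generator does **not** emulate: spatially structured ranges (no
range-size expansion of the focal clade, no spatial autocorrelation of
climate), fossil or extinct sampling, measurement error in the linear
traits, semilandmark sliding geometry, and real climate-variable
collinearity structure. Tests passing on these data show the estimators
recover known truth under the model's own assumptions; they do not certify
behaviour under real-data pathologies (sampling bias, range errors,
phylogenetic uncertainty).

Determinism: one dataset seed expands to per-component child streams via
`numpy.random.SeedSequence.spawn`, and the pipeline seeds each stage
independently, so disabling one stage never changes another's numbers and
identical configurations give byte-identical reports.

## Problem sizes used by the tests and acceptance script

Module and acceptance tests run at desk scale, chosen as the sizes where
each statistical claim is comfortably true: 80–150-tip trees for fit and
calibration checks (500 tips for the boundary behaviour of the
birth–death extinction estimate, where the ML boundary mass needs large
n); 50-replicate power runs for shift localization; DTT batteries on a
120-tip tree with 8 traits and 200-simulation envelopes; 20 end-to-end
pipeline runs at 120 null simulations. The pipeline's DTT default remains
1000 simulations.
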