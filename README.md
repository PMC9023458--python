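# corax

Phylogenetic comparative tools for asking whether a nested clade — a
radiating genus inside its family — underwent **coupled bursts of species,
phenotypic and climatic-niche diversification**, the macroevolutionary
signature of a rapid global radiation such as that of the crows and ravens
within the Corvidae.

Given a time-calibrated tree, continuous trait tables, beak landmark
configurations and occurrence records with climate covariates, `corax`
answers, stage by stage:

1. **Did speciation accelerate in the clade?** Stepwise MEDUSA-style
   birth–death shift searches at nodes and stems (Nee reconstructed-process
   likelihoods on branching times, Yule/BD chosen per partition by AIC) and
   pulled-speciation-rate (PSR) curves on an 8-point time grid — the
   time-course of speciation shared by every congruent birth–death model.
2. **Did phenotypic evolution accelerate?** ML fits of Brownian motion,
   early-burst, Ornstein–Uhlenbeck and Pagel-lambda trait models
   (`x ~ N(z0·1, σ²V(θ))` with the model-specific covariance); two-rate
   "Brownie" tests of a focal clade against its background with a χ²(1)
   likelihood-ratio test; MOTMOT-style stepwise trait-rate shift searches.
3. **Did morphospace expand?** Generalized Procrustes alignment of beak
   landmarks, centroid sizes, phylogenetic PCA under the best-fitting
   evolutionary model, phylogenetic MANOVA of shape on size (Pillai's
   trace, permutation p), size-free shape residuals, and α-hull
   morphospace areas.
4. **When did disparity accumulate?** Disparity-through-time (DTT) curves
   of mean relative subclade disparity with simulation envelopes under a
   single-rate Brownian null and a rate-informed null, the MDI statistic,
   and clade-exclusion reanalysis.
5. **What traits moved with the radiation?** Phylogenetic regression
   (relative brain size as residuals of log brain on log femur),
   phylogenetic ANOVA of focal clade vs background, ancestral states,
   time-slice averages and phenogram coordinates; occurrence thinning,
   climate-space PCA (CLIM1/CLIM2), range areas and sympatric-assemblage
   counts.

A fully seeded synthetic-data generator produces Corvidae-shaped bundles —
a ~100–120-tip family tree containing a ~40-tip focal clade that starts
speciating twice as fast ~10 time units before present, correlated
size/shape traits with a 4× focal rate multiplier, clade-offset wing and
brain traits, beak landmarks with allometry, and per-species Gaussian
climatic niches — so every stage is testable against known truth without
any downloads.

## Worked example

```python
from corax import (SimulationConfig, simulate_dataset, fit_brownie,
                   search_diversification_shifts, estimate_psr)
from corax.disparity import dtt_null

ds = simulate_dataset(SimulationConfig(seed=42))
tree, part = ds.tree, ds.partition
print(f"family tree: {tree.n_tips} species, focal clade: "
      f"{len(part.tip_set(tree))} species, root age {tree.root_age:.1f}")

shifts = search_diversification_shifts(tree)
print(shifts.summary())
print(f"background speciation rate: "
      f"{shifts.background['lambda']:.3f} /unit time")

psr = estimate_psr(tree)
pre = psr.psr[psr.ages >= 10].mean(); post = psr.psr[psr.ages < 10].mean()
print(f"PSR before clade origin: {pre:.3f}; after: {post:.3f}")

two = fit_brownie(tree, ds.traits["lin1"], part)
print(two.summary())

dtt = dtt_null(tree, ds.traits[[c for c in ds.traits
                                if c.startswith("lin")]], nsim=1000, seed=1)
print(dtt.summary())
```

prints

```
family tree: 118 species, focal clade: 41 species, root age 20.0
Stepwise shift search: 1 shift(s) accepted
  AIC trajectory: 599.40 -> 590.21
  shift at node 97 (node): lambda=0.3558, mu=0, model=yule, loglik=-79.3, k=1
background speciation rate: 0.165 /unit time
PSR before clade origin: 0.209; after: 0.207
Two-rate Brownian (focal clade incl. stem vs background)
  sigma2 background = 0.0302014
  sigma2 focal      = 0.0880622 (ratio 2.92)
  loglik single/two = -75.6404 / -67.4290
  LRT = 16.4227 (df=1), p = 5.068e-05
DTT curve over 118 time points; null of 1000 simulations, MDI = 0.0767, 63 exceedance(s)
```

Reading the output: the diversification search accepts one shift — a regime
inside the focal clade speciating at 0.356/unit time against a background
of 0.165, roughly the 2× ratio the generator planted; the two-rate Brownian
model estimates a 2.9× body-size rate in the focal clade (truth 4×) and
decisively rejects a single rate (p ≈ 5e-5); the DTT curve of the six
linear measurements shows positive MDI (excess disparity late) with 63 time
points above the 95% single-rate envelope.

The same analyses run from the shell on a bundle directory:

```bash
corax simulate --out bundle/ --seed 42
corax validate bundle/
corax run bundle/ --seed 1 --out results/   # writes report.json + CSVs
corax psr bundle/
```

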