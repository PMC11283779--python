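# Methods

This note documents the statistical models, numerical choices, and known
limitations of `ouregimes`.

## Trees and time

Branch lengths are millions of years throughout; no unit autodetection is
attempted. Trees are stored as parent-pointer arrays; node *depth* is time
from the root and node *age* is time before present, with the deepest tip
defining age 0. Polytomies are never resolved: the Mk pruning recursion,
the OU covariance construction, and the simmap sampler all operate on
arbitrary out-degree. Fossils are attached by inserting a node on the
branch above the host clade's MRCA at the requested stem age, with each
fossil's branch length equal to stem age minus tip age; the likelihood
core works on the resulting non-ultrametric tree without special casing
(fossil tip ages are not part of the published record for the motivating
dataset, so they are configuration, defaulting to 50 Myr — Eocene — per
fossil).

## Size correction and PCA

Species values are arithmetic means over specimens taken *before* the
log-shape transform `log10(trait_mm / mass_g^(1/3))`. Masses come from a
separate species-level table (literature masses rather than specimen
masses, since most museum specimens lack them). Fossil masses are imputed
by ordinary least squares of `log10(mass)` on `log10(geometric mean of all
linear measurements)` fitted to extant flyers — the log–log scale is the
standard allometric choice and is recorded in the prediction metadata —
then pushed through the identical size-correction path. PCA is an
eigendecomposition of the trait covariance matrix with divisor *n*
(matching the R `princomp` convention used in the motivating analysis);
component signs are arbitrary, so tests compare only sign-invariant
quantities. Whether extinct rows enter the PCA is a flag on the pipeline,
as published variance fractions may reflect either choice.

## Regime histories

Locomotor categories are painted onto regimes by four schemes: `loc4`
(identity) and three mergers (`loc3a` glider+flyer, `loc3b`
arborealist+glider, `loc3c` ground+arborealist). The regime history is an
equal-rates Mk model — a single transition rate `q` between all state
pairs, uniform root prior — fitted by maximizing the pruning likelihood
over `log q` (bounded scalar minimization, tolerance 1e-10). Equal rates
with a uniform prior is the default of the standard simmap tooling and is
the only Mk variant implemented; all-rates-different and hidden-rate
models are out of scope.

Stochastic character maps are drawn exactly from the posterior of
histories given tips and `q`: node states by backward–forward conditional
sampling from the pruning partials, then each branch by
endpoint-conditioned CTMC path sampling — forward rejection up to a
per-branch retry cap (default 10,000), falling back to uniformization
(jump count sampled from its exact conditional distribution, jump times as
uniform order statistics, states by a conditioned discrete chain). The
sampler is validated against brute-force enumeration of the root-state
posterior and against a naive forward-rejection oracle for the conditional
transition-count distribution.

## OU and BM likelihoods

All likelihoods are exact multivariate-normal densities with non-random
root. For a tip at depth `T` the OU mean integrates the piecewise-constant
optimum along the root-to-tip regime history with weights
`exp(-α(T−t1)) − exp(-α(T−t0))` per segment; the covariance between tips
`i, j` is `σ²/(2α) · exp(-α d_ij) · (1 − exp(-2α t_ij))` with `t_ij` the
shared path time and `d_ij` the divergence time — the general
non-ultrametric form, continuous down to the BM limit `σ² t_ij` at
`α = 0` (implemented with `expm1` for small-`α` stability).

Root handling: OU models pin the root value to the root regime's optimum
(the common default of multivariate OU software); a `root_mode="free"`
switch estimates it by GLS instead, since published fits may reflect
either convention. BM always estimates its root state.

Fitting profiles everything linear out of the likelihood: conditional on
`α`, the optima (and free root) are GLS estimates and `σ²` has a closed
form, so the univariate search is one-dimensional in `log α` — a 16-point
grid over `[1e-6, 100/tree height]` followed by bounded quasi-Newton
polish from the best starts (≥3 restarts; convergence 1e-12 on the
profiled log-likelihood). Covariance solves use Cholesky with a jitter
ladder (0, 1e-12, 1e-10, 1e-8 relative) before declaring singularity.
Boundary estimates of `α` are flagged on the result.

Multivariate fits use a diagonal `α` (one pull rate per PC dimension,
shared across regimes — a full `α` matrix is an identifiability burden the
data cannot support), a full positive-definite `σ²` parameterized by its
Cholesky factor, and per-regime optimum vectors profiled by GLS;
L-BFGS-B over `(log α_1..d, chol σ²)` with randomized restarts. The
reported multivariate half-life is the mean of the per-dimension
half-lives `ln 2 / α_m`.

AICc uses `n` = number of species (univariate) or species × dimensions
(multivariate); this convention is recorded on every fit and is a known
comparability caveat between univariate and multivariate tables. Model
ties are broken toward fewer parameters. Optima larger than ten times the
observed trait range are flagged in the run manifest rather than
suppressed (extant+extinct multivariate fits are known to enter this
artifact regime).

For bootstrap and power workloads, thousands of refits share one
(tree, map) covariance structure; a dedicated profiler caches the Cholesky
factor, design matrix, and normal equations on a 32-point `log α` grid so
each refit costs one triangular solve per grid point plus a parabolic
refinement step. This is an implementation detail only: it computes the
same profiled maximum as the general path.

## Uncertainty

Bootstrap CIs are percentile intervals (not BCa) over replicates pooled
across character maps, with per-map summaries retained; each replicate
simulates traits under the fitted model on the generating map and refits
the same specification on that map (no re-sampling of histories within a
replicate). More than 20% refit failures is an error. Power analysis
simulates datasets under both fitted models, computes the likelihood-ratio
statistic `2(logL_alt − logL_null)` by refitting both models on every
dataset, and reports exceedance of the null distribution's 95th
percentile.

## Synthetic data

The generator mirrors the motivating study's design: a birth–death tree
(default birth 0.2/Myr, death 0.05/Myr) conditioned on its tip count
(default 230) by stopping the forward simulation when the extant count
first reaches the target — extended to just before the next event so
terminal branches have positive length — pruned of extinct subtrees and
rescaled to 70 Myr depth; an equal-rates CTMC over the four locomotor
categories (default `q` 0.01/Myr from a ground-dwelling root, giving
regime frequencies of the same order as the empirical 117/71/16/27 split);
and traits sampled by exact per-segment Gaussian OU transitions (`α` = 0
falls back to Brownian increments). Latent log-shape values become
millimetre measurements via `10^z · mass^(1/3)` with log-normal masses
(median ~100 g, ln-sd 1.8) and multiplicative specimen noise (default CV
3%, two specimens per species), so the ingestion path can be exercised end
to end and inverts exactly when noise is zero.

Preset configurations: `strong_signal_config` (α 0.3/Myr, σ² 0.006,
optima 0/0.3/0.6/1.0 — adjacent regimes ≥3 stationary SDs apart),
`weak_signal_config` (separations well under one SD), and
`bm_null_config` (pure drift). The defaults *are* the test conditions;
they were chosen once to mirror the study scale and are not tuned.

What the generator does not emulate: empirical tree shape (it is a
homogeneous birth–death sample, not the mammal phylogeny), correlated
measurement error across traits, trait–mass allometric coupling (masses
are independent of the latent shape values, so fossil-mass imputation
error on synthetic data is pessimistic relative to real bats), and
state-dependent diversification. Passing recovery tests therefore show
the estimators work when the model is true at the study's scale — not
that the empirical data satisfy the model.

## Replication sizes in the test suite

Simulation-based tests use the study scale (~230 tips) where the claim is
about that design (optimum rank order, bootstrap coverage with 100
pipelines × 100 replicates, six-family selection), and 80–400 tips
elsewhere, chosen as the smallest sizes at which the statistical claims
are meaningful. Monte-Carlo assertions use 3-standard-error bands or
binomial bands throughout.

## Known limitations

- Equal-rates Mk only; no hidden or asymmetric transition models.
- Diagonal multivariate `α`; no full selection matrix, no early-burst or
  rate-shift families, and no measurement-error variance term in the
  likelihood.
- Percentile bootstrap can undercover for strongly skewed estimators.
- Shift detection without a priori regimes (EM + lasso style) is a
  non-goal, as are tree inference, dating, and consensus-tree
  construction: the pipeline accepts a user-supplied dated tree or tree
  sample.
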