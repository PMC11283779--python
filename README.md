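# ouregimes

Multi-regime Ornstein–Uhlenbeck modelling of limb evolution on phylogenies.

`ouregimes` is built for comparative morphologists asking whether discrete
ecological regimes — here, mammalian locomotor modes (ground-dweller,
arborealist, glider, flyer) — shape the evolution of size-corrected skeletal
traits. The motivating question is the glider-to-flyer hypothesis for the
origin of bat flight: do glider limb optima sit between those of
arborealists and bats? The package covers the whole workflow: trait
ingestion and log-shape-ratio size correction, PCA, stochastic character
maps of regimes, maximum-likelihood fitting of Brownian-motion and
single-/multi-optimum OU models (univariate and multivariate), AICc model
comparison, parametric-bootstrap confidence intervals, phylogenetic
half-lives, fossil grafting on non-ultrametric trees, and a synthetic-data
generator so every stage is testable without external downloads.

## The model

Traits are size-corrected as log-shape ratios
`z = log10(trait_mm / mass_g^(1/3))` and evolve along a dated phylogeny
under an Ornstein–Uhlenbeck process

    dX = α (θ(t) − X) dt + σ dW,

where `α` (1/Myr) is the pull toward the optimum, `σ²` the diffusion rate,
and `θ(t)` the optimum of the selective regime painted on the branch at
time `t`. Regime histories are stochastic character maps sampled under an
equal-rates Mk model conditioned on the observed tip regimes. Model
families:

| family | optima | free parameters (univariate) |
|---|---|---|
| BM | none (drift) | σ², root state |
| OU1 | one shared θ | α, σ², θ |
| OUM_loc4 | one θ per locomotor mode | α, σ², 4 θ |
| OUM_loc3a/b/c | 3 θ (glider+flyer, arborealist+glider, or ground+arborealist merged) | α, σ², 3 θ |

Multivariate fits on retained principal components use a diagonal `α` (one
pull rate per PC), a full positive-definite `σ²` matrix, and per-regime
`θ` vectors. Models are ranked by small-sample Akaike weights
(`AICc = −2 logL + 2k + 2k(k+1)/(n−k−1)`), averaged over replicate trees
and character maps; supported models have mean ΔAICc < 2. The
responsiveness of a trait to its peaks is summarized by the phylogenetic
half-life `t½ = ln 2 / α`.

## Worked example

```python
import numpy as np
from ouregimes import make_dataset, fit_model, ModelSpec, akaike_weights
from ouregimes.synthetic_data import strong_signal_config

# a synthetic "study": 230-tip dated tree, 4 locomotor regimes, traits
# pulled toward well-separated optima (ground 0.0 < arboreal 0.3 <
# glider 0.6 < flyer 1.0), plus masses and specimen noise
ds = make_dataset(strong_signal_config(), seed=1)

from ouregimes.morphometrics import log_shape_ratios
ratios = log_shape_ratios(ds.trait_table, ds.masses)
y = ratios.ratios["hl"].to_dict()          # humerus-length shape ratios

fits = {}
for spec in [ModelSpec("BM"), ModelSpec("OU1"), ModelSpec("OUM", scheme="loc4")]:
    fits[spec.name] = fit_model(ds.tree, [ds.regime_map], y, spec)[0]
w = akaike_weights([f.aicc for f in fits.values()])
for (name, f), wi in zip(fits.items(), w):
    print(f"{name:8s} AICc {f.aicc:9.2f}  weight {wi:.3f}")
oum = fits["OUM_loc4"]
print("optima:", {r: round(t, 2) for r, t in sorted(oum.theta.items())})
print(f"alpha {oum.alpha:.3f}/Myr  half-life {oum.half_lives[0]:.2f} Myr")
```

Output:

```
BM       AICc    -70.23  weight 0.000
OU1      AICc    -73.40  weight 0.000
OUM_loc4 AICc   -406.66  weight 1.000
optima: {'arboreal': 0.26, 'flyer': 0.99, 'glider': 0.59, 'ground': -0.0}
alpha 0.318/Myr  half-life 2.18 Myr
```

The four-optimum model wins decisively, the fitted optima recover the
generating ground < arboreal < glider < flyer ordering, and the half-life
(~2.2 Myr on a 70-Myr tree) indicates traits that track their adaptive
peaks closely. `run_univariate` / `run_multivariate` /
`run_with_fossils` in `ouregimes.pipeline` wrap the same machinery with
simmap sampling, bootstrap CIs, optima-ordering summaries
(`ground<arb<glide<bat`), and a run manifest; the `ouregimes` CLI exposes
them as subcommands (`fit-uni`, `fit-multi`, `fit-fossil`, `simulate`).

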