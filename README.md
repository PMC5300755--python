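# osmophylo

Osmoregulatory trait derivation and phylogenetic comparative analysis for
intertidal crabs.

Semi-terrestrial crabs such as fiddler crabs live across osmotic niches
ranging from nearly fresh to hyper-saline water. Their physiology is
summarized by a small set of osmoregulatory traits measured in salinity
exposure experiments: the external osmolalities at which half the animals
die (lower and upper median lethal limits, LL50 and UL50, from probit
analysis), the isosmotic point (IC, where hemolymph osmolality equals the
medium), the hemolymph osmolalities predicted at the lethal limits
(Osm_LL50, Osm_UL50), and two bounded regulation-capability indices

    RC_Hyper = 1 − (IC − Osm_LL50) / (IC − LL50)
    RC_Hypo  = 1 − (Osm_UL50 − IC) / (UL50 − IC)

where values near 1 mean the hemolymph barely moves between isosmoticity
and the lethal limit (strong regulation) and values near 0 mean the
hemolymph tracks the medium (osmoconformity).

Because species share ancestry, cross-species questions about these traits
need phylogenetic methods. `osmophylo` provides the full two-layer
pipeline:

1. **Trait derivation** (`osmophylo.osmo_traits`) — probit LC50 fits on
   the linear osmolality scale (censoring-aware), cubic osmoregulatory
   response curves, isosmotic points, regulation indices, and
   per-population → species aggregation (mean ± SE).
2. **Comparative inference** (`osmophylo.phylo`, `osmophylo.comparative`,
   `osmophylo.regimes`) — Moran's I phylogenetic correlograms over
   patristic-distance classes with permutation tests; PGLS with
   simultaneous estimation of the Ornstein–Uhlenbeck attraction strength
   α; maximum-likelihood ancestral states under Brownian motion (via
   re-rooting); conditional-normal OU imputation of missing trait values;
   and multi-optimum OU (Hansen) models with stepwise-AIC detection of
   adaptive regimes, including per-trait partial-AIC decomposition and an
   optional convergent-regime collapse phase.
3. **Synthetic studies** (`osmophylo.synth`) — seed-deterministic
   generators for exposure experiments with known physiology, Yule trees,
   and BM/OU trait evolution with painted regime shifts, so every stage
   is testable against ground truth.

A species-level table of published osmoregulatory traits for 25 fiddler
crab species ships with the package (`osmophylo.load_reference_table()`).

## Worked example

Recompute a published species' regulation indices from its printed inputs:

```python
import osmophylo as op
from osmophylo.osmo_traits import regulation_indices

row = op.load_reference_table().loc["U_pugnax"]
rc_hyper, rc_hypo = regulation_indices(
    ic=row.isosmotic_point, ll50=row.ll50, osm_ll50=row.osm_ll50,
    ul50=row.ul50, osm_ul50=row.osm_ul50)
print(f"U. pugnax  RC_Hyper = {rc_hyper:.2f}  RC_Hypo = {rc_hypo:.2f}")
```

```
U. pugnax  RC_Hyper = 0.77  RC_Hypo = 0.60
```

i.e. this salt-marsh species buffers dilution much better than
concentration. Detect an adaptive-regime shift planted on a known branch:

```python
import numpy as np
from osmophylo.regimes import RegimePainting, surface_forward

tree = op.gen_tree(64, seed=9001)
paint = RegimePainting.single().add_origin(57)   # shift on a 22-tip clade
alpha = 2.0 / tree.tree_height()
y = op.sim_trait_ou(tree, paint, alpha, 2 * alpha,
                    theta=np.array([0.0, 5.0]), seed=42)
trace = surface_forward(tree, y.to_frame("tolerance"),
                        standardize=False, max_regimes=2)
for step in trace.steps:
    print(f"{step.description:<18s} n_regimes={step.fit.n_regimes}  AIC={step.aic:8.2f}")
print("estimated optima:", np.round(trace.final.traits["tolerance"].theta, 2))
```

```
OU1                n_regimes=1  AIC=  134.54
+regime@branch57   n_regimes=2  AIC=  105.08
estimated optima: [0.09 6.26]
```

The search starts from a single optimum, accepts the branch whose new
regime most improves the summed AIC — here exactly the branch the shift
was simulated on — and reports per-regime optima (estimates are noisy for
a single trait at 64 tips; the true optima were 0 and 5).

The whole analysis — trait derivation, correlograms, PGLS, ancestral
states, imputation, regime search — also runs as a CLI:

```bash
osmophylo simulate --seed 1 --n-species 24 --out study/
osmophylo run-all --seed 1 --out results_run/
```

Stage artifacts (CSV/JSON/Newick) are serialized between steps and a
manifest records the seed and config hash; two runs with the same seed
are byte-identical apart from the manifest timestamp.

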