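# traitdiv

Trait-based functional diversity and community-assembly inference for
site-by-species survey data, built for landscape-ecology questions of the
form: *does a managed habitat (say, cacao agroforestry) hold as much
functional diversity as nearby mature forest, and which assembly process —
niche filtering, limiting similarity, or neutral dynamics — structures its
communities?*

Taxonomic metrics such as species richness can stay flat while the
functional composition of a community erodes. `traitdiv` therefore works on
a mixed species-by-trait table (one continuous trait — body mass in grams —
plus binary foraging traits: food types, foraging strata, foraging methods,
activity period, mixed-flock participation) and compares habitats on
richness-corrected functional indices.

## What it computes

All pairwise species dissimilarities use the **Gower** coefficient with
equal trait weights,

    d_ij = (1/T) Σ_k δ_k(i,j),   δ_k = |x_ik − x_jk|          (binary)
                                 δ_k = |x_ik − x_jk| / range_k (continuous),

with the continuous range fixed at the regional-pool level. On top of d:

* **FD** (Petchey–Gaston functional diversity): total branch length of the
  community's UPGMA dendrogram (nothing above the root). Presence-based.
* **FEve** (Villéger functional evenness): regularity of abundance along the
  community's minimum spanning tree in trait space. Species coordinates come
  from principal coordinates of the Cailliez-corrected dissimilarity matrix,
  so no negative eigenvalues distort the geometry.
* **Rao quadratic entropy** Q = Σ_ij d_ij p_i p_j and the taxonomic
  **Simpson** index (Rao with d ≡ 1), both mapped to equivalent-community
  numbers with the Jost transform 1/(1 − x).
* **SES** (standardized effect size) per site, index and ecological subgroup
  (ALL, forest specialists, habitat generalists, frugivores/granivores,
  invertebrate eaters): observed index vs. 999 trait-shuffle null replicates
  that treat each landscape as the regional pool and conserve richness,
  occupancy and abundances exactly. SES < 0 ⇒ functional clustering (niche
  filtering); SES > 0 ⇒ overdispersion (limiting similarity).
* **Inference**: habitat contrasts by two-sample permutation t tests
  (exhaustive when feasible, 100 000 iterations otherwise), one-sample
  t tests of mean SES against 0 per habitat, Spearman decoupling checks
  between taxonomic and functional metrics, and Moran's I
  (inverse-distance weights) for spatial autocorrelation. With 15 SES
  comparisons per landscape, only p < 0.01 is flagged conclusive.

A synthetic-data module generates regional pools (25 binary traits +
lognormal body mass in [2, 2172] g) and two-landscape site layouts
(12 forest + 6 agroforestry, and 4 + 4) under *neutral*, *filtering*
(inclusion ∝ exp(−g²/2σ_f²) around a habitat optimum phenotype) or
*limiting-similarity* (greedy max–min distance) assembly, so the entire
pipeline is testable with known ground truth.

## Worked example

```python
import traitdiv as td

cfg = td.ScenarioConfig(
    n_species_pool=80, richness_mean=20, richness_sd=4,
    assembly={"forest": "neutral", "agroforestry": "filtering"},
    sigma_f=0.08, seed=42,
)
traits, community, manifest = td.generate_landscapes(cfg)

pcfg = td.PipelineConfig(subgroups=("ALL", "FGr"), n_null=199, seed=42)
result = td.run_pipeline(community, traits, pcfg)
asm = result.assembly
print(asm[(asm.landscape == "A") & (asm.subgroup == "ALL")]
      [["habitat", "metric", "mean_ses", "t", "p", "significant"]].round(3))
```

prints

```
     habitat  metric  mean_ses       t     p  significant
      forest   sesFD     0.507   2.172 0.053        False
agroforestry   sesFD    -3.990 -18.924 0.000         True
      forest sesFEve    -0.004  -0.018 0.986        False
agroforestry sesFEve     0.388   0.996 0.365        False
      forest  sesRao     0.749   2.612 0.024        False
agroforestry  sesRao    -3.028  -8.697 0.000         True
```

The filtering injected into agroforestry sites surfaces exactly where it
should: strongly negative mean SES for functional richness (sesFD) and
divergence (sesRao) in agroforestry (functional clustering, conclusive at
p < 0.01), neutral forests, and no evenness signal. The corresponding
habitat contrast (`result.contrasts`) gives mean sesFD 0.507 (forest) vs
−3.990 (agroforestry), permutation p = 0.0001.

The same analyses run from the shell:

```sh
traitdiv simulate --seed 42 --out-dir data/
traitdiv report --traits data/traits.csv --communities data/communities.csv \
    --schema data/schema.yaml --seed 42 --out-dir out/
```

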