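# ripenet

Integrated metabolite–transcript correlation network analysis for
recombinant inbred line (RIL) populations.

## The problem

Fruit quality traits — sweetness, color, aroma, acidity — are shaped by the
accumulation of sugars, carotenoids and volatile compounds during ripening.
A RIL population derived from two phenotypically diverse parents provides
stable genetic variation: phenotyping each line for a panel of metabolic
traits alongside RNA-seq expression profiles lets rank-correlation analysis
link metabolites to each other (co-accumulation networks, ethylene-dependent
vs. -independent process clusters) and to genes (candidate pathways, enzyme
function predictions via functional-category enrichment).

`ripenet` implements that analysis as a reusable, tested pipeline:

1. **Replicate-level trait statistics.** Per trait, a one-way random-effects
   ANOVA with line as the genetic factor. On a balanced design with `r`
   replicates, `σ̂²_E = MSW` and `σ̂²_G = (MSB − MSW)/r` (the REML solution for
   this design); unbalanced designs use the effective replicate number
   `r₀ = (N − Σnᵢ²/N)/(g − 1)`. Broad-sense heritability is the intraclass
   correlation `H² = σ²_G / (σ²_G + σ²_E)`. Severely skewed traits
   (sample skewness g₁ > 1) are square-root transformed first. Parental-range
   fractions report how the population distributes around the founders.
2. **Expression handling.** RPKM (`count·10⁹ / (length_bp · library_size)`),
   a lower **floor** (default 3 RPKM) clamped onto the matrix before ranking
   so unexpressed genes contribute no spurious rank structure, and a
   median-based low-expression filter.
3. **Spearman correlation engine.** ρ as the Pearson correlation of average
   ranks; two-sided p from `t = ρ·√((n−2)/(1−ρ²))` on n−2 df (exact
   permutation enumeration available for small tie-free samples).
   Missing data are handled pairwise-complete; undefined pairs are flagged,
   never zeroed. At n = 96 lines, |ρ| ≥ 0.3 corresponds to p ≤ 0.003.
4. **Signed network.** One edge per trait pair with |ρ| ≥ 0.3, sign-labelled,
   exported as Cytoscape SIF plus node/edge attribute tables (and a
   positive-edges-only layout variant).
5. **Two-way hierarchical clustering.** Metabolites clustered on the rows of
   their ρ matrix and cut into k = 3 groups (R `cutree` semantics); genes
   clustered on their ρ profiles over representative traits and cut into
   k = 4 groups, labelled by deterministic association-sign signatures.
6. **Hierarchical-annotation enrichment.** MapMan/Mercator-style dotted-bin
   trees with ancestor propagation; exact cumulative hypergeometric
   P(X ≥ k) per (gene set, bin) at **every** hierarchy level;
   Benjamini–Hochberg FDR (10%) over the pooled test family; two-tier
   p-value colouring; top-5 categories per representative metabolite; and
   bin → EC projection with group-exclusive EC lists for pathway mapping.
7. **Synthetic-data generator.** A study-shaped simulator (96 lines,
   77 traits in three planted clusters, 3 or 5 replicate fruits per trait,
   27,427 genes, roughly half annotated) with planted trait clusters, planted
   signed gene–trait associations of calibrated Spearman strength, and
   planted enriched bins — so every stage can be validated against ground
   truth.

## Worked example

```python
import pandas as pd
from ripenet import (
    SimulationSpec, GeneGroupSpec, simulate_ril_traits, simulate_annotation,
    trait_trait_matrix, build_network, edge_counts, intra_cluster_fraction,
    hierarchical_cluster, cut_tree, cluster_agreement, ClusterAssignment,
    enrich_all, bh_fdr, top_k_categories,
    anova_variance_components, broad_sense_heritability,
)

spec = SimulationSpec(
    n_lines=96, n_traits=12, n_genes=2000,
    gene_groups=(GeneGroupSpec("G1", 100, "I", +1),
                 GeneGroupSpec("G2", 100, "II", +1),
                 GeneGroupSpec("G3", 100, "III", -1)),
    annotation_depth=3, n_top_bins=6, bin_branching=3, rng_seed=1,
)
replicates, truth = simulate_ril_traits(spec)

vc = anova_variance_components(replicates, "T001")
h2 = broad_sense_heritability(vc)
print(f"T001: sigma2_G={vc.sigma2_G:.3f} sigma2_E={vc.sigma2_E:.3f} H2={h2.H2:.3f}")

tt = trait_trait_matrix(truth.line_means)
net = build_network(tt, threshold=0.3)
clusters = cut_tree(hierarchical_cluster(tt.rho), k=3)
pos, neg = edge_counts(net)
print(f"network: {pos} positive / {neg} negative edges; "
      f"intra-cluster positive fraction = "
      f"{intra_cluster_fraction(net, clusters.as_series(), '+'):.2f}")

planted = ClusterAssignment(ids=list(truth.trait_clusters.index),
                            labels=pd.factorize(truth.trait_clusters)[0] + 1, k=3)
print(f"ARI vs planted clusters = {cluster_agreement(clusters, planted):.2f}")

hierarchy, bin2ec, bin_truth = simulate_annotation(spec)
background = hierarchy.annotated_genes
groups = spec.gene_group_of()
queries = {g: set(groups.index[groups == g]) & background for g in ("G1", "G2", "G3")}
results = bh_fdr(enrich_all(queries, hierarchy, background), q=0.10)
print(top_k_categories(results, k=1)[["query", "bincode", "k", "K", "p"]]
      .to_string(index=False))
```

prints

```
T001: sigma2_G=1.028 sigma2_E=0.885 H2=0.537
network: 18 positive / 0 negative edges; intra-cluster positive fraction = 1.00
ARI vs planted clusters = 1.00
query bincode  k   K             p
   G1   1.1.1 94 112 2.746948e-111
   G2   2.1.1 89 108 1.409025e-100
   G3   3.1.1 90 110 9.793144e-102
```

The simulated trait panel decomposes into genetic and residual variance near
the planted σ²_G = σ²_E = 1 (H² ≈ 0.5); all significant trait–trait edges
fall within the three planted clusters, which the k = 3 tree cut recovers
exactly (adjusted Rand index 1.0); and each planted annotation bin (`1.1.1`,
`2.1.1`, `3.1.1`) is the single most enriched category of its gene group,
with 89–94 of each group's 100 genes inside it.

## Command line

```
ripenet simulate -o fixtures --seed 1          # write a fixture bundle
ripenet run -c config.yaml                     # full pipeline
ripenet stats | correlate | network | cluster | enrich   # single stages
ripenet validate -c config.yaml                # config checks
```

`ripenet run` with no config runs the default synthetic study end to end and
writes every intermediate table, the SIF network, enrichment results, EC
lists and a `manifest.json` (config echo, input checksums, seed) under the
output directory.

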