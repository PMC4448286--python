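# Methods

This note documents the statistical models, the simulator, the numerical
choices and the known limitations of `ripenet`.

## Trait model and heritability

Each line of the RIL population is phenotyped in replicate fruits per trait.
The one-way random-effects model is

    y_ij = mu + g_i + e_ij,   g_i ~ N(0, sigma2_G),  e_ij ~ N(0, sigma2_E),

with line `i` as the genetic factor. The estimators are method-of-moments on
the ANOVA mean squares: `sigma2_E = MSW`, `sigma2_G = (MSB − MSW)/r0`, where
`r0` is the replicate count on balanced designs and the effective replicate
number `(N − Σ n_i²/N)/(g − 1)` otherwise. On balanced one-way designs these
coincide with REML, which is why no iterative mixed-model machinery is
carried. A negative `sigma2_G` is clamped to 0 (the standard convention; it
keeps `H²` in [0, 1]). The genetic-effect test is `F = MSB/MSW` on
`(g−1, N−g)` df.

Broad-sense heritability is reported as the intraclass correlation of a
single observation, `H² = sigma2_G/(sigma2_G + sigma2_E)`. The line-mean
form `sigma2_G/(sigma2_G + sigma2_E/r0)` is available behind
`line_mean_basis=True`; the single-observation form is the default because
"intraclass correlation" conventionally denotes it.

Severely skewed traits are square-root transformed before the ANOVA.
"Severe" is quantified as biased sample skewness g1 > 1 (a conventional
rule of thumb; configurable), with the decision logged per trait in the
summary table. Vectors containing negative values are shifted to zero
before rooting. Skewness of a constant vector is defined as 0. Rank
correlations downstream are unaffected by any monotone transform, so the
transform matters only for the variance decomposition.

Parental-range fractions use the closed interval `[min(parents),
max(parents)]`; endpoints count as "within", and a degenerate point range
counts exact matches only. The three fractions sum to 1 over non-missing
lines.

## Expression floor semantics

The RPKM floor (default 3) admits two readings: clamp values below the floor,
or drop genes entirely. The default **clamps**: in a rank-correlation
pipeline the floor's evident purpose is to stop tiny fluctuations among
unexpressed genes from generating rank structure, and clamping does exactly
that while keeping partially expressed genes. Genes left constant by the
clamp have no defined rank correlation and are flagged undefined (NaN), never
silently zero. The alternative — dropping genes whose median RPKM across
lines falls below a threshold — exists as `filter_low_expression` /
`floor_mode: median_filter`, mirroring the practice of not computing
correlations for genes detected at very low levels.

## Spearman engine

rho is the Pearson correlation of average-rank vectors (average ranks for
ties). The default two-sided p uses `t = rho·sqrt((n−2)/(1−rho²))` on n−2
df, with p = 0 by convention at rho = ±1. For tie-free samples of n ≤ 9 an
exact permutation p (full enumeration of the n! rho null distribution,
convention P(|rho_perm| ≥ |rho_obs|)) is available via `p_method="exact"` or
`"auto"`. At the target population size (n = 96) the t approximation is
accurate and `|rho| ≥ 0.3` pairs with p ≤ 0.003 (computed: 0.00298).

Measured agreement between the t approximation and exact enumeration at
small n (unit-tested): the worst absolute gap at n = 7 is 0.027 over all
inputs and 0.012 in the decision-relevant tail (p ≤ 0.05); at n ≤ 6 the
approximation degrades further (up to 0.33 at n = 3). Small-sample p-values
should therefore use the exact method; the pipeline itself never operates
at such n.

Missing data are handled pairwise-complete with per-pair usable n; pairs
with n < 3 or a constant member are undefined. Thresholding is inclusive
(|rho| ≥ threshold) by default, with a strict switch; the choice is recorded
in run metadata. Matrices are computed vectorised (rank, standardise, one
matrix product) when complete, falling back to per-pair computation in the
presence of missing values.

## Clustering

Default dissimilarity between profile rows is 1 − Spearman rho with average
linkage (the distance matches the correlation heatmaps the analysis
displays; average linkage is the common default of R-era hclust workflows).
Euclidean distance and complete/Ward linkage are configurable. Profiles
shorter than 3 features degrade to Euclidean distance, where rank
correlation is degenerate. Tree cuts use merge-count semantics (R `cutree`):
cutting after n − k merges yields exactly k clusters, and the k-partition
always refines the (k−1)-partition. Labels are renumbered by first
appearance, making assignments stable for identical input.

Metabolites are clustered on the rows of the trait × trait rho matrix
(k = 3); genes on their rho vectors over the representative traits (k = 4),
after filtering to genes with |rho| ≥ 0.3 against at least one
representative. Gene groups get a deterministic signature — the sign
pattern of their mean association per trait cluster (e.g. `I+/II-/III-`) —
as a post-hoc label, never an input. Representative traits are a config
input (they were chosen by hand in the motivating analysis); when absent,
up to 17 evenly spaced trait ids are used.

## Network

One edge per unordered trait pair passing the magnitude threshold, signed by
rho, canonically ordered (a < b, lexicographic). Export is SIF with
interaction tokens `pos`/`neg` (the smallest dialect Cytoscape ingests that
preserves sign), plus node/edge attribute tables and a positive-only SIF
for layout. Drawing/layout is out of scope: the artifact exports, never
renders. The intra-cluster fraction of a sign is the share of that sign's
edges whose endpoints share a cluster label; 0/0 is NaN.

## Enrichment

Bins are dotted-decimal codes; level = dot count + 1; a gene assigned to a
leaf belongs to every ancestor, so a parent's gene set is a superset of its
children's union. Each (query set, bin) test is the exact upper cumulative
hypergeometric P(X ≥ k) with N the background size, K the bin's background
members, n the query size (computed via `scipy.stats.hypergeom.sf`, exact
log-gamma accumulation, no normal approximation; validated against full
subset enumeration for N ≤ 12). Bins empty in the background are skipped. A
gene counts once per category regardless of how many of its leaves sit
beneath it.

The background defaults to annotated genes intersected with the expressed
set (unannotated or unexpressed genes can never enter a query, so counting
them would inflate N); a pure-annotated background is configurable. The BH
FDR (default 10%) pools all query sets, directions and levels of a run into
one family by default — matching a multiple-test correction described over
all groups and all levels — with per-query pooling configurable. Per-
metabolite positively and negatively correlated gene sets are separate
queries. The two-tier display colouring (0.01 < p ≤ 0.05, p ≤ 0.01) is
carried alongside the FDR flag.

Top-k selection (default 5 per representative metabolite) takes
FDR-significant positive-direction rows ordered by (smaller p, deeper
level, lexicographic bincode); deeper bins win ties because the most
specific category is the most informative. The optional sibling-collapse
step — among same-parent categories with identical (query, tier) profiles
keep the lowest bincode — is a display-reduction heuristic and is off by
default; parent/child pairs never collapse.

EC projection takes, per gene group, the union of ECs mapped to any
category its members belong to (leaf assignments plus ancestors); the
exclusive subset keeps ECs present in exactly one group, suitable for
pathway-map highlighting.

## The simulator

The generator's defaults encode the study design the pipeline targets: 96
lines; 77 traits split into three planted clusters; 3 replicate fruits for
the volatile-like majority of traits (64/77) and 5 for the rest; 27,427
genes with 13,579/27,427 of background genes annotated; unit genetic and
residual variances (true intraclass correlation 0.5).

Structure is planted through Gaussian latent factors, one per trait
cluster. A trait in cluster c has genetic value
`sqrt(sigma2_G)·(w·f_c + sqrt(1−w²)·eps)`; replicates add N(0, sigma2_E)
noise. A planted gene's latent score is `sign·(w·f_c + sqrt(1−w²)·eps')`,
mapped through `exp()` to a non-negative abundance — Spearman statistics are
invariant to the monotone map, so planted rank correlations are analytically
controllable. The loading solves the Gaussian-copula Spearman–Pearson
relation `rho_S = (6/pi)·asin(r/2)`: `w = sqrt(2·sin(pi·a/6))`, so that the
product of two loadings is the Pearson correlation whose Spearman image is
the requested strength `a` (at a = 0.6 the naive `w = sqrt(a)` would
deliver rho_S ≈ 0.58; the calibrated loading delivers 0.6). Background
genes are independent noise; a configurable fraction (default 0.25) sits
below the RPKM floor so clamping is actually exercised. Gene lengths
(500–5000 bp) and library sizes (8–12 M reads) are emitted for RPKM
round-trips.

Annotation is a complete tree (default 8 top bins, branching 3, depth 4).
Planted-group genes are always annotated and land in their group's planted
leaf with probability `excess_rate` (default 0.9), otherwise uniformly;
background genes are annotated at the annotated fraction and spread
uniformly; 10% of annotated genes get a second leaf to exercise
multi-assignment. Each leaf maps to a unique synthetic EC at rate 0.7.
Parental values are drawn from the same genetic model as two extra founder
lines (a synthetic stand-in; real parental values can be supplied as a
file). Missing replicate values are injected at a configurable rate
(default 0 — the real data's missingness pattern is unknown, so none is a
choice, not an inference).

What the simulator does **not** emulate: counts-level sequencing noise
(values are lognormal abundances, not negative-binomial counts), genotypes
or markers, trait-specific measurement error structure, batch effects, and
correlated annotation among biologically related background genes. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under a clean generative model, not robustness to every artefact
of real data.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run the trait side at full
study scale (96 lines × 77 traits) and scale the gene panel down (2,000–
3,000 genes with three planted groups of 100–120) — the gene dimension
enters every statistic linearly, so the reduced panel exercises identical
code paths; a full 27,427-gene run completes via `ripenet run` in a couple
of minutes. Heritability recovery uses 500 simulated populations (96 × 5,
sigma2_G = sigma2_E = 1); cluster recovery averages 20 seeds at association
strength 0.8; the null-enrichment FDR check uses 200 independent null runs.

## Numerical conventions and degenerate inputs

- Undefined correlations (n < 3, constant vectors) are NaN with a reported
  usable n, never 0; they are excluded from gene sets, networks, and
  clustering distances (constant gene profiles raise an isolated-item
  error).
- rho is clipped to [−1, 1] against floating-point drift; p at |rho| = 1 is
  0 by convention.
- Hypergeometric p is clamped into (0, 1].
- All-equal ANOVA input yields sigma2_G = sigma2_E = 0, H² = 0, p = 1;
  zero within-line variance with distinct lines yields F = inf, p = 0.
- Fixture files and pipeline outputs are byte-identical for identical spec,
  config and seed; the run manifest carries no wall-clock values for that
  reason.

## Known limitations

- The enrichment tests at different levels of one branch are strongly
  dependent (nested gene sets); pooled BH is valid under positive regression
  dependence but conservative, and discrete p-values make it more so.
- The t-approximation p is inaccurate below n ≈ 10 (see the measured gaps
  above); exact enumeration is provided but limited to tie-free n ≤ 9.
- `gene_groups_from_correlation` clusters rho profiles, not expression
  itself; genes associated with no representative trait are invisible to it.
- The unbalanced-design variance decomposition uses the effective replicate
  number, which is approximate relative to full REML when imbalance is
  extreme.
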