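"""Synthetic RIL-population fixtures with planted, recoverable structure.

The generator emulates the study design this pipeline targets: a population
of recombinant inbred lines (default 96) phenotyped for a panel of metabolic
traits (default 77; volatile-like traits measured in 3 replicate fruits,
others in 5) alongside a genes x lines RPKM expression matrix and a
MapMan-style hierarchical functional annotation.  Everything downstream has
a ground truth: traits belong to planted clusters, planted gene groups track
a trait cluster with a chosen sign and rank-correlation strength, and chosen
annotation bins are enriched for a gene group's members.

Model.  Each trait cluster c has a latent Gaussian factor f_c over lines.
A trait in cluster c has genetic value

    g = sqrt(sigma2_G) * (w * f_c + sqrt(1 - w^2) * eps),

replicate observations add N(0, sigma2_E) noise, and a planted gene's latent
score is sign * (w * f_c + sqrt(1 - w^2) * eps') pushed through exp() to give
a non-negative abundance (Spearman statistics are invariant to the monotone
map, so the planted rank correlations survive).  The loading w is calibrated
so the *Spearman* correlation between two planted variables is the requested
association strength a: for bivariate Gaussians rho_S = (6/pi) asin(r/2), so
w = sqrt(2 sin(pi a / 6)) makes the product of two loadings equal the Pearson
r whose Spearman image is a.

All randomness flows from ``rng_seed``; identical specs produce byte-identical
fixture files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .enrichment import AnnotationHierarchy, bin_level, bin_sort_key
from .errors import AlignmentError, InvalidSpecError
from .expression import ExpressionMatrix

TRAIT_CLUSTERS = ("I", "II", "III")


@dataclass(frozen=True)
class GeneGroupSpec:
    """A planted gene group tied to one trait cluster with a fixed sign."""

    name: str
    size: int
    target_cluster: str
    sign: int = 1


def _default_gene_groups() -> tuple[GeneGroupSpec, ...]:
    return (
        GeneGroupSpec("G1", 150, "I", +1),
        GeneGroupSpec("G2", 150, "II", +1),
        GeneGroupSpec("G3", 150, "III", -1),
    )


def _default_planted_bins(
    groups: Sequence[GeneGroupSpec], depth: int
) -> tuple[tuple[str, str], ...]:
    return tuple(
        (grp.name, ".".join([str(i + 1)] + ["1"] * (depth - 1)))
        for i, grp in enumerate(groups)
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Study-design parameters for the synthetic population.

    Defaults mirror the target study: 96 lines, 77 traits in three planted
    clusters, 3 replicates for the volatile-like majority of traits and 5
    for the rest, 27,427 genes of which roughly half carry a functional
    annotation, and unit genetic/residual variances (heritability 0.5).
    """

    n_lines: int = 96
    n_traits: int = 77
    trait_cluster_labels: Optional[tuple[str, ...]] = None
    n_replicates: Optional[int | tuple[int, ...]] = None
    sigma2_G: float | tuple[float, ...] = 1.0
    sigma2_E: float | tuple[float, ...] = 1.0
    n_genes: int = 27427
    gene_groups: tuple[GeneGroupSpec, ...] = field(
        default_factory=_default_gene_groups
    )
    association_strength: float = 0.8
    annotation_depth: int = 4
    n_top_bins: int = 8
    bin_branching: int = 3
    annotated_fraction: float = 13579 / 27427
    excess_rate: float = 0.9
    multi_assign_rate: float = 0.1
    ec_rate: float = 0.7
    low_expression_fraction: float = 0.25
    log_sigma: float = 0.8
    missing_rate: float = 0.0
    planted_enriched_bins: Optional[tuple[tuple[str, str], ...]] = None
    rng_seed: int = 0

    # -- derived, deterministic layout ------------------------------------
    @property
    def line_ids(self) -> list[str]:
        return [f"L{i:03d}" for i in range(1, self.n_lines + 1)]

    @property
    def trait_ids(self) -> list[str]:
        return [f"T{i:03d}" for i in range(1, self.n_traits + 1)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    def trait_clusters(self) -> pd.Series:
        if self.trait_cluster_labels is not None:
            labels = list(self.trait_cluster_labels)
        else:
            n_clusters = min(len(TRAIT_CLUSTERS), self.n_traits)
            labels = [
                TRAIT_CLUSTERS[(i * n_clusters) // self.n_traits]
                for i in range(self.n_traits)
            ]
        return pd.Series(labels, index=self.trait_ids, name="cluster")

    def replicate_counts(self) -> pd.Series:
        """Per-trait replicate counts: 3 for the volatile-like fraction
        (64/77 of traits), 5 for the remainder, unless overridden."""
        if self.n_replicates is None:
            n_volatile = round(self.n_traits * 64 / 77)
            counts = [3 if i < n_volatile else 5 for i in range(self.n_traits)]
        elif isinstance(self.n_replicates, int):
            counts = [self.n_replicates] * self.n_traits
        else:
            counts = list(self.n_replicates)
        return pd.Series(counts, index=self.trait_ids, name="n_replicates")

    def gene_group_of(self) -> pd.Series:
        """Planted group per gene ('' for background genes)."""
        labels = [""] * self.n_genes
        cursor = 0
        for grp in self.gene_groups:
            for _ in range(grp.size):
                labels[cursor] = grp.name
                cursor += 1
        return pd.Series(labels, index=self.gene_ids, name="group")

    def per_trait(self, value: float | tuple[float, ...]) -> np.ndarray:
        if isinstance(value, (int, float)):
            return np.full(self.n_traits, float(value))
        return np.asarray(value, dtype=float)

    def planted_bins(self) -> tuple[tuple[str, str], ...]:
        if self.planted_enriched_bins is not None:
            return self.planted_enriched_bins
        return _default_planted_bins(self.gene_groups, self.annotation_depth)

    def all_bincodes(self) -> list[str]:
        codes: list[str] = []

        def _extend(prefix: str, depth: int) -> None:
            codes.append(prefix)
            if depth < self.annotation_depth:
                for child in range(1, self.bin_branching + 1):
                    _extend(f"{prefix}.{child}", depth + 1)

        for top in range(1, self.n_top_bins + 1):
            _extend(str(top), 1)
        return sorted(codes, key=bin_sort_key)

    def leaf_bincodes(self) -> list[str]:
        return [c for c in self.all_bincodes() if bin_level(c) == self.annotation_depth]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.n_lines < 4:
            raise InvalidSpecError("n_lines must be >= 4")
        if self.n_traits < 1:
            raise InvalidSpecError("n_traits must be >= 1")
        if self.n_genes < 0:
            raise InvalidSpecError("n_genes must be >= 0")
        counts = self.replicate_counts()
        if len(counts) != self.n_traits or (counts < 1).any():
            raise InvalidSpecError("replicate counts must be >= 1 per trait")
        for name, val in (("sigma2_G", self.sigma2_G), ("sigma2_E", self.sigma2_E)):
            arr = self.per_trait(val)
            if len(arr) != self.n_traits or (arr < 0).any():
                raise InvalidSpecError(f"{name} must be >= 0 per trait")
        if not 0.0 <= self.association_strength <= 1.0:
            raise InvalidSpecError("association_strength must be in [0, 1]")
        if self.annotation_depth < 2:
            raise InvalidSpecError("annotation_depth must be >= 2")
        clusters = set(self.trait_clusters())
        if sum(g.size for g in self.gene_groups) > self.n_genes:
            raise InvalidSpecError("gene groups exceed n_genes")
        for grp in self.gene_groups:
            if grp.target_cluster not in clusters:
                raise InvalidSpecError(
                    f"group {grp.name} targets unknown trait cluster {grp.target_cluster}"
                )
            if grp.sign not in (-1, 1):
                raise InvalidSpecError("gene group sign must be +1 or -1")
        valid_codes = set(self.all_bincodes())
        group_names = {g.name for g in self.gene_groups}
        for group, code in self.planted_bins():
            if group not in group_names:
                raise InvalidSpecError(f"planted bin for unknown group {group}")
            if bin_level(code) > self.annotation_depth or code not in valid_codes:
                raise InvalidSpecError(
                    f"planted bin {code} absent from the generated hierarchy"
                )
        for rate in (
            self.annotated_fraction,
            self.excess_rate,
            self.multi_assign_rate,
            self.ec_rate,
            self.low_expression_fraction,
            self.missing_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise InvalidSpecError("rates must be in [0, 1]")


def spearman_loading(strength: float) -> float:
    """Latent loading w with w^2 = 2 sin(pi a / 6): the Pearson correlation
    whose Gaussian-copula Spearman correlation equals ``a``."""
    return math.sqrt(2.0 * math.sin(math.pi * strength / 6.0))


@dataclass
class TraitSimulationTruth:
    """Planted quantities emitted alongside the trait fixtures."""

    factors: pd.DataFrame  # lines x clusters latent factors
    genetic_values: pd.DataFrame  # lines x traits
    trait_clusters: pd.Series
    line_means: pd.DataFrame  # realized replicate means, lines x traits


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.rng_seed, stream])


def simulate_ril_traits(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, TraitSimulationTruth]:
    """Replicate-level trait table plus the planted genetic truth.

    Returns a long-format table (line, trait, replicate, value) and a
    :class:`TraitSimulationTruth` carrying the latent cluster factors, the
    per-line genetic values and the realized line means.
    """
    spec.validate()
    rng = _rng(spec, 1)
    clusters = spec.trait_clusters()
    cluster_names = list(dict.fromkeys(clusters))
    factors = pd.DataFrame(
        rng.standard_normal((spec.n_lines, len(cluster_names))),
        index=spec.line_ids,
        columns=cluster_names,
    )
    w = spearman_loading(spec.association_strength)
    s2g = spec.per_trait(spec.sigma2_G)
    s2e = spec.per_trait(spec.sigma2_E)
    eps = rng.standard_normal((spec.n_lines, spec.n_traits))
    z = w * factors[clusters].to_numpy() + math.sqrt(1.0 - w * w) * eps
    genetic = np.sqrt(s2g)[None, :] * z
    genetic_df = pd.DataFrame(genetic, index=spec.line_ids, columns=spec.trait_ids)

    counts = spec.replicate_counts()
    records = []
    for t_idx, trait in enumerate(spec.trait_ids):
        r = int(counts[trait])
        noise = math.sqrt(s2e[t_idx]) * rng.standard_normal((spec.n_lines, r))
        values = genetic[:, t_idx : t_idx + 1] + noise
        if spec.missing_rate > 0:
            mask = rng.random((spec.n_lines, r)) < spec.missing_rate
            values = np.where(mask, np.nan, values)
        for l_idx, line in enumerate(spec.line_ids):
            for rep in range(1, r + 1):
                records.append((line, trait, rep, values[l_idx, rep - 1]))
    table = pd.DataFrame(records, columns=_io.REPLICATE_COLUMNS)
    means = table.pivot_table(
        index="line", columns="trait", values="value", aggfunc="mean"
    ).reindex(index=spec.line_ids, columns=spec.trait_ids)
    truth = TraitSimulationTruth(
        factors=factors,
        genetic_values=genetic_df,
        trait_clusters=clusters,
        line_means=means,
    )
    return table, truth


def simulate_parents(spec: SimulationSpec) -> pd.DataFrame:
    """Synthetic parental trait values drawn from the same genetic model.

    The two founders get independent latent draws; returned as a per-trait
    table with columns parent_a / parent_b (a stand-in for the real printed
    parental values, which can be supplied instead).
    """
    spec.validate()
    rng = _rng(spec, 4)
    clusters = spec.trait_clusters()
    cluster_names = list(dict.fromkeys(clusters))
    w = spearman_loading(spec.association_strength)
    s2g = spec.per_trait(spec.sigma2_G)
    out = {}
    for parent in ("parent_a", "parent_b"):
        f = pd.Series(
            rng.standard_normal(len(cluster_names)), index=cluster_names
        )
        eps = rng.standard_normal(spec.n_traits)
        z = w * f[clusters].to_numpy() + math.sqrt(1.0 - w * w) * eps
        out[parent] = np.sqrt(s2g) * z
    parents = pd.DataFrame(out, index=spec.trait_ids)
    parents.insert(0, "trait", parents.index)
    return parents.reset_index(drop=True)


def simulate_expression(
    spec: SimulationSpec, truth: TraitSimulationTruth
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Genes x lines RPKM-like matrix with planted gene-trait associations.

    Planted genes follow their target cluster's latent factor (shared with
    the traits in ``truth``) with the calibrated loading and planted sign;
    background genes are independent noise, a configurable fraction of them
    effectively unexpressed (values concentrated below the usual floor of 3).
    Latent scores map through exp() so values are non-negative while rank
    correlations are preserved.  Gene lengths and per-line library sizes are
    emitted so RPKM arithmetic can be round-tripped.
    """
    spec.validate()
    if list(truth.factors.index) != spec.line_ids:
        raise AlignmentError("truth line ids do not match the spec")
    rng = _rng(spec, 2)
    w = spearman_loading(spec.association_strength)
    groups = spec.gene_group_of()
    by_name = {g.name: g for g in spec.gene_groups}
    z = rng.standard_normal((spec.n_genes, spec.n_lines))
    factors = truth.factors
    planted_rows = np.flatnonzero(groups.to_numpy() != "")
    for row in planted_rows:
        grp = by_name[groups.iloc[row]]
        f = factors[grp.target_cluster].to_numpy()
        z[row] = grp.sign * (w * f + math.sqrt(1.0 - w * w) * z[row])
    # baseline log-abundance: planted genes well expressed; a fraction of
    # background genes sit below the floor to exercise clamping
    mu = rng.normal(math.log(50.0), 1.0, size=spec.n_genes)
    low = rng.random(spec.n_genes) < spec.low_expression_fraction
    mu[low] = math.log(0.3)
    mu[planted_rows] = math.log(100.0)
    values = np.exp(mu[:, None] + spec.log_sigma * z)
    expr = pd.DataFrame(values, index=spec.gene_ids, columns=spec.line_ids)
    gene_lengths = pd.Series(
        rng.integers(500, 5001, size=spec.n_genes), index=spec.gene_ids, name="length_bp"
    )
    library_sizes = pd.Series(
        rng.integers(8_000_000, 12_000_001, size=spec.n_lines),
        index=spec.line_ids,
        name="mapped_reads",
    )
    gene_truth = pd.DataFrame(
        {
            "gene": spec.gene_ids,
            "group": groups.to_numpy(),
            "target_cluster": [
                by_name[g].target_cluster if g else "" for g in groups
            ],
            "sign": [by_name[g].sign if g else 0 for g in groups],
        }
    )
    return (
        ExpressionMatrix(expr, gene_lengths=gene_lengths, library_sizes=library_sizes),
        gene_truth,
    )


def simulate_annotation(
    spec: SimulationSpec,
) -> tuple[AnnotationHierarchy, pd.DataFrame, pd.DataFrame]:
    """Hierarchical bin annotation with planted enriched bins + bin2ec table.

    Every planted-group gene is annotated; members land in their group's
    planted leaf with probability ``excess_rate`` (uniform leaf otherwise).
    Background genes are annotated at ``annotated_fraction`` and spread
    uniformly over leaves; a small fraction receives a second leaf to
    exercise multi-assignment.  Each leaf maps to a unique synthetic EC
    number at rate ``ec_rate``.
    """
    spec.validate()
    rng = _rng(spec, 3)
    codes = spec.all_bincodes()
    leaves = spec.leaf_bincodes()
    bin_names = {code: f"category {code}" for code in codes}
    planted_leaf = dict()
    for group, code in spec.planted_bins():
        planted_leaf[group] = code
    groups = spec.gene_group_of()
    assignments: dict[str, set[str]] = {}
    leaf_arr = np.array(leaves)
    for gene in spec.gene_ids:
        group = groups[gene]
        if group:
            target = planted_leaf.get(group)
            if target is not None and rng.random() < spec.excess_rate:
                leaf = target
            else:
                leaf = leaf_arr[rng.integers(len(leaf_arr))]
            assignments[gene] = {leaf}
        else:
            if rng.random() < spec.annotated_fraction:
                assignments[gene] = {leaf_arr[rng.integers(len(leaf_arr))]}
        if gene in assignments and rng.random() < spec.multi_assign_rate:
            assignments[gene].add(leaf_arr[rng.integers(len(leaf_arr))])
    hierarchy = AnnotationHierarchy(bin_names=bin_names, assignments=assignments)
    ec_records = []
    for i, leaf in enumerate(leaves, start=1):
        if rng.random() < spec.ec_rate:
            ec_records.append((leaf, f"1.1.1.{i}"))
    bin2ec = pd.DataFrame(ec_records, columns=["BINCODE", "EC"])
    bin_truth = pd.DataFrame(
        [(g, c) for g, c in spec.planted_bins()], columns=["group", "bincode"]
    )
    return hierarchy, bin2ec, bin_truth


def write_mercator_file(hierarchy: AnnotationHierarchy, path: str | Path) -> None:
    """Mercator-dialect annotation: bin rows then (gene, bin) assignment rows."""
    rows = []
    for code in hierarchy.bincodes:
        rows.append((code, hierarchy.bin_names[code], "", ""))
    for gene in sorted(hierarchy.assignments):
        for code in sorted(hierarchy.assignments[gene], key=bin_sort_key):
            rows.append((code, hierarchy.bin_names[code], gene, ""))
    pd.DataFrame(rows, columns=["BINCODE", "NAME", "IDENTIFIER", "DESCRIPTION"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_fixtures(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full fixture bundle; deterministic per spec.

    Files: trait replicates, line means, parental values, expression matrix,
    gene lengths, library sizes, Mercator annotation, bin2ec, and the planted
    truth tables (trait clusters, gene groups, planted bins).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_ril_traits(spec)
    expr, gene_truth = simulate_expression(spec, truth)
    hierarchy, bin2ec, bin_truth = simulate_annotation(spec)
    parents = simulate_parents(spec)
    paths = {
        "trait_replicates": outdir / "trait_replicates.tsv",
        "line_means": outdir / "line_means.tsv",
        "parental_values": outdir / "parental_values.tsv",
        "expression": outdir / "expression.tsv",
        "gene_lengths": outdir / "gene_lengths.tsv",
        "library_sizes": outdir / "library_sizes.tsv",
        "annotation": outdir / "annotation_mercator.tsv",
        "bin2ec": outdir / "bin2ec.tsv",
        "truth_trait_clusters": outdir / "truth_trait_clusters.tsv",
        "truth_gene_groups": outdir / "truth_gene_groups.tsv",
        "truth_planted_bins": outdir / "truth_planted_bins.tsv",
    }
    _io.write_replicate_table(table, paths["trait_replicates"])
    _io.write_matrix(truth.line_means, paths["line_means"], index_label="line")
    _io.write_parental_values(parents, paths["parental_values"])
    _io.write_matrix(expr.values, paths["expression"], index_label="gene")
    expr.gene_lengths.to_csv(
        paths["gene_lengths"], sep="\t", index_label="gene", lineterminator="\n"
    )
    expr.library_sizes.to_csv(
        paths["library_sizes"], sep="\t", index_label="line", lineterminator="\n"
    )
    write_mercator_file(hierarchy, paths["annotation"])
    bin2ec.to_csv(paths["bin2ec"], sep="\t", index=False, lineterminator="\n")
    truth.trait_clusters.rename("cluster").to_csv(
        paths["truth_trait_clusters"], sep="\t", index_label="trait", lineterminator="\n"
    )
    gene_truth.to_csv(
        paths["truth_gene_groups"], sep="\t", index=False, lineterminator="\n"
    )
    bin_truth.to_csv(
        paths["truth_planted_bins"], sep="\t", index=False, lineterminator="\n"
    )
    return paths
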