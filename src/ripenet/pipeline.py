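"""End-to-end orchestration: phenotype stats -> expression norm ->
correlations -> clustering -> network -> enrichment, with every intermediate
written to disk and a checksum-stable run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__, io as _io
from . import (
    clustering,
    correlation,
    enrichment,
    expression,
    network,
    phenotype,
    synthetic,
)
from .config import PipelineConfig, validate_config
from .errors import InvalidInputError

log = logging.getLogger("ripenet")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _default_representatives(trait_ids: list[str], n: int = 17) -> list[str]:
    """Evenly spaced representative traits when none are configured."""
    if len(trait_ids) <= n:
        return list(trait_ids)
    step = (len(trait_ids) - 1) / (n - 1)
    return [trait_ids[round(i * step)] for i in range(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dictionary.

    Any stage failure aborts with :class:`StageFailure` naming the stage.
    Outputs land under ``config.output_dir``; identical config + inputs +
    seed produce identical output bytes.
    """
    problems = validate_config(config)
    if problems:
        raise InvalidInputError("invalid config: " + "; ".join(problems))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "seed": config.rng_seed,
        "stages": {},
        "inputs": {},
        "results": {},
    }

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageFailure(name, exc) from exc
                # wall-clock goes to the log only, keeping the manifest
                # byte-identical across identical runs
                log.info("stage %s done in %.2fs", name, time.perf_counter() - self.t0)
                manifest["stages"][name] = "ok"
                return False

        return _Ctx()

    # -- inputs (simulate if requested) -----------------------------------
    with _stage("inputs"):
        if config.synthetic is not None:
            fixdir = outdir / "fixtures"
            paths = synthetic.write_fixtures(config.synthetic, fixdir)
            config.trait_replicates = str(paths["trait_replicates"])
            config.parental_values = str(paths["parental_values"])
            config.expression = str(paths["expression"])
            config.annotation = str(paths["annotation"])
            config.bin2ec = str(paths["bin2ec"])
        for key in (
            "trait_replicates",
            "parental_values",
            "expression",
            "annotation",
            "bin2ec",
        ):
            path = getattr(config, key)
            if path and Path(path).exists():
                manifest["inputs"][key] = {
                    "path": str(path),
                    "sha256": _io.sha256_of(path),
                }
        table = _io.read_replicate_table(config.trait_replicates)
        parents = (
            _io.read_parental_values(config.parental_values)
            if config.parental_values
            else None
        )
        expr_values = _io.read_matrix(config.expression)
        log.info(
            "inputs: %d replicate rows, %d genes x %d lines",
            len(table),
            *expr_values.shape,
        )

    # -- phenotype stats ---------------------------------------------------
    with _stage("phenotype_stats"):
        summary = phenotype.trait_summary(
            table,
            parents=parents,
            skew_threshold=config.skew_threshold,
            line_mean_basis=config.h2_line_mean_basis,
        )
        summary.to_csv(
            outdir / "trait_summary.tsv", sep="\t", index=False, lineterminator="\n"
        )
        means = phenotype.line_means(table)
        _io.write_matrix(means, outdir / "line_means.tsv", index_label="line")
        manifest["results"]["n_traits"] = int(summary.shape[0])
        manifest["results"]["median_H2"] = float(summary["H2"].median())
        log.info("phenotype: %d traits, median H2=%.3f", *summary.shape[:1], summary["H2"].median())

    # -- expression normalisation -----------------------------------------
    with _stage("expression_norm"):
        if config.floor_mode == "median_filter":
            expr_used, dropped = expression.filter_low_expression(
                expr_values, config.rpkm_floor
            )
            dropped.to_csv(
                outdir / "dropped_low_expression.tsv",
                sep="\t",
                index=False,
                lineterminator="\n",
            )
            log.info("expression: dropped %d low-median genes", len(dropped))
        else:
            expr_used = expr_values
        manifest["results"]["n_genes_used"] = int(expr_used.shape[0])

    # -- correlations ------------------------------------------------------
    with _stage("correlation"):
        tt = correlation.trait_trait_matrix(means)
        _io.write_matrix(tt.rho, outdir / "trait_trait_rho.tsv", index_label="trait")
        _io.write_matrix(tt.p, outdir / "trait_trait_p.tsv", index_label="trait")
        _io.write_long_correlations(tt.to_long(), outdir / "trait_trait_long.tsv")
        tg = correlation.trait_gene_matrix(means, expr_used, floor=config.rpkm_floor)
        _io.write_matrix(tg.rho, outdir / "trait_gene_rho.tsv", index_label="trait")
        associated = correlation.associated_gene_union(
            tg, config.rho_threshold, config.threshold_inclusive
        )
        manifest["results"]["n_associated_genes"] = len(associated)
        log.info(
            "correlation: %d traits, %d genes, %d associated genes",
            tt.rho.shape[0],
            tg.rho.shape[1],
            len(associated),
        )

    # -- metabolite clustering + network ----------------------------------
    with _stage("cluster_metabolites"):
        dend = clustering.hierarchical_cluster(
            tt.rho, distance=config.distance, linkage=config.linkage
        )
        met_clusters = clustering.cut_tree(dend, config.k_metabolites)
        met_clusters.to_frame().to_csv(
            outdir / "metabolite_clusters.tsv", sep="\t", index=False, lineterminator="\n"
        )

    with _stage("network"):
        net = network.build_network(
            tt, config.rho_threshold, config.threshold_inclusive
        )
        n_pos, n_neg = network.edge_counts(net)
        labels = met_clusters.as_series()
        intra_pos = network.intra_cluster_fraction(net, labels, "+")
        intra_neg = network.intra_cluster_fraction(net, labels, "-")
        network.export_network(net, outdir / "network")
        manifest["results"].update(
            n_positive_edges=n_pos,
            n_negative_edges=n_neg,
            intra_cluster_positive_fraction=intra_pos,
            intra_cluster_negative_fraction=intra_neg,
        )
        log.info(
            "network: %d positive / %d negative edges, intra+ %.3f", n_pos, n_neg, intra_pos
        )

    # -- gene groups -------------------------------------------------------
    with _stage("cluster_genes"):
        reps = config.representative_trait_ids or _default_representatives(
            list(means.columns)
        )
        gene_groups = clustering.gene_groups_from_correlation(
            tg,
            reps,
            k=config.k_genes,
            min_assoc=config.rho_threshold,
            trait_clusters=labels,
            distance=config.distance,
            linkage=config.linkage,
            inclusive=config.threshold_inclusive,
        )
        gene_groups.to_frame().to_csv(
            outdir / "gene_groups.tsv", sep="\t", index=False, lineterminator="\n"
        )
        manifest["results"]["n_genes_in_groups"] = len(gene_groups.ids)
        log.info("gene groups: %d genes in %d groups", len(gene_groups.ids), gene_groups.k)

    # -- enrichment --------------------------------------------------------
    with _stage("enrichment"):
        hierarchy = enrichment.parse_bin_hierarchy(config.annotation)
        expressed = set(expr_used.index.astype(str))
        background = hierarchy.annotated_genes
        if config.background == "expressed_annotated":
            background = background & expressed
        query_sets: dict[tuple[str, str], set[str]] = {}
        pos_sets = correlation.significant_gene_sets(
            tg, config.rho_threshold, "positive", config.threshold_inclusive
        )
        neg_sets = correlation.significant_gene_sets(
            tg, config.rho_threshold, "negative", config.threshold_inclusive
        )
        for trait in reps:
            query_sets[(trait, "positive")] = pos_sets[trait] & background
            query_sets[(trait, "negative")] = neg_sets[trait] & background
        for glabel in sorted(set(gene_groups.labels)):
            query_sets[(f"gene_group_{glabel}", "")] = (
                gene_groups.members(glabel) & background
            )
        results = enrichment.enrich_all(query_sets, hierarchy, background)
        if config.fdr_family == "per_query":
            results = (
                results.groupby("query", group_keys=False)
                .apply(lambda df: enrichment.bh_fdr(df, config.fdr_q))
                .reset_index(drop=True)
            )
        else:
            results = enrichment.bh_fdr(results, config.fdr_q)
        results.to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False, lineterminator="\n"
        )
        trait_rows = results.loc[results["direction"] != ""]
        top = enrichment.top_k_categories(trait_rows, config.top_k)
        if config.collapse_redundant:
            top = enrichment.collapse_redundant(top, hierarchy)
        top.to_csv(
            outdir / "top_categories.tsv", sep="\t", index=False, lineterminator="\n"
        )
        ecs_ready = config.bin2ec and Path(config.bin2ec).exists()
        if ecs_ready:
            bin2ec = enrichment.read_bin2ec(config.bin2ec)
            group_ecs, exclusive = enrichment.bins_to_ecs(
                gene_groups, hierarchy, bin2ec
            )
            enrichment.write_ec_lists(group_ecs, outdir / "ec_lists")
            enrichment.write_ec_lists(
                exclusive, outdir / "ec_lists", prefix="ec_exclusive_group"
            )
            manifest["results"]["n_exclusive_ecs"] = {
                g: len(e) for g, e in exclusive.items()
            }
        manifest["results"]["n_enrichment_tests"] = int(results.shape[0])
        manifest["results"]["n_fdr_significant"] = int(results["fdr_significant"].sum())
        log.info(
            "enrichment: %d tests, %d FDR-significant",
            results.shape[0],
            int(results["fdr_significant"].sum()),
        )

    with _stage("manifest"):
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
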