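"""Generator contracts: determinism, planted structure, calibrated correlations."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ripenet import correlation, io as rio, phenotype
from ripenet.errors import AlignmentError, InvalidSpecError
from ripenet.synthetic import (
    SimulationSpec,
    simulate_annotation,
    simulate_expression,
    simulate_ril_traits,
    spearman_loading,
    write_fixtures,
)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_lines=3),
            dict(sigma2_G=-1.0),
            dict(association_strength=1.5),
            dict(annotation_depth=1),
            dict(n_replicates=0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            SimulationSpec(**kwargs).validate()

    def test_planted_bin_outside_hierarchy_rejected(self, small_spec):
        bad = replace(small_spec, planted_enriched_bins=(("G1", "1.1.1.1.1"),))
        with pytest.raises(InvalidSpecError):
            bad.validate()

    def test_replicate_defaults_follow_study_design(self):
        counts = SimulationSpec().replicate_counts()
        assert len(counts) == 77
        assert (counts.iloc[:64] == 3).all()  # volatile-like traits
        assert (counts.iloc[64:] == 5).all()


class TestTraitSimulation:
    def test_replicate_counts_match_spec(self, small_spec):
        table, _ = simulate_ril_traits(small_spec)
        sizes = table.groupby(["line", "trait"]).size().unstack()
        expected = small_spec.replicate_counts()
        for trait in small_spec.trait_ids:
            assert (sizes[trait] == expected[trait]).all()

    def test_zero_residual_variance_identical_replicates(self, noise_free_spec):
        table, truth = simulate_ril_traits(noise_free_spec)
        spread = table.groupby(["line", "trait"])["value"].agg(np.ptp)
        assert (spread == 0).all()
        # downstream H2 = 1 for every trait
        for trait in noise_free_spec.trait_ids[:3]:
            vc = phenotype.anova_variance_components(table, trait)
            assert phenotype.broad_sense_heritability(vc).H2 == 1.0

    def test_shared_factor_perfect_correlation(self, noise_free_spec):
        _, truth = simulate_ril_traits(noise_free_spec)
        clusters = truth.trait_clusters
        same = [t for t in clusters.index if clusters[t] == "I"][:2]
        res = correlation.spearman(
            truth.line_means[same[0]], truth.line_means[same[1]]
        )
        assert res.rho == pytest.approx(1.0)

    def test_correlation_monotone_in_strength(self):
        """Realized same-cluster rank correlation grows with the planted strength."""
        means = []
        for strength in (0.2, 0.5, 0.8):
            vals = []
            for seed in range(3):
                spec = SimulationSpec(
                    n_lines=96, n_traits=6, n_genes=0, gene_groups=(),
                    association_strength=strength, sigma2_E=0.0, rng_seed=seed,
                )
                _, truth = simulate_ril_traits(spec)
                cl = truth.trait_clusters
                pair = [t for t in cl.index if cl[t] == "I"][:2]
                vals.append(
                    correlation.spearman(
                        truth.line_means[pair[0]], truth.line_means[pair[1]]
                    ).rho
                )
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_loading_calibration_targets_spearman_scale(self):
        """The loading maps association strength through the Gaussian-copula
        Spearman-Pearson relation: realized rho_S ~ a, not systematically below."""
        spec = SimulationSpec(
            n_lines=96, n_traits=8, n_genes=0, gene_groups=(),
            association_strength=0.6, sigma2_E=0.0, rng_seed=0,
        )
        rhos = []
        for seed in range(20):
            _, truth = simulate_ril_traits(replace(spec, rng_seed=seed))
            cl = truth.trait_clusters
            pair = [t for t in cl.index if cl[t] == "I"][:2]
            rhos.append(
                correlation.spearman(
                    truth.line_means[pair[0]], truth.line_means[pair[1]]
                ).rho
            )
        assert np.mean(rhos) == pytest.approx(0.6, abs=0.05)
        # and the loading itself solves 2*sin(pi*a/6) at a=1 -> w=1
        assert spearman_loading(1.0) == pytest.approx(1.0)

    def test_missing_rate_injects_nans(self, small_spec):
        spec = replace(small_spec, missing_rate=0.2)
        table, _ = simulate_ril_traits(spec)
        frac = table["value"].isna().mean()
        assert 0.1 < frac < 0.3


class TestExpressionSimulation:
    def test_planted_sign_perfect_association(self, noise_free_spec):
        table, truth = simulate_ril_traits(noise_free_spec)
        expr, gene_truth = simulate_expression(noise_free_spec, truth)
        planted = gene_truth.loc[gene_truth["group"] != ""]
        cl = truth.trait_clusters
        for _, row in planted.iloc[[0, 40, 70]].iterrows():
            trait = [t for t in cl.index if cl[t] == row["target_cluster"]][0]
            rho = correlation.spearman(
                expr.values.loc[row["gene"]], truth.line_means[trait]
            ).rho
            assert rho == pytest.approx(float(row["sign"]), abs=1e-12)

    def test_background_genes_null_rate(self, small_spec):
        """Null gene-trait pairs cross |rho| >= 0.3 rarely at n = 48."""
        table, truth = simulate_ril_traits(small_spec)
        expr, gene_truth = simulate_expression(small_spec, truth)
        background = gene_truth.loc[gene_truth["group"] == "", "gene"]
        corr = correlation.trait_gene_matrix(
            truth.line_means, expr.values.loc[background], floor=3.0
        )
        rate = (corr.rho.abs() >= 0.3).to_numpy().mean()
        # p(|rho| >= 0.3) at n=48 is ~0.038; allow broad slack either way
        assert rate < 0.12

    def test_values_non_negative_with_low_fraction(self, small_spec):
        _, truth = simulate_ril_traits(small_spec)
        expr, _ = simulate_expression(small_spec, truth)
        vals = expr.values.to_numpy()
        assert (vals >= 0).all()
        below = (vals < 3.0).mean()
        assert below > 0.05  # floor handling is actually exercised
        assert expr.gene_lengths.gt(0).all()
        assert expr.library_sizes.gt(0).all()

    def test_line_mismatch_rejected(self, small_spec):
        _, truth = simulate_ril_traits(small_spec)
        other = replace(small_spec, n_lines=small_spec.n_lines + 2)
        with pytest.raises(AlignmentError):
            simulate_expression(other, truth)


class TestAnnotationSimulation:
    def test_planted_members_concentrate_in_planted_bin(self, small_spec):
        hier, bin2ec, bin_truth = simulate_annotation(small_spec)
        groups = small_spec.gene_group_of()
        for _, row in bin_truth.iterrows():
            members = set(groups.index[groups == row["group"]])
            inside = members & hier.genes_in(row["bincode"])
            assert len(inside) / len(members) > 0.6  # excess rate 0.9
        assert set(bin2ec.columns) == {"BINCODE", "EC"}

    def test_annotated_fraction_near_spec(self, small_spec):
        hier, _, _ = simulate_annotation(small_spec)
        planted = (small_spec.gene_group_of() != "").sum()
        background = small_spec.n_genes - planted
        n_bg_annot = len(hier.annotated_genes) - planted
        assert n_bg_annot / background == pytest.approx(
            small_spec.annotated_fraction, abs=0.12
        )

    def test_all_group_genes_annotated(self, small_spec):
        hier, _, _ = simulate_annotation(small_spec)
        groups = small_spec.gene_group_of()
        for gene in groups.index[groups != ""]:
            assert gene in hier.annotated_genes


class TestFixtureFiles:
    def test_byte_identical_across_runs(self, small_spec, tmp_path):
        p1 = write_fixtures(small_spec, tmp_path / "a")
        p2 = write_fixtures(small_spec, tmp_path / "b")
        for name in p1:
            assert rio.sha256_of(p1[name]) == rio.sha256_of(p2[name]), name

    def test_seed_changes_fixtures(self, small_spec, tmp_path):
        p1 = write_fixtures(small_spec, tmp_path / "a")
        p2 = write_fixtures(replace(small_spec, rng_seed=999), tmp_path / "b")
        assert rio.sha256_of(p1["expression"]) != rio.sha256_of(p2["expression"])

    def test_truth_files_cover_planted_structure(self, small_spec, tmp_path):
        paths = write_fixtures(small_spec, tmp_path / "fx")
        clusters = pd.read_csv(paths["truth_trait_clusters"], sep="\t")
        assert len(clusters) == small_spec.n_traits
        genes = pd.read_csv(paths["truth_gene_groups"], sep="\t").fillna("")
        assert (genes["group"] != "").sum() == sum(
            g.size for g in small_spec.gene_groups
        )
        bins = pd.read_csv(paths["truth_planted_bins"], sep="\t", dtype=str)
        assert set(bins["group"]) == {g.name for g in small_spec.gene_groups}

    def test_round_trip_via_io(self, small_spec, tmp_path):
        paths = write_fixtures(small_spec, tmp_path / "fx")
        table = rio.read_replicate_table(paths["trait_replicates"])
        means_file = rio.read_matrix(paths["line_means"])
        recomputed = phenotype.line_means(table)
        pd.testing.assert_frame_equal(
            means_file,
            recomputed.loc[means_file.index, means_file.columns],
            check_names=False,
            rtol=1e-12,
        )
        parents = rio.read_parental_values(paths["parental_values"])
        assert list(parents.columns) == ["parent_a", "parent_b"]
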