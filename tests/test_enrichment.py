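"""Hierarchy parsing, exact hypergeometric enrichment, FDR and EC projection."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ripenet import enrichment
from ripenet.errors import MalformedHierarchyError


def _hierarchy(bins, assignments):
    return enrichment.AnnotationHierarchy(
        bin_names={c: f"category {c}" for c in bins},
        assignments={g: set(a) for g, a in assignments.items()},
    )


@pytest.fixture()
def small_hierarchy():
    bins = ["1", "1.1", "1.2", "2", "2.1", "2.1.3", "3"]
    assignments = {
        "gA": {"2.1.3"},
        "gB": {"1.1"},
        "gC": {"1.2"},
        "gD": {"2.1"},
        "gE": {"3", "1.1"},
    }
    return _hierarchy(bins, assignments)


class TestHierarchy:
    def test_ancestor_propagation(self, small_hierarchy):
        for code in ("2", "2.1", "2.1.3"):
            assert "gA" in small_hierarchy.genes_in(code)
        assert "gA" not in small_hierarchy.genes_in("1")

    def test_sibling_assignments_sum_in_parent(self, small_hierarchy):
        assert small_hierarchy.genes_in("1") == {"gB", "gC", "gE"}

    def test_parent_superset_of_children(self, small_hierarchy):
        for code in small_hierarchy.bincodes:
            parent = enrichment.bin_parent(code)
            if parent:
                assert small_hierarchy.genes_in(code) <= small_hierarchy.genes_in(parent)

    def test_orphan_bincode_rejected(self):
        with pytest.raises(MalformedHierarchyError):
            _hierarchy(["1", "2.1"], {})

    def test_parse_mercator_dialect(self, tmp_path):
        path = tmp_path / "mercator.tsv"
        path.write_text(
            "BINCODE\tNAME\tIDENTIFIER\tDESCRIPTION\n"
            "'1'\t'metabolism'\t\t\n"
            "'1.1'\t'metabolism.synthesis'\t\t\n"
            "'1.1'\t'metabolism.synthesis'\t'gX'\t'enzyme'\n"
            "'1.1'\t'metabolism.synthesis'\t'gY'\t'enzyme'\n"
        )
        h = enrichment.parse_bin_hierarchy(path)
        assert h.bin_names["1.1"] == "metabolism.synthesis"
        assert h.genes_in("1") == {"gX", "gY"}
        assert len(h.annotated_genes) == 2

    def test_parse_deduplicates_with_warning(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "BINCODE\tNAME\tIDENTIFIER\tDESCRIPTION\n"
            "1\troot\t\t\n"
            "1\troot\tgX\t\n"
            "1\troot\tgX\t\n"
        )
        with pytest.warns(UserWarning):
            h = enrichment.parse_bin_hierarchy(path)
        assert h.assignments["gX"] == {"1"}


class TestHypergeometric:
    def test_worked_example_20_5_4_3(self):
        """P(X >= 3) for N=20, K=5, n=4 equals 155/4845 by direct combinatorics."""
        bins = ["1"]
        genes = [f"g{i}" for i in range(20)]
        h = _hierarchy(bins, {g: {"1"} for g in genes[:5]})
        background = set(genes)
        query = set(genes[:3]) | {genes[10]}  # k = 3 of n = 4
        res = enrichment.hypergeometric_enrichment(query, "1", h, background)
        assert res.k == 3 and res.K == 5 and res.n == 4 and res.N == 20
        assert res.p == pytest.approx(155 / 4845, rel=1e-12)
        assert res.tier == "0.01<p<=0.05"

    def test_single_term_case_10_3_3_3(self):
        genes = [f"g{i}" for i in range(10)]
        h = _hierarchy(["1"], {g: {"1"} for g in genes[:3]})
        res = enrichment.hypergeometric_enrichment(
            set(genes[:3]), "1", h, set(genes)
        )
        assert res.p == pytest.approx(1 / 120, rel=1e-12)
        assert res.tier == "p<=0.01"

    def test_zero_overlap_p_is_one(self):
        genes = [f"g{i}" for i in range(10)]
        h = _hierarchy(["1"], {g: {"1"} for g in genes[:3]})
        res = enrichment.hypergeometric_enrichment(
            set(genes[5:8]), "1", h, set(genes)
        )
        assert res.k == 0 and res.p == pytest.approx(1.0)

    def test_empty_category_skipped(self):
        genes = [f"g{i}" for i in range(6)]
        h = _hierarchy(["1", "2"], {g: {"1"} for g in genes[:3]})
        assert (
            enrichment.hypergeometric_enrichment(set(genes[:2]), "2", h, set(genes))
            is None
        )

    def test_query_outside_background_rejected(self):
        h = _hierarchy(["1"], {"gA": {"1"}})
        with pytest.raises(ValueError):
            enrichment.hypergeometric_enrichment({"gZ"}, "1", h, {"gA"})

    def test_matches_subset_enumeration_small_n(self):
        """Exact check against full enumeration of all C(N, n) draws, N <= 9."""
        for N in (5, 7, 9):
            genes = [f"g{i}" for i in range(N)]
            for K in range(1, N + 1):
                h = _hierarchy(["1"], {g: {"1"} for g in genes[:K]})
                for n in range(1, N + 1):
                    tallies: dict[int, int] = {}
                    for subset in itertools.combinations(range(N), n):
                        k_obs = sum(1 for i in subset if i < K)
                        tallies[k_obs] = tallies.get(k_obs, 0) + 1
                    total = sum(tallies.values())
                    for k in sorted(tallies):
                        upper = Fraction(
                            sum(v for kk, v in tallies.items() if kk >= k), total
                        )
                        query = set(genes[:k]) | set(genes[K : K + n - k])
                        res = enrichment.hypergeometric_enrichment(
                            query, "1", h, set(genes)
                        )
                        assert res.p == pytest.approx(float(upper), rel=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        N=st.integers(4, 60),
        data=st.data(),
    )
    def test_p_monotone_in_k(self, N, data):
        """At fixed (N, K, n), P(X >= k) never increases as k grows."""
        from scipy.stats import hypergeom

        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        ps = [float(hypergeom.sf(k - 1, N, K, n)) for k in range(0, min(K, n) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestEnrichAll:
    def test_cross_product_of_queries_and_bins(self, small_hierarchy):
        background = small_hierarchy.annotated_genes
        table = enrichment.enrich_all(
            {"q1": {"gA", "gB"}, "q2": {"gC"}}, small_hierarchy, background
        )
        # 7 bins but each non-empty in background; 2 queries -> 14 rows
        assert len(table) == 14

    def test_query_equals_background_all_p_one(self, small_hierarchy):
        background = small_hierarchy.annotated_genes
        table = enrichment.enrich_all({"all": background}, small_hierarchy, background)
        np.testing.assert_allclose(table["p"].to_numpy(), 1.0, rtol=1e-12)

    def test_directional_queries_kept_separate(self, small_hierarchy):
        background = small_hierarchy.annotated_genes
        table = enrichment.enrich_all(
            {("t1", "positive"): {"gA"}, ("t1", "negative"): {"gB"}},
            small_hierarchy,
            background,
        )
        assert set(table["direction"]) == {"positive", "negative"}

    def test_parent_p_not_smaller_when_only_child_enriched(self):
        """Adding only non-query genes to the parent weakens the signal."""
        genes = [f"g{i}" for i in range(40)]
        assignments = {g: {"1.1"} for g in genes[:10]}
        assignments.update({g: {"1.2"} for g in genes[10:30]})
        assignments.update({g: {"2"} for g in genes[30:]})
        h = _hierarchy(["1", "1.1", "1.2", "2"], assignments)
        query = set(genes[:8])  # concentrated in 1.1
        background = set(genes)
        child = enrichment.hypergeometric_enrichment(query, "1.1", h, background)
        parent = enrichment.hypergeometric_enrichment(query, "1", h, background)
        assert parent.p >= child.p


class TestBhFdr:
    def test_worked_thresholds(self):
        table = pd.DataFrame(
            {"query": "q", "p": [0.001, 0.04, 0.2]}
        )
        out = enrichment.bh_fdr(table.assign(fdr_significant=False), q=0.1)
        assert out["fdr_significant"].tolist() == [True, True, False]

    def test_all_p_one_none_flagged(self):
        table = pd.DataFrame({"p": [1.0] * 5, "fdr_significant": False})
        assert not enrichment.bh_fdr(table, 0.1)["fdr_significant"].any()

    def test_empty_table(self):
        out = enrichment.bh_fdr(pd.DataFrame({"p": []}), 0.1)
        assert out.empty

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_flags_monotone_in_p(self, seed):
        gen = np.random.default_rng(seed)
        table = pd.DataFrame({"p": gen.uniform(size=25), "fdr_significant": False})
        out = enrichment.bh_fdr(table, 0.1)
        flagged = out.loc[out["fdr_significant"], "p"]
        unflagged = out.loc[~out["fdr_significant"], "p"]
        if not flagged.empty and not unflagged.empty:
            assert flagged.max() <= unflagged.min() + 1e-15


class TestTopKAndCollapse:
    @pytest.fixture()
    def results(self):
        rows = [
            ("m1", "positive", "1.1.1", 3, 1e-6, True),
            ("m1", "positive", "2", 1, 1e-6, True),  # tie: deeper bin wins
            ("m1", "positive", "1.1", 2, 1e-4, True),
            ("m1", "positive", "3", 1, 0.02, True),
            ("m1", "negative", "3", 1, 1e-9, True),  # negative direction excluded
            ("m2", "positive", "1", 1, 0.001, True),
            ("m2", "positive", "2", 1, 0.9, False),
        ]
        return pd.DataFrame(
            rows, columns=["query", "direction", "bincode", "level", "p", "fdr_significant"]
        )

    def test_top_k_order_and_tiebreak(self, results):
        top = enrichment.top_k_categories(results, k=2)
        m1 = top.loc[top["query"] == "m1", "bincode"].tolist()
        assert m1 == ["1.1.1", "2"]  # equal p: level 3 before level 1

    def test_fewer_than_k_returned(self, results):
        top = enrichment.top_k_categories(results, k=5)
        assert top.loc[top["query"] == "m2", "bincode"].tolist() == ["1"]

    def test_collapse_identical_sibling_profiles(self, small_hierarchy):
        rows = [
            ("m1", "1.1", "p<=0.01"),
            ("m1", "1.2", "p<=0.01"),
            ("m1", "2.1", "p<=0.01"),  # different parent: kept
        ]
        selected = pd.DataFrame(rows, columns=["query", "bincode", "tier"])
        out = enrichment.collapse_redundant(selected, small_hierarchy)
        assert set(out["bincode"]) == {"1.1", "2.1"}

    def test_distinct_profiles_untouched(self, small_hierarchy):
        rows = [
            ("m1", "1.1", "p<=0.01"),
            ("m1", "1.2", "0.01<p<=0.05"),
        ]
        selected = pd.DataFrame(rows, columns=["query", "bincode", "tier"])
        out = enrichment.collapse_redundant(selected, small_hierarchy)
        assert len(out) == 2

    def test_parent_child_never_collapse(self, small_hierarchy):
        rows = [
            ("m1", "2.1", "p<=0.01"),
            ("m1", "2.1.3", "p<=0.01"),
        ]
        selected = pd.DataFrame(rows, columns=["query", "bincode", "tier"])
        out = enrichment.collapse_redundant(selected, small_hierarchy)
        assert len(out) == 2


class TestBinsToEcs:
    def test_single_gene_single_ec_exclusive(self, small_hierarchy):
        bin2ec = pd.DataFrame({"BINCODE": ["2.1.3"], "EC": ["1.1.1.1"]})
        groups = {"grp": {"gA"}}
        ecs, exclusive = enrichment.bins_to_ecs(groups, small_hierarchy, bin2ec)
        assert ecs["grp"] == {"1.1.1.1"}
        assert exclusive["grp"] == {"1.1.1.1"}

    def test_shared_ec_excluded_from_exclusive(self, small_hierarchy):
        bin2ec = pd.DataFrame(
            {"BINCODE": ["1.1", "1.2"], "EC": ["2.2.2.2", "2.2.2.2"]}
        )
        ecs, exclusive = enrichment.bins_to_ecs(
            {"a": {"gB"}, "b": {"gC"}}, small_hierarchy, bin2ec
        )
        assert ecs["a"] == ecs["b"] == {"2.2.2.2"}
        assert exclusive["a"] == exclusive["b"] == set()

    def test_unknown_bincode_warned_and_skipped(self, small_hierarchy):
        bin2ec = pd.DataFrame({"BINCODE": ["9.9"], "EC": ["3.3.3.3"]})
        with pytest.warns(UserWarning):
            ecs, _ = enrichment.bins_to_ecs({"a": {"gA"}}, small_hierarchy, bin2ec)
        assert ecs["a"] == set()

    def test_ancestor_bins_contribute_ecs(self, small_hierarchy):
        bin2ec = pd.DataFrame({"BINCODE": ["2"], "EC": ["4.4.4.4"]})
        ecs, _ = enrichment.bins_to_ecs({"a": {"gA"}}, small_hierarchy, bin2ec)
        assert ecs["a"] == {"4.4.4.4"}  # gA sits in 2.1.3 under 2

    def test_ec_lists_written_one_per_line(self, small_hierarchy, tmp_path):
        paths = enrichment.write_ec_lists({"g1": {"1.1.1.1", "2.2.2.2"}}, tmp_path)
        assert paths["g1"].read_text() == "1.1.1.1\n2.2.2.2\n"
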