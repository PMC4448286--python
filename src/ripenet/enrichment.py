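"""Hierarchical-annotation enrichment with exact hypergeometric tests.

The annotation is a rooted tree of dotted-decimal bincodes (MapMan/Mercator
style: ``2``, ``2.1``, ``2.1.3``).  Genes are assigned to leaf bins, possibly
several, and implicitly belong to every ancestor bin, so a category's gene
set is the union of assignments at or below it.

For a query gene set (e.g. the genes positively correlated with one
metabolite, or one gene group from the two-way clustering) and a category
with K members among N background genes, enrichment is the upper cumulative
hypergeometric probability P(X >= k) of seeing at least the observed k
category members in a query of size n.  Tests run at every hierarchy level;
the family of all tests in a run is controlled at a Benjamini-Hochberg FDR
(default 10%), with a two-tier p-value colouring (0.01 < p <= 0.05 and
p <= 0.01) retained for display purposes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import MalformedHierarchyError
from .clustering import ClusterAssignment

MERCATOR_COLUMNS = ["BINCODE", "NAME", "IDENTIFIER", "DESCRIPTION"]

RESULT_COLUMNS = [
    "query",
    "direction",
    "bincode",
    "name",
    "level",
    "k",
    "n",
    "K",
    "N",
    "p",
    "tier",
    "fdr_significant",
]


def bin_level(bincode: str) -> int:
    return bincode.count(".") + 1


def bin_parent(bincode: str) -> str | None:
    return bincode.rsplit(".", 1)[0] if "." in bincode else None


def bin_sort_key(bincode: str) -> tuple[int, ...]:
    return tuple(int(part) for part in bincode.split("."))


def p_value_tier(p: float) -> str:
    if p <= 0.01:
        return "p<=0.01"
    if p <= 0.05:
        return "0.01<p<=0.05"
    return "none"


@dataclass
class AnnotationHierarchy:
    """Bin tree plus gene-to-leaf assignments with ancestor propagation."""

    bin_names: dict[str, str]
    assignments: dict[str, set[str]]  # gene -> leaf-level bincodes
    category_genes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code in self.bin_names:
            parent = bin_parent(code)
            if parent is not None and parent not in self.bin_names:
                raise MalformedHierarchyError(
                    f"bincode {code} has no parent bin {parent}"
                )
        for gene, codes in self.assignments.items():
            unknown = codes - set(self.bin_names)
            if unknown:
                raise MalformedHierarchyError(
                    f"gene {gene} assigned to unknown bins {sorted(unknown)}"
                )
        if not self.category_genes:
            self.category_genes = {code: set() for code in self.bin_names}
            for gene, codes in self.assignments.items():
                for code in codes:
                    cursor: str | None = code
                    while cursor is not None:
                        self.category_genes[cursor].add(gene)
                        cursor = bin_parent(cursor)

    @property
    def bincodes(self) -> list[str]:
        return sorted(self.bin_names, key=bin_sort_key)

    @property
    def annotated_genes(self) -> set[str]:
        return set(self.assignments)

    def genes_in(self, bincode: str) -> set[str]:
        return self.category_genes.get(bincode, set())


def parse_bin_hierarchy(path: str | Path) -> AnnotationHierarchy:
    """Parse a Mercator-dialect annotation file.

    Tab-delimited columns BINCODE / NAME / IDENTIFIER / DESCRIPTION, one row
    per gene-bin assignment; rows with an empty IDENTIFIER declare the bin
    itself.  Values may be wrapped in single quotes (Mercator's habit).
    Duplicate (gene, bin) rows are deduplicated with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().upper() for c in df.columns]
    missing = set(MERCATOR_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise MalformedHierarchyError(f"annotation file missing columns {sorted(missing)}")
    strip = lambda s: s.strip().strip("'")
    bin_names: dict[str, str] = {}
    assignments: dict[str, set[str]] = {}
    n_dupes = 0
    for row in df.itertuples(index=False):
        code = strip(row.BINCODE)
        if not code:
            continue
        name = strip(row.NAME)
        bin_names.setdefault(code, name)
        gene = strip(row.IDENTIFIER)
        if gene:
            seen = assignments.setdefault(gene, set())
            if code in seen:
                n_dupes += 1
            seen.add(code)
    if n_dupes:
        warnings.warn(f"deduplicated {n_dupes} repeated (gene, bin) rows")
    return AnnotationHierarchy(bin_names=bin_names, assignments=assignments)


@dataclass
class EnrichmentResult:
    query: str
    bincode: str
    level: int
    k: int
    n: int
    K: int
    N: int
    p: float
    tier: str
    direction: str = ""
    name: str = ""
    fdr_significant: bool = False


def hypergeometric_enrichment(
    query: set[str],
    bincode: str,
    hierarchy: AnnotationHierarchy,
    background: set[str],
    query_id: str = "query",
    direction: str = "",
) -> EnrichmentResult | None:
    """Exact upper-tail hypergeometric test of one (query set, category) pair.

    Counts restrict to the background: N = |background|, K = category genes in
    the background, n = |query| (must be a subset of the background), k =
    query genes in the category.  Categories empty in the background (K = 0)
    are undefined and return None.
    """
    if not query <= background:
        raise ValueError("query set must be a subset of the background")
    members = hierarchy.genes_in(bincode) & background
    K = len(members)
    if K == 0:
        return None
    N = len(background)
    n = len(query)
    k = len(members & query)
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(1.0, max(p, np.nextafter(0, 1)))
    return EnrichmentResult(
        query=query_id,
        bincode=bincode,
        level=bin_level(bincode),
        k=k,
        n=n,
        K=K,
        N=N,
        p=p,
        tier=p_value_tier(p),
        direction=direction,
        name=hierarchy.bin_names.get(bincode, ""),
    )


def enrich_all(
    query_sets: dict[str, set[str]] | dict[tuple[str, str], set[str]],
    hierarchy: AnnotationHierarchy,
    background: set[str],
) -> pd.DataFrame:
    """Test every query set against every bin at every hierarchy level.

    Query keys may be plain ids or (id, direction) pairs — per-metabolite
    positively and negatively correlated gene sets are separate queries.
    Categories with no background member are skipped.  Returns a long-format
    table with RESULT_COLUMNS (fdr_significant all False until bh_fdr runs).
    """
    rows: list[EnrichmentResult] = []
    for key, genes in query_sets.items():
        if isinstance(key, tuple):
            query_id, direction = key
        else:
            query_id, direction = key, ""
        qset = set(genes) & background
        for code in hierarchy.bincodes:
            res = hypergeometric_enrichment(
                qset, code, hierarchy, background, query_id=str(query_id),
                direction=direction,
            )
            if res is not None:
                rows.append(res)
    table = pd.DataFrame(
        [
            {
                "query": r.query,
                "direction": r.direction,
                "bincode": r.bincode,
                "name": r.name,
                "level": r.level,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "tier": r.tier,
                "fdr_significant": r.fdr_significant,
            }
            for r in rows
        ],
        columns=RESULT_COLUMNS,
    )
    return table


def bh_fdr(results: pd.DataFrame, q: float = 0.10) -> pd.DataFrame:
    """Benjamini-Hochberg over the pooled family of all tests in the table.

    Flags every test with p at or below the largest p(i) satisfying
    p(i) <= i*q/m.  Returns a copy with ``fdr_significant`` filled in.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    out = results.copy()
    if out.empty:
        return out
    reject, _, _, _ = multipletests(out["p"].to_numpy(), alpha=q, method="fdr_bh")
    out["fdr_significant"] = reject
    return out


def top_k_categories(results: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k FDR-significant positive-direction categories per query set.

    Ordering: smaller p first, then deeper (more specific) level, then
    lexicographic bincode.  Queries with fewer than k significant categories
    return what they have.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = results.loc[results["fdr_significant"]]
    if "direction" in sub.columns and (sub["direction"] == "positive").any():
        sub = sub.loc[sub["direction"].isin(["positive", ""])]
    sub = sub.copy()
    sub["_key"] = sub["bincode"].map(bin_sort_key)
    sub = sub.sort_values(
        by=["query", "p", "level", "_key"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    out = sub.groupby("query", sort=True, group_keys=False).head(k)
    return out.drop(columns="_key").reset_index(drop=True)


def collapse_redundant(
    selected: pd.DataFrame, hierarchy: AnnotationHierarchy
) -> pd.DataFrame:
    """Collapse sibling categories with identical across-query profiles.

    Among selected categories sharing a parent bin whose (query, tier)
    significance profiles coincide, only the lowest bincode is retained;
    parent/child pairs never collapse.  This is a display-reduction heuristic
    and is off by default in the pipeline.
    """
    if selected.empty:
        return selected.copy()
    profiles: dict[str, frozenset] = {}
    for code, grp in selected.groupby("bincode"):
        profiles[code] = frozenset(zip(grp["query"], grp["tier"]))
    keep: set[str] = set()
    by_parent: dict[str | None, list[str]] = {}
    for code in sorted(profiles, key=bin_sort_key):
        by_parent.setdefault(bin_parent(code), []).append(code)
    for siblings in by_parent.values():
        seen: dict[frozenset, str] = {}
        for code in siblings:  # already in bincode order
            prof = profiles[code]
            if prof not in seen:
                seen[prof] = code
                keep.add(code)
    return selected.loc[selected["bincode"].isin(keep)].reset_index(drop=True)


def read_bin2ec(path: str | Path) -> pd.DataFrame:
    """Two-column bincode -> EC number table (one row per pair)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().upper() for c in df.columns]
    if not {"BINCODE", "EC"} <= set(df.columns):
        raise ValueError("bin2ec table needs columns BINCODE and EC")
    return df[["BINCODE", "EC"]]


def bins_to_ecs(
    gene_groups: ClusterAssignment | dict[str, set[str]],
    hierarchy: AnnotationHierarchy,
    bin2ec: pd.DataFrame,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Project gene groups onto EC numbers via their members' bins.

    For each group, the EC set is the union over member genes of the ECs
    mapped to any category the gene belongs to (leaf assignments plus
    ancestors).  The exclusive subset keeps ECs appearing in exactly one
    group.  Unknown bincodes in the map are warned about and skipped.
    """
    if isinstance(gene_groups, ClusterAssignment):
        groups = {
            str(label): gene_groups.members(label)
            for label in sorted(set(gene_groups.labels))
        }
    else:
        groups = {str(k): set(v) for k, v in gene_groups.items()}
    ec_by_bin: dict[str, set[str]] = {}
    unknown: set[str] = set()
    for row in bin2ec.itertuples(index=False):
        code, ec = row.BINCODE, row.EC
        if code not in hierarchy.bin_names:
            unknown.add(code)
            continue
        ec_by_bin.setdefault(code, set()).add(ec)
    if unknown:
        warnings.warn(f"bin2ec references unknown bincodes: {sorted(unknown)[:5]}...")
    gene_categories: dict[str, set[str]] = {}
    for gene, codes in hierarchy.assignments.items():
        cats: set[str] = set()
        for code in codes:
            cursor: str | None = code
            while cursor is not None:
                cats.add(cursor)
                cursor = bin_parent(cursor)
        gene_categories[gene] = cats
    group_ecs: dict[str, set[str]] = {}
    for group, genes in groups.items():
        ecs: set[str] = set()
        for gene in genes:
            for code in gene_categories.get(gene, ()):
                ecs |= ec_by_bin.get(code, set())
        group_ecs[group] = ecs
    exclusive: dict[str, set[str]] = {}
    for group, ecs in group_ecs.items():
        others: set[str] = set()
        for other, oecs in group_ecs.items():
            if other != group:
                others |= oecs
        exclusive[group] = ecs - others
    return group_ecs, exclusive


def write_ec_lists(
    group_ecs: dict[str, set[str]], outdir: str | Path, prefix: str = "ec_group"
) -> dict[str, Path]:
    """One plain-text EC list per group (one EC per line), KEGG-Mapper ready."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for group, ecs in group_ecs.items():
        path = outdir / f"{prefix}_{group}.txt"
        path.write_text("".join(ec + "\n" for ec in sorted(ecs)))
        paths[group] = path
    return paths
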