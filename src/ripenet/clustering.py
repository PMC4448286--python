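"""Two-way hierarchical clustering with fixed-k tree cuts.

Metabolites are clustered on the rows of their trait x trait rho matrix and
cut into k = 3 groups; genes are clustered on their rho vectors against a set
of representative traits and cut into k = 4 groups — both mirroring an
R-style ``hclust`` + ``cutree`` workflow.  The default dissimilarity is
1 - Spearman rho between profile vectors with average linkage; Euclidean
distance and complete/Ward linkage are available.

Cutting is done by merge count (the first n - k merges), which is exactly
R's ``cutree`` semantics and guarantees that the k-partition refines the
(k-1)-partition of the same tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .errors import (
    AlignmentError,
    EmptyResultError,
    InvalidKError,
    IsolatedItemError,
)
from .correlation import CorrelationMatrix, _pairwise_spearman

DISTANCES = ("one_minus_correlation", "euclidean")
LINKAGES = ("average", "complete", "ward")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over named items."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) linkage encoding
    ids: list[str]
    distance: str
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = _hier.leaves_list(self.linkage_matrix)
        return [self.ids[i] for i in order]


@dataclass
class ClusterAssignment:
    """Partition of items into k labelled clusters."""

    ids: list[str]
    labels: np.ndarray  # int labels 1..k, in order of ids
    k: int
    distance: str = ""
    linkage: str = ""
    signatures: dict[int, str] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.ids, name="cluster")

    def members(self, label: int) -> set[str]:
        return {i for i, lab in zip(self.ids, self.labels) if lab == label}

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"item": self.ids, "cluster": self.labels})
        if self.signatures:
            out["signature"] = [self.signatures.get(int(c), "") for c in self.labels]
        return out


def _profile_distances(
    profiles: pd.DataFrame, distance: str
) -> np.ndarray:
    values = profiles.to_numpy(dtype=float)
    if np.isnan(values).all(axis=1).any():
        raise IsolatedItemError("item with all-missing profile")
    if distance == "euclidean":
        return pdist(values)
    if distance != "one_minus_correlation":
        raise ValueError(f"unknown distance {distance!r}; choose from {DISTANCES}")
    if values.shape[1] < 3:
        # rank correlation between length-<3 profiles is degenerate;
        # Euclidean is the only meaningful dissimilarity there
        return pdist(values)
    if np.isnan(values).any():
        raise IsolatedItemError("missing profile entries not supported for rank distance")
    rho, _ = _pairwise_spearman(values, values)
    if np.isnan(rho).any():
        bad = profiles.index[np.isnan(rho).all(axis=1)].tolist()
        raise IsolatedItemError(f"undefined distance for constant profiles: {bad}")
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return squareform(np.maximum(d, 0.0), checks=False)


def hierarchical_cluster(
    profiles: pd.DataFrame,
    distance: str = "one_minus_correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of the rows of an items x features matrix."""
    if profiles.shape[0] < 2:
        raise InvalidKError("need >= 2 items to cluster")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    condensed = _profile_distances(profiles, distance)
    Z = _hier.linkage(condensed, method=linkage)
    return Dendrogram(
        linkage_matrix=Z,
        ids=[str(i) for i in profiles.index],
        distance=distance,
        linkage=linkage,
    )


def cut_tree(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into exactly k clusters (R cutree semantics).

    Labels are renumbered 1..k by first appearance in item order, so the
    assignment is stable for identical input.
    """
    n = len(dend.ids)
    if not 1 <= k <= n:
        raise InvalidKError(f"k={k} out of range [1, {n}]")
    raw = _hier.cut_tree(dend.linkage_matrix, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return ClusterAssignment(
        ids=list(dend.ids),
        labels=labels,
        k=k,
        distance=dend.distance,
        linkage=dend.linkage,
    )


def cluster_agreement(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Adjusted Rand index between two partitions of the same item set."""
    if set(a.ids) != set(b.ids):
        raise AlignmentError("partitions cover different item sets")
    sb = b.as_series()
    return float(adjusted_rand_score(a.labels, sb.loc[a.ids].to_numpy()))


def _group_signature(mean_rho: pd.Series) -> str:
    """Sign pattern of a group's mean association per trait cluster, e.g. 'I+/II-/III-'."""
    parts = []
    for cluster, value in mean_rho.items():
        sign = "0" if abs(value) < 0.05 else ("+" if value > 0 else "-")
        parts.append(f"{cluster}{sign}")
    return "/".join(parts)


def gene_groups_from_correlation(
    corr: CorrelationMatrix,
    representative_traits: list[str],
    k: int = 4,
    min_assoc: float = 0.3,
    trait_clusters: pd.Series | None = None,
    distance: str = "one_minus_correlation",
    linkage: str = "average",
    inclusive: bool = True,
) -> ClusterAssignment:
    """Cluster genes by their rho profile over the representative traits.

    Genes are first filtered to those with |rho| >= ``min_assoc`` against at
    least one representative trait; the retained genes' rho vectors over the
    representative traits are clustered and the tree is cut at ``k``.  When a
    trait -> cluster labelling is supplied, each gene group is annotated with
    a deterministic sign signature of its mean association per trait cluster
    (the "black"/"red"/"green"-style naming is this signature, never an input).
    """
    missing = [t for t in representative_traits if t not in corr.rho.index]
    if missing:
        raise AlignmentError(f"representative traits absent from matrix: {missing}")
    sub = corr.rho.loc[representative_traits]  # traits x genes
    strength = sub.abs().max(axis=0)
    mask = (strength >= min_assoc) if inclusive else (strength > min_assoc)
    mask &= ~sub.isna().all(axis=0)
    genes = sub.columns[mask.to_numpy()]
    if len(genes) == 0:
        raise EmptyResultError("no gene passes the association filter")
    profiles = sub[genes].T  # genes x representative traits
    if len(genes) == 1 or k == 1:
        assignment = ClusterAssignment(
            ids=[str(g) for g in genes],
            labels=np.ones(len(genes), dtype=int),
            k=1,
            distance=distance,
            linkage=linkage,
        )
    else:
        dend = hierarchical_cluster(profiles, distance=distance, linkage=linkage)
        assignment = cut_tree(dend, min(k, len(genes)))
    if trait_clusters is not None:
        by_cluster = profiles.T.groupby(
            trait_clusters.loc[representative_traits].to_numpy()
        ).mean()  # trait-cluster x genes
        for label in sorted(set(assignment.labels)):
            members = list(assignment.members(label))
            assignment.signatures[int(label)] = _group_signature(
                by_cluster[members].mean(axis=1)
            )
    return assignment
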