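"""Spearman rank correlation engine for trait x trait and trait x gene matrices.

rho is the Pearson correlation of average-rank vectors (ties get average
ranks); the two-sided p-value uses the t approximation

    t = rho * sqrt((n - 2) / (1 - rho^2))   on n - 2 df,

with p = 0 by convention at rho = +/-1.  For small tie-free samples an exact
permutation p (full enumeration of the rho null distribution) is available,
mirroring what R's cor.test does at small n; at the population sizes this
pipeline targets (n ~ 96) the t approximation is accurate and is the default.

Missing values are handled pairwise-complete with the usable sample size
reported per pair.  Pairs with fewer than MIN_N usable observations or with a
zero-variance member are flagged undefined (NaN), never silently zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError
from . import expression as _expression

MIN_N = 3
EXACT_N_MAX = 9


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n_used: int


@dataclass
class CorrelationMatrix:
    """Pairwise rho / p / usable-n rectangles with shared row & column ids."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n_used: pd.DataFrame

    @property
    def row_ids(self) -> pd.Index:
        return self.rho.index

    @property
    def col_ids(self) -> pd.Index:
        return self.rho.columns

    def to_long(self) -> pd.DataFrame:
        """Long-format records (row, col, rho, p, n_used)."""
        rows = np.repeat(self.rho.index.to_numpy(), len(self.rho.columns))
        cols = np.tile(self.rho.columns.to_numpy(), len(self.rho.index))
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "rho": self.rho.to_numpy().ravel(),
                "p": self.p.to_numpy().ravel(),
                "n_used": self.n_used.to_numpy().ravel(),
            }
        )


def _t_approx_p(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t approximation, elementwise; NaN passes through."""
    rho, n = np.broadcast_arrays(
        np.asarray(rho, dtype=float), np.asarray(n, dtype=float)
    )
    p = np.full(rho.shape, np.nan)
    ok = ~np.isnan(rho) & (n >= MIN_N)
    at_one = ok & (np.abs(rho) >= 1.0 - 1e-15)
    interior = ok & ~at_one
    if interior.any():
        rr = rho[interior]
        nn = n[interior]
        t = np.abs(rr) * np.sqrt((nn - 2.0) / (1.0 - rr * rr))
        p[interior] = 2.0 * stats.t.sf(t, nn - 2.0)
    p[at_one] = 0.0
    return p


def t_approx_p(rho: float, n: int) -> float:
    """Two-sided p of a correlation of magnitude |rho| at sample size n
    under the t approximation (the significance scale behind the |rho| >= 0.3
    threshold at n = 96)."""
    return float(_t_approx_p(np.asarray(rho, dtype=float), np.asarray(n, dtype=float)))


@lru_cache(maxsize=None)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| null distribution over all n! permutations (tie-free)."""
    x = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(x)))
    d2 = ((perms - x) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return np.sort(np.abs(rho))


def exact_permutation_p(rho: float, n: int) -> float:
    """Exact two-sided permutation p = P(|rho_perm| >= |rho_obs|), tie-free x/y."""
    null = _exact_null_abs_rho(n)
    idx = np.searchsorted(null, abs(rho) - 1e-12, side="left")
    return float((null.size - idx) / null.size)


def spearman(
    x: Iterable[float],
    y: Iterable[float],
    p_method: Literal["t", "exact", "auto"] = "t",
) -> SpearmanResult:
    """Spearman rho with two-sided p for a single pair of vectors.

    Pairs with a missing member are dropped.  Returns NaN rho/p when fewer
    than three complete pairs remain or either vector is constant after
    dropping ("undefined", not an exception).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise AlignmentError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < MIN_N or np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(np.nan, np.nan, n)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    tie_free = len(set(x)) == n and len(set(y)) == n
    use_exact = p_method == "exact" or (
        p_method == "auto" and tie_free and n <= EXACT_N_MAX
    )
    if use_exact and tie_free:
        p = exact_permutation_p(rho, n)
    else:
        p = float(_t_approx_p(np.array(rho), np.array(n)))
    return SpearmanResult(rho, p, n)


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Average ranks along rows; rows with zero variance become NaN rows."""
    ranks = stats.rankdata(values, axis=1).astype(float)
    spread = values.max(axis=1) - values.min(axis=1)
    ranks[spread == 0] = np.nan
    return ranks


def _standardize_rows(ranks: np.ndarray) -> np.ndarray:
    mean = ranks.mean(axis=1, keepdims=True)
    centered = ranks - mean
    norm = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return centered / norm


def _pairwise_spearman(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs rho between rows of ``a`` and rows of ``b`` (no missing data).

    Returns (rho, n_used); zero-variance rows yield NaN rho.
    """
    n = a.shape[1]
    za = _standardize_rows(_rank_rows(a))
    zb = _standardize_rows(_rank_rows(b))
    rho = np.clip(za @ zb.T, -1.0, 1.0)
    n_used = np.full(rho.shape, n, dtype=int)
    return rho, n_used


def _pairwise_spearman_missing(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete rho for inputs with missing values (slow path)."""
    rho = np.full((a.shape[0], b.shape[0]), np.nan)
    n_used = np.zeros(rho.shape, dtype=int)
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            res = spearman(a[i], b[j])
            rho[i, j] = res.rho
            n_used[i, j] = res.n_used
    return rho, n_used


def _correlate_blocks(
    rows: pd.DataFrame, cols: pd.DataFrame
) -> CorrelationMatrix:
    """rows, cols: items x lines frames sharing identical line order."""
    a = rows.to_numpy(dtype=float)
    b = cols.to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        rho, n_used = _pairwise_spearman_missing(a, b)
    else:
        rho, n_used = _pairwise_spearman(a, b)
    p = _t_approx_p(rho, n_used)
    idx, col = rows.index, cols.index
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=col),
        p=pd.DataFrame(p, index=idx, columns=col),
        n_used=pd.DataFrame(n_used, index=idx, columns=col),
    )


def trait_trait_matrix(traits: pd.DataFrame) -> CorrelationMatrix:
    """Symmetric trait x trait Spearman matrix from a lines x traits table."""
    if traits.shape[1] < 2:
        raise AlignmentError("need >= 2 traits")
    profiles = traits.T  # traits x lines
    corr = _correlate_blocks(profiles, profiles)
    rho = corr.rho.to_numpy().copy()
    pm = corr.p.to_numpy().copy()
    defined = ~np.isnan(np.diag(rho))
    np.fill_diagonal(rho, np.where(defined, 1.0, np.nan))
    np.fill_diagonal(pm, np.where(defined, 0.0, np.nan))
    ids = corr.rho.index
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        p=pd.DataFrame(pm, index=ids, columns=ids),
        n_used=corr.n_used,
    )


def trait_gene_matrix(
    traits: pd.DataFrame,
    expr: "_expression.ExpressionMatrix | pd.DataFrame",
    floor: float = 3.0,
) -> CorrelationMatrix:
    """Traits x genes Spearman matrix; the RPKM floor is applied before ranking.

    Genes constant after flooring are flagged undefined (NaN column).
    """
    values = expr.values if isinstance(expr, _expression.ExpressionMatrix) else expr
    shared = traits.index.intersection(values.columns)
    if len(shared) < MIN_N:
        raise AlignmentError(
            f"need >= {MIN_N} shared lines, got {len(shared)}"
        )
    floored, _constant = _expression.apply_floor(values[shared], floor)
    return _correlate_blocks(traits.loc[shared].T, floored)


def significant_gene_sets(
    corr: CorrelationMatrix,
    threshold: float = 0.3,
    direction: Literal["positive", "negative"] = "positive",
    inclusive: bool = True,
) -> dict[str, set[str]]:
    """Per-trait sets of genes passing the signed rho threshold.

    ``inclusive`` keeps pairs at exactly the threshold (|rho| >= thr); the
    strict variant uses >.  Undefined pairs never qualify.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    rho = corr.rho
    if direction == "positive":
        mask = rho >= threshold if inclusive else rho > threshold
    else:
        mask = rho <= -threshold if inclusive else rho < -threshold
    mask = mask.fillna(False)
    return {
        trait: set(rho.columns[mask.loc[trait].to_numpy()])
        for trait in rho.index
    }


def associated_gene_union(
    corr: CorrelationMatrix, threshold: float = 0.3, inclusive: bool = True
) -> set[str]:
    """Genes associated (either sign) with at least one trait."""
    pos = significant_gene_sets(corr, threshold, "positive", inclusive)
    neg = significant_gene_sets(corr, threshold, "negative", inclusive)
    out: set[str] = set()
    for sets in (pos, neg):
        for genes in sets.values():
            out |= genes
    return out
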