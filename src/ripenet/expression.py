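"""RPKM normalisation, expression flooring and low-expression filtering.

Expression values are held as a genes x lines :class:`pandas.DataFrame` with
RPKM semantics (reads per kilobase of exon model per million mapped reads),
optionally accompanied by gene lengths (bp) and per-line library sizes
(mapped reads) so count matrices can be normalised and round-tripped.

The floor is a lower clamp applied before rank correlation: among genes that
are effectively unexpressed, tiny RPKM fluctuations would otherwise generate
spurious rank structure.  Genes that are constant after clamping carry no
rank information and are flagged so the correlation engine can mark them
undefined rather than silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import InvalidInputError


@dataclass
class ExpressionMatrix:
    """Genes x lines abundance matrix with optional normalisation metadata."""

    values: pd.DataFrame
    gene_lengths: Optional[pd.Series] = None
    library_sizes: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise InvalidInputError("gene and line ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise InvalidInputError("expression values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def lines(self) -> pd.Index:
        return self.values.columns


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series,
) -> ExpressionMatrix:
    """Normalise raw counts to RPKM: count * 1e9 / (length_bp * library_size).

    Parameters
    ----------
    counts : genes x lines integer matrix of aligned-read counts.
    gene_lengths : exon-model length in bp, indexed by gene id.
    library_sizes : mapped reads per line, indexed by line id.
    """
    lengths = gene_lengths.reindex(counts.index)
    libs = library_sizes.reindex(counts.columns)
    if lengths.isna().any() or libs.isna().any():
        raise InvalidInputError("gene lengths / library sizes missing for some ids")
    if (lengths <= 0).any():
        raise InvalidInputError("gene lengths must be > 0")
    if (libs <= 0).any():
        raise InvalidInputError("library sizes must be > 0")
    values = counts.to_numpy(dtype=float) * 1e9
    values /= lengths.to_numpy(dtype=float)[:, None]
    values /= libs.to_numpy(dtype=float)[None, :]
    out = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    return ExpressionMatrix(out, gene_lengths=lengths, library_sizes=libs)


def apply_floor(
    expr: ExpressionMatrix | pd.DataFrame, floor: float = 3.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Clamp every value below ``floor`` up to ``floor``.

    Returns the clamped matrix and a boolean per-gene flag marking genes left
    constant (zero variance) by the clamp; such genes have no defined rank
    correlation and are excluded downstream.
    """
    if floor < 0:
        raise InvalidInputError("floor must be >= 0")
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    clamped = values.clip(lower=floor)
    constant = clamped.nunique(axis=1) <= 1
    constant.name = "constant_after_floor"
    return clamped, constant


def filter_low_expression(
    expr: ExpressionMatrix | pd.DataFrame, median_threshold: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genes whose median RPKM across lines falls below the threshold.

    Returns (kept matrix, report of dropped genes with their medians).
    """
    if median_threshold < 0:
        raise InvalidInputError("median_threshold must be >= 0")
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    medians = values.median(axis=1)
    dropped_mask = medians < median_threshold
    report = pd.DataFrame(
        {"gene": values.index[dropped_mask], "median": medians[dropped_mask].to_numpy()}
    )
    return values.loc[~dropped_mask], report
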