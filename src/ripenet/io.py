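"""Readers and writers for the tab-delimited file dialects used throughout.

All tables are plain TSV.  Matrices carry the row-id in the first column and
one header row; the replicate trait table is long-format with columns
``line``, ``trait``, ``replicate``, ``value``; parental values are one row per
trait with columns ``trait``, ``parent_a``, ``parent_b``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

REPLICATE_COLUMNS = ["line", "trait", "replicate", "value"]
PARENTAL_COLUMNS = ["trait", "parent_a", "parent_b"]


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_replicate_table(table: pd.DataFrame, path: str | Path) -> None:
    table[REPLICATE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_replicate_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"line": str, "trait": str})
    missing = set(REPLICATE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")
    return table


def write_parental_values(parents: pd.DataFrame, path: str | Path) -> None:
    parents[PARENTAL_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_parental_values(path: str | Path) -> pd.DataFrame:
    parents = pd.read_csv(path, sep="\t", dtype={"trait": str})
    missing = set(PARENTAL_COLUMNS) - set(parents.columns)
    if missing:
        raise ValueError(f"parental table missing columns: {sorted(missing)}")
    return parents.set_index("trait")


def write_long_correlations(long: pd.DataFrame, path: str | Path) -> None:
    """Long-format correlation records: row, col, rho, p, n_used."""
    long.to_csv(path, sep="\t", index=False, lineterminator="\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
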