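"""Replicate-level trait statistics for a RIL population.

Each line of the population was phenotyped in several replicate fruits per
trait.  Treating the line as a random genetic factor, a one-way random-effects
ANOVA splits the phenotypic variance into a between-line (genetic) component
sigma2_G and a within-line (residual) component sigma2_E.  Broad-sense
heritability is the intraclass correlation

    H2 = sigma2_G / (sigma2_G + sigma2_E)

On a balanced design the method-of-moments estimators below (sigma2_E = MSW,
sigma2_G = (MSB - MSW) / r) coincide with REML; unbalanced designs use the
standard effective replicate number r0 = (N - sum(ni^2)/N) / (g - 1).

Severely right-skewed traits (abundance data frequently are) are square-root
transformed before the ANOVA; the decision is recorded per trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CannotEstimateError, EmptyInputError, UnknownTraitError


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_E: float
    F: float
    p_genetic: float
    n_lines: int
    reps_per_line: float  # effective replicate number r0 (== r when balanced)


@dataclass
class HeritabilityResult:
    H2: float
    transform_applied: bool = False


def sample_skewness(values: np.ndarray) -> float:
    """Biased sample skewness g1; defined as 0 for constant vectors."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise EmptyInputError("all-missing vector")
    if values.size < 3 or np.ptp(values) == 0:
        return 0.0
    return float(stats.skew(values, bias=True))


def sqrt_transform_if_skewed(
    values: np.ndarray | pd.Series, skew_threshold: float = 1.0
) -> tuple[np.ndarray, bool]:
    """Square-root transform a trait vector iff its skewness g1 exceeds the threshold.

    Negative values (possible on derived scales) are shifted to zero before
    taking roots.  Missing values pass through untouched.
    """
    arr = np.asarray(values, dtype=float)
    if np.all(np.isnan(arr)):
        raise EmptyInputError("all-missing vector")
    if sample_skewness(arr) > skew_threshold:
        shifted = arr - min(0.0, np.nanmin(arr))
        return np.sqrt(shifted), True
    return arr.copy(), False


def _groups_for_trait(table: pd.DataFrame, trait: str) -> list[np.ndarray]:
    sub = table.loc[table["trait"] == trait]
    if sub.empty:
        raise UnknownTraitError(trait)
    groups = []
    for _, vals in sub.groupby("line", sort=True)["value"]:
        arr = vals.to_numpy(dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size:
            groups.append(arr)
    return groups


def anova_variance_components(
    table: pd.DataFrame, trait: str
) -> VarianceComponents:
    """One-way random-effects ANOVA of a trait with line as the genetic factor.

    ``table`` is a long-format replicate table (columns line/trait/replicate/
    value).  Lines with a single replicate are allowed within an otherwise
    replicated design; a design where every line is a singleton cannot
    separate the variance components.
    """
    groups = _groups_for_trait(table, trait)
    g = len(groups)
    sizes = np.array([len(gr) for gr in groups], dtype=float)
    N = sizes.sum()
    if g < 2:
        raise CannotEstimateError("need >= 2 lines")
    if (sizes <= 1).all():
        raise CannotEstimateError("every line has a single replicate")
    means = np.array([gr.mean() for gr in groups])
    grand = np.concatenate(groups).mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(sum(((gr - m) ** 2).sum() for gr, m in zip(groups, means)))
    msb = ssb / (g - 1)
    msw = ssw / (N - g)
    r0 = (N - (sizes**2).sum() / N) / (g - 1)
    sigma2_e = msw
    sigma2_g = max(0.0, (msb - msw) / r0)
    if msw > 0:
        F = msb / msw
        p = float(stats.f.sf(F, g - 1, N - g))
    elif msb > 0:
        F, p = np.inf, 0.0
    else:  # all values identical
        F, p = np.nan, 1.0
    return VarianceComponents(
        sigma2_G=sigma2_g,
        sigma2_E=sigma2_e,
        F=F,
        p_genetic=p,
        n_lines=g,
        reps_per_line=float(r0),
    )


def broad_sense_heritability(
    vc: VarianceComponents,
    transform_applied: bool = False,
    line_mean_basis: bool = False,
) -> HeritabilityResult:
    """Intraclass-correlation heritability H2 = sG2 / (sG2 + sE2).

    ``line_mean_basis=True`` switches to the line-mean form
    sG2 / (sG2 + sE2 / r0), the heritability of a line's replicate mean.
    """
    denom_e = vc.sigma2_E / vc.reps_per_line if line_mean_basis else vc.sigma2_E
    total = vc.sigma2_G + denom_e
    h2 = 0.0 if total == 0 else vc.sigma2_G / total
    return HeritabilityResult(H2=float(h2), transform_applied=transform_applied)


def line_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean accumulation over available replicates -> lines x traits matrix.

    (line, trait) cells with no observed replicate are left missing (NaN).
    """
    if table.empty:
        raise EmptyInputError("empty replicate table")
    return table.pivot_table(index="line", columns="trait", values="value", aggfunc="mean")


def parental_range_fractions(
    traits: pd.DataFrame, parents: pd.DataFrame, trait: str
) -> tuple[float, float, float]:
    """Fractions of lines within / above / below the closed parental range.

    ``parents`` is indexed by trait with columns parent_a / parent_b; the
    range is [min, max] of the two parental values, endpoints included.
    """
    if trait not in traits.columns:
        raise UnknownTraitError(trait)
    if trait not in parents.index:
        raise UnknownTraitError(f"no parental values for {trait}")
    lo, hi = sorted(
        (float(parents.loc[trait, "parent_a"]), float(parents.loc[trait, "parent_b"]))
    )
    vals = traits[trait].dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise EmptyInputError(f"no non-missing lines for {trait}")
    within = float(np.mean((vals >= lo) & (vals <= hi)))
    above = float(np.mean(vals > hi))
    below = float(np.mean(vals < lo))
    return within, above, below


SUMMARY_COLUMNS = [
    "trait",
    "transform_applied",
    "sigma2_G",
    "sigma2_E",
    "F",
    "p_genetic",
    "H2",
    "fraction_within",
    "fraction_above",
    "fraction_below",
]


def trait_summary(
    table: pd.DataFrame,
    parents: pd.DataFrame | None = None,
    skew_threshold: float = 1.0,
    line_mean_basis: bool = False,
) -> pd.DataFrame:
    """Per-trait statistics table: transform flag, variance components, H2,
    genetic-effect test and (when parental values are supplied) parental-range
    fractions.  Column order is stable (``SUMMARY_COLUMNS``)."""
    rows = []
    means = line_means(table)
    for trait in sorted(table["trait"].unique()):
        sub = table.loc[table["trait"] == trait].copy()
        transformed, flag = sqrt_transform_if_skewed(
            sub["value"].to_numpy(dtype=float), skew_threshold
        )
        sub["value"] = transformed
        vc = anova_variance_components(sub, trait)
        h2 = broad_sense_heritability(vc, flag, line_mean_basis=line_mean_basis)
        row = {
            "trait": trait,
            "transform_applied": flag,
            "sigma2_G": vc.sigma2_G,
            "sigma2_E": vc.sigma2_E,
            "F": vc.F,
            "p_genetic": vc.p_genetic,
            "H2": h2.H2,
            "fraction_within": np.nan,
            "fraction_above": np.nan,
            "fraction_below": np.nan,
        }
        if parents is not None and trait in parents.index:
            within, above, below = parental_range_fractions(means, parents, trait)
            row.update(
                fraction_within=within, fraction_above=above, fraction_below=below
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
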