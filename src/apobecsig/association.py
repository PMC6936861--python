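"""Expression-mutation association statistics.

Pearson correlation between log10-transformed expression and log10
mutation load, Mann-Whitney group comparisons with a median fold-difference,
and subgroup selection (APOBEC-mutated samples only, or the lowest quartile
of a gene's expression). Correlations are Pearson throughout; a Spearman
option exists for sensitivity analyses but is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ZERO_POLICIES = ("offset1", "half_min", "drop")


def log10_with_zero_policy(
    values: Sequence[float], policy: str = "offset1"
) -> tuple[np.ndarray, np.ndarray]:
    """log10-transform non-negative values under an explicit zero policy.

    Policies: ``offset1`` -> log10(x + 1); ``half_min`` -> zeros replaced by
    half the smallest positive value before log10; ``drop`` -> zeros removed.
    Returns ``(transformed, kept_indices)``; the index map is the identity
    except under ``drop``.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("values must be non-negative for log10 transformation")
    if policy == "offset1":
        return np.log10(x + 1.0), np.arange(x.size)
    if policy == "half_min":
        pos = x[x > 0]
        if pos.size == 0:
            raise ValueError("half_min policy requires at least one positive value")
        y = np.where(x == 0, pos.min() / 2.0, x)
        return np.log10(y), np.arange(x.size)
    if policy == "drop":
        keep = np.nonzero(x > 0)[0]
        return np.log10(x[keep]), keep
    raise ValueError(f"unknown zero policy {policy!r}; expected one of {ZERO_POLICIES}")


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Sample Pearson correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; correlation undefined")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def spearman(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Spearman rank correlation (sensitivity-analysis alternative)."""
    res = stats.spearmanr(x, y)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], exact_max_n: int = 12
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the tie-corrected
    normal approximation with continuity correction. Returns (U, p) with U
    the statistic for the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def median_fold(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """median(a) / median(b); the fold-difference the groups' medians show."""
    med_b = float(np.median(np.asarray(group_b, dtype=float)))
    if med_b <= 0:
        raise ValueError("median of the reference group must be positive for a fold-difference")
    return float(np.median(np.asarray(group_a, dtype=float))) / med_b


def build_sample_table(
    expression: pd.DataFrame,
    enrichment: pd.DataFrame,
    on: str = "sample_id",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Inner-join expression and enrichment tables on the sample key.

    Returns the joined table plus a join report (rows in each input, rows
    joined, rows dropped from each side). Duplicate sample ids are an error.
    """
    for name, df in (("expression", expression), ("enrichment", enrichment)):
        if df[on].duplicated().any():
            dups = df.loc[df[on].duplicated(), on].tolist()
            raise ValueError(f"duplicate sample ids in {name} table: {dups[:5]}")
    joined = expression.merge(enrichment, on=on, how="inner")
    report = {
        "n_expression": len(expression),
        "n_enrichment": len(enrichment),
        "n_joined": len(joined),
        "n_dropped_expression": len(expression) - len(joined),
        "n_dropped_enrichment": len(enrichment) - len(joined),
    }
    return joined, report


def subset(table: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Select a sample subgroup.

    Rules: ``"apobec_mutated"`` keeps samples whose ``is_apobec_mutated``
    flag is set; ``"low_quartile:<gene>"`` keeps samples whose expression of
    <gene> is at or below the 25th percentile (linear-interpolation
    percentile; ties kept).
    """
    import warnings

    if rule == "apobec_mutated":
        out = table[table["is_apobec_mutated"].astype(bool)]
    elif rule.startswith("low_quartile:"):
        gene = rule.split(":", 1)[1]
        if gene not in table.columns:
            raise KeyError(f"gene column {gene!r} not in table")
        q25 = float(np.percentile(table[gene].astype(float), 25))
        out = table[table[gene].astype(float) <= q25]
    else:
        raise ValueError(f"unknown subset rule {rule!r}")
    if out.empty:
        warnings.warn(f"subset rule {rule!r} selected no samples")
    return out.reset_index(drop=True)


def correlate_expression_mutation(
    table: pd.DataFrame,
    gene: str,
    load_column: str = "min_estimate",
    zero_policy: str = "offset1",
) -> PearsonResult:
    """Pearson correlation of log10 expression against log10 mutation load.

    Both axes pass through :func:`log10_with_zero_policy`; under ``drop``
    a sample removed on either axis is removed from both.
    """
    x, keep_x = log10_with_zero_policy(table[gene].astype(float).to_numpy(), zero_policy)
    y, keep_y = log10_with_zero_policy(table[load_column].astype(float).to_numpy(), zero_policy)
    if zero_policy == "drop":
        keep = np.intersect1d(keep_x, keep_y)
        pos_x = {v: i for i, v in enumerate(keep_x)}
        pos_y = {v: i for i, v in enumerate(keep_y)}
        x = x[[pos_x[k] for k in keep]]
        y = y[[pos_y[k] for k in keep]]
    return pearson(x, y)
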