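"""Cohort-level nonparametric statistics: Spearman age trends,
Kruskal–Wallis cross-tissue comparisons, and median/IQR summaries.

These are the study's inference layer over the phenotyping tables.  The
conventions are fixed and recorded in each result's ``method`` field:
Spearman's rho on midranks with the two-sided asymptotic p-value;
Kruskal–Wallis H with tie correction and the chi-square approximation on
(#groups − 1) degrees of freedom; percentiles by linear interpolation.
No multiple-testing correction is applied by default (results are judged at
p < 0.05 marginally); Benjamini–Hochberg can be switched on per table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (DegenerateDataError, InsufficientDataError,
                         ValidationError)

SPEARMAN_METHOD = "spearman_midranks_asymptotic_two_sided"
KRUSKAL_METHOD = "kruskal_wallis_tie_corrected_chi2"
PERCENTILE_METHOD = "linear_interpolation"


@dataclass(frozen=True)
class TrendResult:
    """Spearman correlation of a quantity against age for one grouping."""

    grouping: tuple
    rho: float
    p_value: float
    n: int
    method: str = SPEARMAN_METHOD


@dataclass(frozen=True)
class GroupComparisonResult:
    """Kruskal–Wallis comparison of one quantity across groups."""

    groups: tuple
    H: float
    p_value: float
    group_sizes: tuple[int, ...]
    method: str = KRUSKAL_METHOD


def spearman_trend(pairs: Iterable[tuple[float, float]],
                   grouping: tuple = ()) -> TrendResult:
    """Spearman rank correlation over (age, value) pairs.

    Requires n >= 3 finite pairs; a constant vector has no defined rank
    correlation and raises :class:`DegenerateDataError`.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be (age, value) tuples")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("ages and values must be finite")
    n = arr.shape[0]
    if n < 3:
        raise InsufficientDataError(
            f"Spearman correlation needs n >= 3 pairs, got {n}")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError(
            "rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return TrendResult(grouping=tuple(grouping), rho=float(rho),
                       p_value=float(p), n=n)


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   labels: Sequence = ()) -> GroupComparisonResult:
    """Kruskal–Wallis H test across two or more groups of values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("Kruskal–Wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("every group must be non-empty")
    if sum(g.size for g in groups) < 3:
        raise InsufficientDataError("Kruskal–Wallis needs total n >= 3")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        raise DegenerateDataError(
            "all values identical: rank test is degenerate")
    h, p = stats.kruskal(*groups)
    return GroupComparisonResult(
        groups=tuple(labels) if len(labels) else tuple(range(len(groups))),
        H=float(h), p_value=float(p),
        group_sizes=tuple(g.size for g in groups))


def median_iqr(values: Iterable[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear percentile interpolation."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("median/IQR undefined for empty input")
    med, q1, q3 = np.percentile(arr, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# table-level drivers over CohortTable output
# ---------------------------------------------------------------------------

def subset_age_trends(cohort: pd.DataFrame, value_col: str = "frequency",
                      bh_correct: bool = False) -> pd.DataFrame:
    """Spearman rho of ``value_col`` vs donor age, per
    (tissue, compartment, subset).

    Groups with fewer than 3 donors or a constant value vector are skipped.
    With ``bh_correct`` a Benjamini–Hochberg adjusted p column is appended.
    """
    rows = []
    for (tissue, compartment, subset), grp in cohort.groupby(
            ["tissue", "compartment", "subset"], observed=True):
        try:
            res = spearman_trend(
                zip(grp["age_years"], grp[value_col]),
                grouping=(tissue, compartment, subset))
        except (InsufficientDataError, DegenerateDataError):
            continue
        rows.append({"tissue": tissue, "compartment": compartment,
                     "subset": subset, "rho": res.rho, "p_value": res.p_value,
                     "n": res.n, "method": res.method})
    out = pd.DataFrame(rows)
    if bh_correct and not out.empty:
        from statsmodels.stats.multitest import multipletests
        out["p_adj_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def tissue_comparisons(table: pd.DataFrame, value_col: str,
                       group_col: str = "tissue",
                       by: Sequence[str] = ("compartment", "subset")
                       ) -> pd.DataFrame:
    """Kruskal–Wallis comparison of ``value_col`` across ``group_col``
    levels, separately for each combination of ``by`` columns."""
    rows = []
    for keys, grp in table.groupby(list(by), observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        chunks = [g[value_col].to_numpy()
                  for _, g in grp.groupby(group_col, observed=True)]
        labels = [lvl for lvl, _ in grp.groupby(group_col, observed=True)]
        if len(chunks) < 2:
            continue
        try:
            res = kruskal_wallis(chunks, labels=labels)
        except (DegenerateDataError, InsufficientDataError):
            continue
        row = dict(zip(by, keys))
        row.update({"groups": ";".join(map(str, res.groups)),
                    "H": res.H, "p_value": res.p_value,
                    "group_sizes": ";".join(map(str, res.group_sizes)),
                    "method": res.method})
        rows.append(row)
    return pd.DataFrame(rows)
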