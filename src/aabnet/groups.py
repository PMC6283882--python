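"""Per-analyte two-group comparisons (Mann-Whitney U, median/IQR).

The U statistic reported here counts (x, y) pairs in which the x observation
precedes (is smaller than) the y observation, ties counted 1/2, so that
U(x, y) + U(y, x) = n1 * n2 always.  Exact p-values are used when both
samples have n <= 8 and no ties; otherwise a tie-corrected normal
approximation with continuity correction.

Panel-level summaries report both raw and Benjamini-Hochberg adjusted
p-values: the source analyses report raw p <= 0.05 over panels of ten or
more analytes, so multiplicity is made explicit rather than silent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable

_METHODS = {"exact": "exact", "normal-approx": "asymptotic", "auto": "auto"}


@dataclass
class GroupTestResult:
    analyte: str
    u_stat: float
    p_raw: float
    p_adj: float
    direction: str  # increased | decreased | unchanged (comparator vs reference)
    median_iqr: dict[str, tuple[float, float, float]]  # group -> (median, Q1, Q3)
    n: dict[str, int]


def mann_whitney_u(
    x,
    y,
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test of two independent samples.

    Returns (U, p) with U = #{(i, j): x_i < y_j} + 1/2 #{ties}.
    ``alternative="less"`` tests whether x is stochastically smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}")
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=_METHODS[method])
    # scipy's statistic counts pairs with x > y (+ half ties); complement it
    u = x.size * y.size - float(res.statistic)
    return u, float(min(res.pvalue, 1.0))


def _median_iqr(v: np.ndarray) -> tuple[float, float, float]:
    return (float(np.median(v)), float(np.percentile(v, 25)), float(np.percentile(v, 75)))


def compare_panel(
    table: CohortTable,
    reference: str,
    comparator: str,
    alpha: float = 0.05,
    method: str = "auto",
) -> list[GroupTestResult]:
    """Test every analyte between two groups with BH adjustment across the
    panel.  Direction is the comparator's median relative to the reference,
    declared only when the adjusted p-value clears ``alpha``."""
    for g in (reference, comparator):
        if g not in set(table.meta["group"]):
            raise ValueError(f"group {g!r} not present")
        if (table.meta["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    results: list[GroupTestResult] = []
    p_raws = []
    for analyte in table.analytes:
        ref = table.group_values(reference, analyte).dropna().to_numpy()
        cmp_ = table.group_values(comparator, analyte).dropna().to_numpy()
        u, p = mann_whitney_u(ref, cmp_, alternative="two-sided", method=method)
        results.append(
            GroupTestResult(
                analyte=analyte,
                u_stat=u,
                p_raw=p,
                p_adj=np.nan,
                direction="unchanged",
                median_iqr={reference: _median_iqr(ref), comparator: _median_iqr(cmp_)},
                n={reference: ref.size, comparator: cmp_.size},
            )
        )
        p_raws.append(p)
    _, p_adj, _, _ = multipletests(p_raws, method="fdr_bh")
    for r, pa in zip(results, p_adj):
        r.p_adj = float(pa)
        if pa <= alpha:
            med_ref = r.median_iqr[reference][0]
            med_cmp = r.median_iqr[comparator][0]
            if med_cmp > med_ref:
                r.direction = "increased"
            elif med_cmp < med_ref:
                r.direction = "decreased"
    return results


def panel_summary(results: list[GroupTestResult]) -> dict[str, int]:
    """Counts of increased / decreased / unchanged analytes."""
    counts = {"increased": 0, "decreased": 0, "unchanged": 0}
    for r in results:
        counts[r.direction] += 1
    return counts


def results_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    """Tidy one-row-per-analyte frame for CSV export."""
    rows = []
    for r in results:
        row = {"analyte": r.analyte, "u_stat": r.u_stat, "p_raw": r.p_raw,
               "p_adj": r.p_adj, "direction": r.direction}
        for g, (med, q1, q3) in r.median_iqr.items():
            row[f"median_{g}"] = med
            row[f"q1_{g}"] = q1
            row[f"q3_{g}"] = q3
            row[f"n_{g}"] = r.n[g]
        rows.append(row)
    return pd.DataFrame(rows)
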