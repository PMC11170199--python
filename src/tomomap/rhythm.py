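"""Heart-rate comparison statistics for knockout phenotyping.

Per-embryo beats-per-minute samples are compared between a knockout
arm and each control arm (uninjected; scrambled-injected).  A
Shapiro–Wilk gate justifies the nonparametric path; group comparisons
use the two-sided Wilcoxon rank-sum test; the family of comparisons in
one run is corrected with the Holm–Bonferroni step-down procedure.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ranksum import rank_sum_test

__all__ = ["normality_gate", "compare_groups", "adjust_holm",
           "heart_rate_comparisons", "GroupComparison"]


class GroupComparison(NamedTuple):
    statistic: float
    p_value: float
    median_difference: float


def normality_gate(values) -> float:
    """Shapiro–Wilk p-value; p < 0.05 routes to the nonparametric path.

    Requires n >= 3.  A constant sample is maximally non-normal: p is
    reported as 0 with a degeneracy warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(values) == 0:
        warnings.warn("constant sample: Shapiro-Wilk is degenerate, "
                      "reporting p = 0", stacklevel=2)
        return 0.0
    return float(stats.shapiro(values).pvalue)


def compare_groups(a, b) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two bpm samples.

    Exact for min(n) <= 6, tie-corrected normal approximation
    otherwise.  ``median_difference`` is median(b) - median(a), i.e.
    the shift of the second group relative to the first.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    stat, p = rank_sum_test(a, b)
    return GroupComparison(stat, p, float(np.median(b) - np.median(a)))


def adjust_holm(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def heart_rate_comparisons(table: pd.DataFrame,
                           test_groups: Sequence[str] | None = None,
                           control_groups: Sequence[str] | None = None,
                           ) -> pd.DataFrame:
    """Compare each test (knockout) arm with each control arm.

    ``table`` needs columns ``group`` and ``bpm``.  By default, groups
    whose name starts with ``control`` are the control arms and the
    remaining groups the test arms.  One Holm family spans all
    comparisons of the run.  Returns one row per comparison with group
    sizes, Shapiro–Wilk gate p-values, rank-sum statistic, raw and
    Holm-adjusted p, and the median bpm difference (test - control).
    """
    groups = {g: table.loc[table["group"] == g, "bpm"].to_numpy(dtype=float)
              for g in pd.unique(table["group"])}
    if control_groups is None:
        control_groups = [g for g in groups if str(g).startswith("control")]
    if test_groups is None:
        test_groups = [g for g in groups if g not in set(control_groups)]
    if not control_groups or not test_groups:
        raise ValueError("need at least one control and one test group")
    rows = []
    for t in test_groups:
        for c in control_groups:
            a, b = groups[c], groups[t]
            if min(a.size, b.size) < 2:
                raise ValueError(f"groups {c!r} vs {t!r} too small to test")
            res = compare_groups(a, b)
            rows.append({
                "comparison": f"{t}_vs_{c}",
                "n_control": a.size, "n_test": b.size,
                "shapiro_p_control": normality_gate(a) if a.size >= 3 else np.nan,
                "shapiro_p_test": normality_gate(b) if b.size >= 3 else np.nan,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "median_diff": res.median_difference,
            })
    out = pd.DataFrame(rows)
    out["p_holm"] = adjust_holm(out["p_value"].to_numpy())
    return out
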