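"""Baseline-comparison tables: group summaries and two-group tests.

Continuous variables are compared with Welch's unequal-variance t-test and
summarized both as mean (SD) and median (IQR); categorical variables with
Pearson's chi-squared, or Fisher's exact test when a 2x2 table has any
expected cell below five. The test actually used for each variable is
recorded in the output rather than guessed, and no multiplicity adjustment
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonTable",
    "welch_t",
    "fisher_exact_2x2",
    "categorical_test",
    "build_comparison_table",
]


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: ``(statistic, dof, p)``.

    Degrees of freedom by Welch-Satterthwaite; two-sided p. Each sample
    needs n >= 2, and at least one must have nonzero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t requires n >= 2 in each sample")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("welch_t undefined: zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table: ``(odds_ratio, p)``.

    Two-sided by the point-probability rule: the p-value sums the
    hypergeometric probabilities of every table (margins fixed) no more
    likely than the observed one.
    """
    orr, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(orr), float(p)


def categorical_test(table) -> tuple[str, float, float]:
    """Two-group categorical test on a 2xk contingency table.

    Returns ``(test_name, statistic, p)`` where the statistic is the odds
    ratio for Fisher's exact test and the chi-squared statistic otherwise.
    Fisher (two-sided by the point-probability rule) is used when the table
    is 2x2 and any expected count is below 5; Pearson chi-squared without
    continuity correction otherwise.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("expected a 2xk contingency table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an all-zero margin")
    expected = stats.contingency.expected_freq(t)
    if t.shape == (2, 2) and (expected < 5).any():
        orr, p = fisher_exact_2x2(t)
        return "fisher_exact", orr, p
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return "chi_squared", float(chi2), float(p)


@dataclass
class ComparisonTable:
    """Tidy comparison table plus the group definition it was built under."""

    frame: pd.DataFrame
    group_col: str
    group_labels: tuple[str, str]

    def render(self) -> str:
        g1, g2 = self.group_labels
        w = max(24, int(self.frame["variable"].str.len().max()) + 2)
        lines = [
            f"{'variable':<{w}} {g1:>24} {g2:>24} {'test':>14} {'p':>8}"
        ]
        for r in self.frame.itertuples(index=False):
            p = f"{r.p_value:8.4f}" if np.isfinite(r.p_value) else f"{'':>8}"
            lines.append(
                f"{r.variable:<{w}} {r.group1:>24} {r.group2:>24} "
                f"{r.test:>14} {p}"
            )
        return "\n".join(lines)


def _cont_summary(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{x.mean():.2f} ({x.std(ddof=1):.2f}); {med:.2f} ({q1:.2f}-{q3:.2f})"


def build_comparison_table(
    cohort: pd.DataFrame,
    group_col: str,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> ComparisonTable:
    """Summarize and test every variable between the two groups defined by
    the binary column ``group_col``.

    Continuous rows show ``mean (SD); median (IQR)`` per group with a Welch
    p-value; categorical variables get one row per level showing
    ``count (%)`` and a single variable-level chi-squared/Fisher p-value
    attached to the first level's row.
    """
    groups = sorted(cohort[group_col].dropna().unique(), key=str)
    if len(groups) != 2:
        raise ValueError(f"{group_col} must define exactly two groups, got {groups}")
    g1 = cohort[cohort[group_col] == groups[0]]
    g2 = cohort[cohort[group_col] == groups[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both comparison groups must be non-empty")

    continuous = continuous or []
    categorical = categorical or []
    rows = []
    rows.append(
        {
            "variable": "n",
            "group1": str(len(g1)),
            "group2": str(len(g2)),
            "test": "",
            "p_value": np.nan,
        }
    )
    for var in continuous:
        a = g1[var].dropna().to_numpy(dtype=float)
        b = g2[var].dropna().to_numpy(dtype=float)
        stat, dof, p = welch_t(a, b)
        rows.append(
            {
                "variable": var,
                "group1": _cont_summary(a),
                "group2": _cont_summary(b),
                "test": "welch_t",
                "p_value": p,
            }
        )
    for var in categorical:
        levels = sorted(cohort[var].dropna().unique(), key=str)
        counts = np.array(
            [
                [(g[var] == lev).sum() for lev in levels]
                for g in (g1, g2)
            ]
        )
        if counts.shape[1] >= 2:
            test, _, p = categorical_test(counts)
        else:  # single level: no variation to test
            test, p = "", np.nan
        for j, lev in enumerate(levels):
            rows.append(
                {
                    "variable": f"{var} = {lev}",
                    "group1": f"{counts[0, j]} ({100 * counts[0, j] / len(g1):.1f}%)",
                    "group2": f"{counts[1, j]} ({100 * counts[1, j] / len(g2):.1f}%)",
                    "test": test if j == 0 else "",
                    "p_value": p if j == 0 else np.nan,
                }
            )
    frame = pd.DataFrame(rows)
    return ComparisonTable(
        frame=frame, group_col=group_col, group_labels=(str(groups[0]), str(groups[1]))
    )
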