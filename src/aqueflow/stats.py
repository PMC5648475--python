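"""Nonparametric group comparison and Tukey box-plot summaries.

The cohort design compares control / iNPH / AD metric distributions with
two-sample Mann-Whitney U and Kolmogorov-Smirnov tests, two-sided, without
multiplicity adjustment (the comparisons mirror the study's reporting; both
facts are stamped into the output). Box-plot summaries use Tukey hinges
with 'outside' values beyond 1.5*IQR and 'far-out' values beyond 3*IQR
from the hinges.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

__all__ = [
    "TestResult",
    "BoxplotSummary",
    "mann_whitney_u",
    "ks_two_sample",
    "boxplot_summary",
    "compare_groups",
    "GroupComparison",
    "evaluate_group_pattern",
]

MWU_EXACT_MAX = 20  # exact enumeration when n+m <= 20 and no ties
KS_EXACT_MAX = 16   # exact two-sample KS when n+m <= 16


@dataclass
class TestResult:
    """Two-sided test outcome with the method actually used."""

    test: str        # 'mann-whitney' | 'ks'
    statistic: float
    pvalue: float
    method: str      # 'exact' | 'asymptotic'
    n1: int
    n2: int


def _as_sample(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("sample contains non-finite values")
    return a


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U with midranks for ties.

    Exact p by enumeration of the U null distribution when n+m <= 20 and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    and continuity corrections. The reported statistic is U of ``x``
    (U_x + U_y = n*m).
    """
    x, y = _as_sample(x), _as_sample(y)
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if n + m <= MWU_EXACT_MAX and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method={"exact": "exact", "asymptotic": "asymptotic"}[method],
    )
    return TestResult(
        test="mann-whitney", statistic=float(res.statistic),
        pvalue=float(res.pvalue), method=method, n1=n, n2=m,
    )


def ks_two_sample(x, y) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_x - ECDF_y|; exact null distribution when n+m <= 16,
    otherwise the asymptotic Kolmogorov distribution at effective sample
    size n*m/(n+m).
    """
    x, y = _as_sample(x), _as_sample(y)
    n, m = x.size, y.size
    if n + m <= KS_EXACT_MAX:
        import warnings

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sps.ks_2samp(x, y, alternative="two-sided", method="exact")
        # scipy falls back to the asymptotic formula in rare degenerate
        # configurations; report the method actually used
        fell_back = any("asymp" in str(w.message) for w in caught)
        return TestResult(
            test="ks", statistic=float(res.statistic), pvalue=float(res.pvalue),
            method="asymptotic" if fell_back else "exact", n1=n, n2=m,
        )
    d = float(sps.ks_2samp(x, y, alternative="two-sided", method="asymp").statistic)
    en = n * m / (n + m)
    p = float(np.clip(special.kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    return TestResult(test="ks", statistic=d, pvalue=p, method="asymptotic", n1=n, n2=m)


@dataclass
class BoxplotSummary:
    """Tukey five-number summary with outside / far-out classification.

    Hinges are medians of the data halves (including the median itself for
    odd n). 'outside' points lie beyond hinge +/- 1.5*IQR but within 3*IQR;
    'far-out' points lie beyond 3*IQR and are not double-counted as outside.
    Whiskers extend to the most extreme data inside the inner fences.
    """

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outside: np.ndarray = field(default_factory=lambda: np.array([]))
    far_out: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _tukey_hinges(sorted_x: np.ndarray) -> tuple[float, float]:
    n = sorted_x.size
    half = (n + 1) // 2
    lower = sorted_x[:half]
    upper = sorted_x[n - half:]
    return float(np.median(lower)), float(np.median(upper))


def boxplot_summary(x) -> BoxplotSummary:
    """Summarize a sample the way the study's box plots are drawn."""
    x = np.sort(_as_sample(x))
    q1, q3 = _tukey_hinges(x)
    iqr = q3 - q1
    inner_lo, inner_hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outer_lo, outer_hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    inside = x[(x >= inner_lo) & (x <= inner_hi)]
    far_out = x[(x < outer_lo) | (x > outer_hi)]
    outside = x[((x < inner_lo) | (x > inner_hi)) & (x >= outer_lo) & (x <= outer_hi)]
    return BoxplotSummary(
        n=x.size,
        median=float(np.median(x)),
        q1=q1, q3=q3,
        whisker_low=float(inside.min()) if inside.size else q1,
        whisker_high=float(inside.max()) if inside.size else q3,
        outside=outside,
        far_out=far_out,
    )


@dataclass
class GroupComparison:
    """All pairwise tests and per-group summaries for one metric."""

    metric: str
    pairwise: dict[tuple[str, str], dict[str, TestResult]]
    summaries: dict[str, BoxplotSummary]
    notes: dict = field(default_factory=lambda: {
        "sided": "two-sided",
        "multiplicity_adjustment": "none",
    })

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), tests in self.pairwise.items():
            for name, t in tests.items():
                rows.append(dict(
                    metric=self.metric, group_a=a, group_b=b, test=name,
                    statistic=t.statistic, pvalue=t.pvalue, method=t.method,
                    n_a=t.n1, n_b=t.n2,
                ))
        return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame, metric: str, group_col: str = "group"
) -> GroupComparison:
    """Pairwise MWU + KS tests and box-plot summaries for one metric column.

    Requires at least two groups with at least one subject each; the study
    design has three (control, iNPH, AD), giving three pairwise comparisons.
    """
    if metric not in table.columns:
        raise KeyError(f"metric column {metric!r} not in table")
    groups = {g: sub[metric].to_numpy() for g, sub in table.groupby(group_col, sort=False)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    pairwise: dict[tuple[str, str], dict[str, TestResult]] = {}
    for a, b in combinations(groups, 2):
        pairwise[(a, b)] = {
            "mann-whitney": mann_whitney_u(groups[a], groups[b]),
            "ks": ks_two_sample(groups[a], groups[b]),
        }
    summaries = {g: boxplot_summary(v) for g, v in groups.items()}
    return GroupComparison(metric=metric, pairwise=pairwise, summaries=summaries)


def _pair_p(comp: GroupComparison, a: str, b: str) -> dict[str, float]:
    for (x, y), tests in comp.pairwise.items():
        if {x, y} == {a, b}:
            return {name: t.pvalue for name, t in tests.items()}
    raise KeyError(f"no comparison between {a} and {b}")


def evaluate_group_pattern(
    comparisons: dict[str, GroupComparison],
    control: str = "control",
    patients: tuple[str, str] = ("iNPH", "AD"),
    alpha: float = 0.05,
) -> dict:
    """Check whether a cohort reproduces the study's qualitative pattern.

    The pattern: pressure gradient and rotation separate each patient group
    from controls, velocity separates none of them. A pairwise difference is
    *claimed* only when both reported tests (Mann-Whitney and KS) fall below
    ``alpha`` — the conservative agreement rule for a study that reports two
    tests side by side.
    """
    def significant(metric: str, a: str, b: str) -> bool:
        ps = _pair_p(comparisons[metric], a, b)
        return all(p < alpha for p in ps.values())

    flags = {
        "pressure_gradient_separates_patients": all(
            significant("pressure_gradient", p, control) for p in patients
        ),
        "rotation_separates_patients": all(
            significant("rotation", p, control) for p in patients
        ),
        "velocity_separates_no_patient_group": not any(
            significant("velocity", p, control) for p in patients
        ),
    }
    flags["matches_study_pattern"] = all(flags.values())
    return flags


def plot_boxplots(
    table: pd.DataFrame, metric: str, group_col: str = "group", ax=None
):
    """Simple Tukey box plot per group (optional; requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    groups = list(dict.fromkeys(table[group_col]))
    data = [table.loc[table[group_col] == g, metric] for g in groups]
    ax.boxplot(data, tick_labels=groups, whis=1.5)
    ax.set_ylabel(metric)
    return ax
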