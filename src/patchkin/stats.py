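"""Group summaries and hypothesis tests for cohort comparisons.

Two-group comparisons use the classical pooled-variance unpaired two-tailed
t-test (Welch available behind a flag); three or more groups get a one-way
ANOVA omnibus F followed by Bonferroni-adjusted pairwise t-tests (raw p
multiplied by the number of pairs, capped at 1).  Significance stars follow
the usual convention: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "significance_stars",
    "ttest_unpaired_twotailed",
    "anova_bonferroni",
    "cohort_report",
    "render_report",
]


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float | None  # undefined at n = 1
    unit: str = ""

    @classmethod
    def from_values(cls, label: str, values, unit: str = "") -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size < 1:
            raise ValueError("group needs at least one value")
        sd = float(v.std(ddof=1)) if v.size > 1 else None
        return cls(label, int(v.size), float(v.mean()), sd, unit)


@dataclass(frozen=True)
class ComparisonResult:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    stars: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.p_adjusted < self.p_raw - 1e-15:
            raise ValueError("adjusted p must be >= raw p")


def ttest_unpaired_twotailed(
    a, b, labels: tuple[str, str] = ("a", "b"), welch: bool = False
) -> ComparisonResult:
    """Classical unpaired two-tailed t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return ComparisonResult(labels, 0.0, 1.0, 1.0, "ns", degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(p):
        t, p = 0.0, 1.0
    return ComparisonResult(labels, t, p, p, significance_stars(p))


def anova_bonferroni(
    groups: dict[str, np.ndarray], welch: bool = False
) -> tuple[float, float, list[ComparisonResult]]:
    """One-way ANOVA omnibus test plus Bonferroni-adjusted pairwise t-tests.

    Returns
    -------
    (F, p_omnibus, pairwise) where each pairwise adjusted p is
    min(1, m * raw p) for m = C(k, 2) comparisons.
    """
    if len(groups) < 3:
        raise ValueError("ANOVA path expects >= 3 groups; use the t-test for two")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least two values")
    degenerate = all(v.std(ddof=1) == 0 for v in arrays.values())
    if degenerate and len({float(v.mean()) for v in arrays.values()}) == 1:
        pairs = [
            ComparisonResult((x, y), 0.0, 1.0, 1.0, "ns", degenerate=True)
            for x, y in combinations(arrays, 2)
        ]
        return 0.0, 1.0, pairs
    F, p_omni = sps.f_oneway(*arrays.values())
    m = len(list(combinations(arrays, 2)))
    pairs = []
    for x, y in combinations(arrays, 2):
        r = ttest_unpaired_twotailed(arrays[x], arrays[y], (x, y), welch=welch)
        p_adj = min(1.0, m * r.p_raw)
        pairs.append(
            ComparisonResult((x, y), r.statistic, r.p_raw, p_adj, significance_stars(p_adj),
                             degenerate=r.degenerate)
        )
    return float(F), float(p_omni), pairs


def cohort_report(
    metrics: pd.DataFrame,
    group_col: str = "variant",
    value_col: str = "po",
    unit: str = "",
    reference: str | None = None,
    welch: bool = False,
) -> dict:
    """Summarise a tidy metrics table: group means +/- SD, comparisons, stars.

    Two groups produce one t-test row; three or more produce the ANOVA +
    Bonferroni pairwise table.  ``reference`` additionally reports fold
    changes of each group mean relative to the reference group mean.
    """
    if group_col not in metrics or value_col not in metrics:
        raise KeyError(f"metrics table needs columns {group_col!r} and {value_col!r}")
    groups = {
        str(g): df[value_col].to_numpy() for g, df in metrics.groupby(group_col, sort=False)
    }
    if reference is not None and reference not in groups:
        raise KeyError(f"unknown group label {reference!r}")
    summaries = [GroupSummary.from_values(g, v, unit) for g, v in groups.items()]
    comparisons: list[ComparisonResult] = []
    omnibus = None
    if len(groups) == 2:
        (la, va), (lb, vb) = groups.items()
        comparisons = [ttest_unpaired_twotailed(va, vb, (la, lb), welch=welch)]
    elif len(groups) >= 3:
        F, p, comparisons = anova_bonferroni(groups, welch=welch)
        omnibus = {"F": F, "p": p}
    folds = None
    if reference is not None:
        ref_mean = groups[reference].mean()
        folds = {g: float(v.mean() / ref_mean) for g, v in groups.items() if g != reference}
    return {
        "summaries": summaries,
        "comparisons": comparisons,
        "omnibus": omnibus,
        "fold_vs_reference": folds,
    }


def render_report(report: dict) -> str:
    """Markdown rendering of a cohort report."""
    lines = ["| group | n | mean | sd |", "|---|---|---|---|"]
    for s in report["summaries"]:
        sd = "-" if s.sd is None else f"{s.sd:.4g}"
        lines.append(f"| {s.label} | {s.n} | {s.mean:.4g} | {sd} |")
    if report["omnibus"]:
        o = report["omnibus"]
        lines += ["", f"One-way ANOVA: F = {o['F']:.4g}, p = {o['p']:.3g}"]
    if report["comparisons"]:
        lines += ["", "| pair | t | p raw | p adj | sig |", "|---|---|---|---|---|"]
        for c in report["comparisons"]:
            lines.append(
                f"| {c.pair[0]} vs {c.pair[1]} | {c.statistic:.3g} | "
                f"{c.p_raw:.3g} | {c.p_adjusted:.3g} | {c.stars} |"
            )
    if report["fold_vs_reference"]:
        lines += ["", "| group | fold vs reference |", "|---|---|"]
        for g, f in report["fold_vs_reference"].items():
            lines.append(f"| {g} | {f:.3g} |")
    return "\n".join(lines)
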