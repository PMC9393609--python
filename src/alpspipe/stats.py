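"""Group-comparison and correlation statistics for ALPS studies.

Implements the statistical layer of a two-group observational comparison:
pooled-variance (Student) two-sample t-tests — computable either from raw
samples or directly from printed summary statistics (mean, SD, n), so
published tables can be audited without raw data — chi-square/Fisher tests
for 2x2 categorical tables, Pearson correlation, and Bonferroni-corrected
comparison tables over the nine fiber-axis diffusivities plus the ALPS
index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TTestResult",
    "CategoricalTestResult",
    "CorrelationResult",
    "GroupComparisonRow",
    "t_test_from_summary",
    "t_test_on_samples",
    "categorical_test",
    "pearson_correlation",
    "bonferroni_threshold",
    "build_comparison_table",
    "comparison_rows_to_frame",
    "summary_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and size of one measure in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    @classmethod
    def of(cls, sample: Sequence[float]) -> "GroupSummary":
        x = np.asarray(sample, dtype=float)
        if x.size < 2:
            raise ValueError(f"sample must have >= 2 values, got {x.size}")
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class CategoricalTestResult:
    p: float
    method: str  # "chi-square" | "fisher"
    statistic: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class GroupComparisonRow:
    measure: str
    group1: GroupSummary
    group2: GroupSummary
    test: TTestResult
    threshold: float
    significant: bool


def t_test_from_summary(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Pooled-variance two-sample Student's t-test from summary statistics.

    df = n1 + n2 - 2, two-tailed p.  Agrees exactly with
    :func:`t_test_on_samples` on any raw samples realising the same
    (mean, sd, n).
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    if sp2 == 0:
        if g1.mean == g2.mean:
            return TTestResult(t=0.0, df=df, p=1.0)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = (g1.mean - g2.mean) / np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def t_test_on_samples(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Pooled Student's t-test on raw samples (each with >= 2 values)."""
    return t_test_from_summary(GroupSummary.of(x), GroupSummary.of(y))


def welch_t_test(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Welch's unequal-variance t-test (Satterthwaite df), for sensitivity
    checks against the pooled default."""
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    if v1 + v2 == 0:
        if g1.mean == g2.mean:
            return TTestResult(t=0.0, df=g1.n + g2.n - 2, p=1.0)
        raise ValueError("zero variance with unequal means: t undefined")
    t = (g1.mean - g2.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def categorical_test(table: Sequence[Sequence[int]]) -> CategoricalTestResult:
    """2x2 association test: Pearson chi-square, Fisher's exact fallback.

    Uses the uncorrected chi-square when every expected count is >= 5,
    otherwise the two-sided Fisher exact test; the method tag records
    which ran.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("table must hold nonnegative integer counts")
        t = t.astype(int)
    if t.sum() < 1:
        raise ValueError("empty table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if np.all(expected >= 5):
        chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
        return CategoricalTestResult(p=float(p), method="chi-square",
                                     statistic=float(chi2))
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return CategoricalTestResult(p=float(p), method="fisher",
                                 statistic=float(odds))


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Sample correlation with two-tailed p on n-2 degrees of freedom.

    Pearson by default (p from t = r*sqrt((n-2)/(1-r^2))); Spearman
    available via ``method="spearman"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 for a correlation, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the samples")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


def build_comparison_table(
    data: pd.DataFrame,
    measures: Sequence[str],
    group_col: str,
    groups: tuple[str, str],
    alpha: float = 0.05,
    m: int | None = None,
    raw_alpha_measures: Sequence[str] = ("alps_index",),
    welch: bool = False,
) -> list[GroupComparisonRow]:
    """One pooled-t comparison row per measure between two groups.

    Measures listed in ``raw_alpha_measures`` (by default the ALPS index)
    are flagged at the raw ``alpha``; the remaining measures — the
    per-axis diffusivities — share a Bonferroni threshold ``alpha / m``,
    with ``m`` defaulting to their count.  ``welch=True`` switches every
    row to Welch's unequal-variance test for sensitivity analyses.
    """
    corrected_measures = [mn for mn in measures if mn not in raw_alpha_measures]
    if m is None:
        m = max(len(corrected_measures), 1)
    corrected = bonferroni_threshold(alpha, m)

    rows = []
    for measure in measures:
        if measure not in data.columns:
            raise KeyError(f"measure {measure!r} missing from the table")
        missing = data.loc[data[measure].isna(), :]
        if len(missing):
            sid = missing.iloc[0].get("subject_id", missing.index[0])
            raise ValueError(f"subject {sid!r} has no value for {measure!r}")
        samples = [
            data.loc[data[group_col] == grp, measure].to_numpy() for grp in groups
        ]
        for grp, s in zip(groups, samples):
            if s.size < 2:
                raise ValueError(f"group {grp!r} has {s.size} subjects (< 2)")
        g1, g2 = GroupSummary.of(samples[0]), GroupSummary.of(samples[1])
        test = welch_t_test(g1, g2) if welch else t_test_from_summary(g1, g2)
        thr = alpha if measure in raw_alpha_measures else corrected
        rows.append(GroupComparisonRow(
            measure=measure, group1=g1, group2=g2, test=test,
            threshold=thr, significant=test.p < thr,
        ))
    return rows


def comparison_rows_to_frame(rows: Sequence[GroupComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a table with 4-decimal p-values alongside raw p."""
    return pd.DataFrame([
        {
            "measure": r.measure,
            "mean1": r.group1.mean, "sd1": r.group1.sd, "n1": r.group1.n,
            "mean2": r.group2.mean, "sd2": r.group2.sd, "n2": r.group2.n,
            "t": r.test.t, "df": r.test.df, "p": r.test.p,
            "p_4dp": round(r.test.p, 4),
            "threshold": r.threshold, "significant": r.significant,
        }
        for r in rows
    ])


def summary_table(
    summaries: pd.DataFrame, alpha: float = 0.05, m: int = 1
) -> pd.DataFrame:
    """Recompute t/df/p from a summary-statistics table.

    Expects columns measure, mean1, sd1, n1, mean2, sd2, n2 (one row per
    measure); returns the same rows with t, df, p and a significance flag
    at ``alpha / m``.
    """
    required = ["measure", "mean1", "sd1", "n1", "mean2", "sd2", "n2"]
    missing = [c for c in required if c not in summaries.columns]
    if missing:
        raise ValueError(f"summary table missing columns {missing}")
    thr = bonferroni_threshold(alpha, m)
    out = []
    for _, row in summaries.iterrows():
        test = t_test_from_summary(
            GroupSummary(row["mean1"], row["sd1"], int(row["n1"])),
            GroupSummary(row["mean2"], row["sd2"], int(row["n2"])),
        )
        out.append({
            "measure": row["measure"],
            **{c: row[c] for c in required[1:]},
            "t": test.t, "df": test.df, "p": test.p,
            "p_4dp": round(test.p, 4), "significant": test.p < thr,
        })
    return pd.DataFrame(out)
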