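"""Group-level inference: repeated-measures ANOVA, Tukey HSD, t-comparisons.

The design is one within-subject factor (Chroma condition, k = 4) with
subject as a blocking factor.  The ANOVA table carries Condition, Subject
and Residual rows in the layout of the study's tables; the decomposition
is computed directly so the Subject sum of squares is available (it is
not part of the usual one-way RM output of stats packages).  No
sphericity correction is applied by default.  Post-hoc pairwise tests use
Tukey's honestly significant difference with the studentized-range
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaTable",
    "PairwiseComparison",
    "CompareResult",
    "to_wide",
    "rm_anova_oneway",
    "rm_anova_f_batch",
    "tukey_hsd",
    "compare_means",
    "inside_on_ratio",
]


@dataclass
class AnovaTable:
    """Source / df / SS / MS / F / p rows of the within-subject ANOVA."""

    conditions: list
    n_subjects: int
    df_cond: int
    df_subj: int
    df_resid: int
    ss_cond: float
    ss_subj: float
    ss_resid: float
    gg_epsilon: "float | None" = None  # set when sphericity-corrected

    @property
    def ms_cond(self) -> float:
        return self.ss_cond / self.df_cond

    @property
    def ms_subj(self) -> float:
        return self.ss_subj / self.df_subj

    @property
    def ms_resid(self) -> float:
        return self.ss_resid / self.df_resid

    @property
    def f_value(self) -> float:
        if self.ms_resid == 0.0:
            # degenerate table: no residual variation
            return 0.0 if self.ss_cond == 0.0 else float("inf")
        return self.ms_cond / self.ms_resid

    @property
    def p_value(self) -> float:
        if self.gg_epsilon is None:
            return float(stats.f.sf(self.f_value, self.df_cond, self.df_resid))
        e = self.gg_epsilon
        return float(stats.f.sf(self.f_value, e * self.df_cond, e * self.df_resid))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Chroma condition", self.df_cond, self.ss_cond, self.ms_cond,
             self.f_value, self.p_value),
            ("Subject", self.df_subj, self.ss_subj, self.ms_subj, np.nan, np.nan),
            ("Residuals", self.df_resid, self.ss_resid, self.ms_resid,
             np.nan, np.nan),
        ]
        return pd.DataFrame(rows, columns=["Source", "Df", "Sum Sq", "Mean Sq",
                                           "F value", "p"])


def to_wide(table) -> tuple:
    """(subjects x conditions) array from a tidy (subject, condition, value)
    frame, validating the complete crossing."""
    if isinstance(table, pd.DataFrame):
        wide = table.pivot(index="subject", columns="condition", values="value")
        if wide.isna().any().any():
            raise ValueError("incomplete crossing: every subject needs exactly "
                             "one value per condition")
        return wide.to_numpy(float), list(wide.columns), list(wide.index)
    arr = np.asarray(table, float)
    if arr.ndim != 2:
        raise ValueError("expected a (subjects x conditions) array")
    return arr, list(range(arr.shape[1])), list(range(arr.shape[0]))


def rm_anova_oneway(table, gg_correction: bool = False) -> AnovaTable:
    """One-way repeated-measures ANOVA.

    Parameters
    ----------
    table
        Tidy frame with columns subject, condition, value, or an
        (n_subjects x k) array.
    gg_correction
        Apply the Greenhouse-Geisser sphericity correction to the F-test
        degrees of freedom (off by default; the table is flagged via
        ``gg_epsilon`` when on).
    """
    arr, conditions, _ = to_wide(table)
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = arr.mean()
    ss_cond = n * float(((arr.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((arr.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((arr - grand) ** 2).sum())
    ss_resid = ss_total - ss_cond - ss_subj

    gg = None
    if gg_correction:
        # Greenhouse-Geisser epsilon from the double-centered covariance
        cov = np.cov(arr, rowvar=False, ddof=1)
        c = cov - cov.mean(axis=0) - cov.mean(axis=1)[:, None] + cov.mean()
        gg = float(np.trace(c) ** 2 / ((k - 1) * np.sum(c * c)))
    return AnovaTable(
        conditions=conditions, n_subjects=n,
        df_cond=k - 1, df_subj=n - 1, df_resid=(k - 1) * (n - 1),
        ss_cond=ss_cond, ss_subj=ss_subj, ss_resid=max(ss_resid, 0.0),
        gg_epsilon=gg,
    )


def rm_anova_f_batch(tables: np.ndarray) -> tuple:
    """Vectorised F and p for a stack of (n x k) tables, shape (m, n, k).

    Used for null-calibration simulations; numerically identical to
    :func:`rm_anova_oneway` applied table by table.
    """
    arr = np.asarray(tables, float)
    m, n, k = arr.shape
    grand = arr.mean(axis=(1, 2), keepdims=True)
    ss_cond = n * ((arr.mean(axis=1, keepdims=True) - grand) ** 2).sum(axis=(1, 2))
    ss_subj = k * ((arr.mean(axis=2, keepdims=True) - grand) ** 2).sum(axis=(1, 2))
    ss_total = ((arr - grand) ** 2).sum(axis=(1, 2))
    ss_resid = ss_total - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_resid / ((k - 1) * (n - 1)))
    p = stats.f.sf(f, k - 1, (k - 1) * (n - 1))
    return f, p


@dataclass
class PairwiseComparison:
    pair: tuple
    mean_difference: float
    q: float
    p_adjusted: float


def tukey_hsd(table, anova: "AnovaTable | None" = None) -> list:
    """All-pairs Tukey HSD on the within-subject design.

    q = |mean_i - mean_j| / sqrt(MS_resid / n), with the residual mean
    square and degrees of freedom of the repeated-measures ANOVA;
    adjusted p from the studentized-range distribution.
    """
    arr, conditions, _ = to_wide(table)
    if anova is None:
        anova = rm_anova_oneway(arr)
    if anova.df_resid < 1:
        raise ValueError("Tukey HSD needs at least 1 residual degree of freedom")
    n, k = arr.shape
    means = arr.mean(axis=0)
    se = np.sqrt(anova.ms_resid / n)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, anova.df_resid))
            out.append(PairwiseComparison(
                pair=(conditions[i], conditions[j]),
                mean_difference=diff, q=float(q),
                p_adjusted=float(np.clip(p, 0.0, 1.0)),
            ))
    return out


@dataclass
class CompareResult:
    t: float
    df: float
    p: float
    mode: str


def compare_means(group_a, group_b, mode: str = "welch") -> CompareResult:
    """Two-sided t comparison of two groups of subject means.

    ``welch`` (default) does not assume equal variances — appropriate for
    the partially overlapping main/control cohorts; ``paired`` compares
    matched values; ``student`` pools variances.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    if mode == "paired":
        if a.size != b.size:
            raise ValueError("paired comparison requires equal group sizes")
        if np.all(a == b):  # no difference anywhere: t = 0, p = 1
            return CompareResult(t=0.0, df=float(a.size - 1), p=1.0, mode=mode)
        res = stats.ttest_rel(a, b)
        df = a.size - 1
    elif mode == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        df = res.df
    elif mode == "student":
        res = stats.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
    else:
        raise ValueError(f"unknown comparison mode {mode!r}")
    return CompareResult(t=float(res.statistic), df=float(df),
                         p=float(res.pvalue), mode=mode)


def inside_on_ratio(inside_values, on_values) -> float:
    """Ratio of condition-averaged response magnitudes inside vs. on the
    patch ring — a plain quotient, not a statistical test."""
    inside = float(np.mean(np.asarray(inside_values, float)))
    on = float(np.mean(np.asarray(on_values, float)))
    return inside / on
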