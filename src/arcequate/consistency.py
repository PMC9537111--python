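"""Consistency (correlation) analysis and demographic group comparison.

Consistency between two score series — either the two scales in the
conversion group, or original vs. converted scores in the validation
group — is measured by correlation.  Both Pearson and Spearman
coefficients are always computed; Spearman (average ranks for ties) is
the primary statistic for bounded integer scores with floor effects,
Pearson the secondary one for comparability with linear-agreement
reports.

Group comparison mirrors the usual baseline table of a two-arm cohort:
chi-square on the 2x2 sex table, and for continuous variables a two-sided
t-test when both samples pass a Shapiro-Wilk normality screen at
alpha = 0.05, otherwise a Mann-Whitney U test (exact p for combined
n <= 20 without ties, normal approximation with continuity correction
otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circle_arc import ConversionTable, apply_conversion
from .errors import InsufficientDataError, UndefinedCorrelationError
from .score_data import Cohort

NORMALITY_ALPHA = 0.05
EXACT_MWU_MAX_N = 20


class CorrelationResult(NamedTuple):
    r_pearson: float
    p_pearson: float
    r_spearman: float
    p_spearman: float


def correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson and Spearman correlation with two-sided p-values.

    Spearman uses average ranks for ties.  Constant vectors have no
    defined correlation and raise :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    pear = stats.pearsonr(x, y)
    spear = stats.spearmanr(x, y)
    return CorrelationResult(
        r_pearson=float(pear.statistic), p_pearson=float(pear.pvalue),
        r_spearman=float(spear.statistic), p_spearman=float(spear.pvalue))


@dataclass
class ConsistencyReport:
    """Correlation plus descriptives for one group's pair of score series."""

    label: str
    n: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    r_pearson: float
    p_pearson: float
    r_spearman: float
    p_spearman: float
    x_name: str = "x"
    y_name: str = "y"

    @classmethod
    def from_series(cls, label: str, x, y, *, x_name: str = "x",
                    y_name: str = "y") -> "ConsistencyReport":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        corr = correlation(x, y)
        return cls(label=label, n=int(x.size),
                   mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
                   mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)),
                   r_pearson=corr.r_pearson, p_pearson=corr.p_pearson,
                   r_spearman=corr.r_spearman, p_spearman=corr.p_spearman,
                   x_name=x_name, y_name=y_name)

    def to_row(self) -> dict:
        return {
            "label": self.label, "n": self.n,
            "x": self.x_name, "y": self.y_name,
            "mean_x": self.mean_x, "sd_x": self.sd_x,
            "mean_y": self.mean_y, "sd_y": self.sd_y,
            "r_pearson": self.r_pearson, "p_pearson": self.p_pearson,
            "r_spearman": self.r_spearman, "p_spearman": self.p_spearman,
        }


def scale_consistency(cohort: Cohort, label: str | None = None) -> ConsistencyReport:
    """Correlate the two scales (MMSE vs MoCA) within one group."""
    return ConsistencyReport.from_series(
        label if label is not None else cohort.label,
        cohort.mmse, cohort.moca, x_name="mmse", y_name="moca")


def validate_conversion(group_b: Cohort, table: ConversionTable,
                        label: str | None = None) -> ConsistencyReport:
    """Correlate original vs. converted target scores in the validation group.

    Each subject's source score is pushed through the conversion table;
    agreement of the converted with the actually observed target score is
    the validation criterion.
    """
    if len(group_b) == 0:
        raise InsufficientDataError("validation group is empty")
    converted = apply_conversion(table, group_b)
    return ConsistencyReport.from_series(
        label if label is not None else group_b.label,
        group_b.moca, converted, x_name="moca", y_name="converted_moca")


@dataclass
class GroupComparisonRow:
    """One baseline-table row: a variable compared between groups A and B."""

    variable: str
    summary_a: str
    summary_b: str
    test: str  # "chi-square" | "t" | "mann-whitney"
    statistic: float
    p_value: float
    rule: str = ""
    notes: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {"variable": self.variable, "group_A": self.summary_a,
                "group_B": self.summary_b, "test": self.test,
                "statistic": self.statistic, "p_value": self.p_value,
                "rule": self.rule}


def _mean_sd(v: np.ndarray) -> str:
    return f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"


def _compare_continuous(name: str, a: np.ndarray, b: np.ndarray) -> GroupComparisonRow:
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"{name}: need n >= 2 per group for a continuous comparison")
    # identical constant samples: no variability, declare perfect agreement
    if np.ptp(np.concatenate([a, b])) == 0:
        return GroupComparisonRow(variable=name, summary_a=_mean_sd(a),
                                  summary_b=_mean_sd(b), test="t",
                                  statistic=0.0, p_value=1.0,
                                  rule="degenerate: all values equal")
    normal_a = a.size >= 3 and np.ptp(a) > 0 and stats.shapiro(a).pvalue > NORMALITY_ALPHA
    normal_b = b.size >= 3 and np.ptp(b) > 0 and stats.shapiro(b).pvalue > NORMALITY_ALPHA
    if normal_a and normal_b:
        res = stats.ttest_ind(a, b)
        return GroupComparisonRow(variable=name, summary_a=_mean_sd(a),
                                  summary_b=_mean_sd(b), test="t",
                                  statistic=float(res.statistic),
                                  p_value=float(res.pvalue),
                                  rule="Shapiro-Wilk p > 0.05 in both groups")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= EXACT_MWU_MAX_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method=method, use_continuity=True)
    return GroupComparisonRow(variable=name, summary_a=_mean_sd(a),
                              summary_b=_mean_sd(b), test="mann-whitney",
                              statistic=float(res.statistic),
                              p_value=float(res.pvalue),
                              rule=f"non-normal by Shapiro-Wilk; {method} p")


def chi_square_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Chi-square test on a 2x2 count table (no Yates correction by default)."""
    res = stats.chi2_contingency(np.asarray(table), correction=yates)
    return float(res.statistic), float(res.pvalue)


def compare_groups(group_a: Cohort, group_b: Cohort,
                   yates: bool = False) -> list[GroupComparisonRow]:
    """Baseline comparison of the two split halves (sex, age, both scales)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise InsufficientDataError("both groups must be nonempty")
    rows: list[GroupComparisonRow] = []

    males_a = sum(r.sex == "male" for r in group_a)
    males_b = sum(r.sex == "male" for r in group_b)
    counts = np.array([[males_a, len(group_a) - males_a],
                       [males_b, len(group_b) - males_b]])
    if counts.sum(axis=0).min() == 0:
        # one sex absent from both groups: no association testable
        stat, p = 0.0, 1.0
        rule = "degenerate: a sex category is empty"
    else:
        stat, p = chi_square_2x2(counts, yates=yates)
        rule = "Yates correction" if yates else "no Yates correction"
    rows.append(GroupComparisonRow(
        variable="sex (male)",
        summary_a=f"{males_a} ({100 * males_a / len(group_a):.1f}%)",
        summary_b=f"{males_b} ({100 * males_b / len(group_b):.1f}%)",
        test="chi-square", statistic=stat, p_value=p, rule=rule))

    ages_a = np.array([r.age for r in group_a], dtype=float)
    ages_b = np.array([r.age for r in group_b], dtype=float)
    rows.append(_compare_continuous("age", ages_a, ages_b))
    rows.append(_compare_continuous("mmse", group_a.mmse.astype(float),
                                    group_b.mmse.astype(float)))
    rows.append(_compare_continuous("moca", group_a.moca.astype(float),
                                    group_b.moca.astype(float)))
    return rows


def reports_to_frame(reports: Sequence[ConsistencyReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])


def comparison_to_frame(rows: Sequence[GroupComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in rows])
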