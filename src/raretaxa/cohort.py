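"""Cohort-level statistics linking colonization status to immune readouts.

Age-stratified prevalence tables, two-group comparisons of sIgA or
relative expression (Student's t by default, Welch and Mann-Whitney a
flag away), fold-change + Benjamini-Hochberg differential selection,
and Shannon diversity of taxon abundance profiles.

A cohort table is a pandas DataFrame with at least the columns
``subject_id``, ``age_months``, ``sfb_status`` ('positive'/'negative');
``siga_ug_ml`` and per-gene Ct columns are optional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_AGE_BINS",
    "GroupComparison",
    "prevalence_table",
    "compare_groups",
    "bh_adjust",
    "select_differential",
    "shannon_index",
]

#: closed-interval age strata in months, matching the published prevalence table
DEFAULT_AGE_BINS = ((0, 36), (37, 72), (73, 108), (109, 181))


def prevalence_table(cohort: pd.DataFrame, bins=DEFAULT_AGE_BINS) -> pd.DataFrame:
    """Colonization prevalence per age stratum.

    Bins are closed intervals in whole months; fractional ages are
    floored to months before binning.  A subject falling in no bin is
    an error; an empty bin reports a missing (NaN) percentage, not 0.
    Percentages are rounded to 2 decimals.
    """
    ages = np.floor(cohort["age_months"].to_numpy(dtype=float)).astype(int)
    if (ages <= 0).any():
        raise ValueError("ages must be > 0 months")
    positive = (cohort["sfb_status"] == "positive").to_numpy()
    assigned = np.full(len(ages), -1)
    for b, (lo, hi) in enumerate(bins):
        inside = (ages >= lo) & (ages <= hi)
        assigned[inside] = b
    if (assigned < 0).any():
        stray = sorted(set(ages[assigned < 0]))
        raise ValueError(f"subjects with ages {stray} fall in no age bin")
    rows = []
    for b, (lo, hi) in enumerate(bins):
        n_total = int((assigned == b).sum())
        n_positive = int(positive[assigned == b].sum())
        rows.append({
            "age_bin": f"{lo}-{hi}",
            "n_total": n_total,
            "n_positive": n_positive,
            "percent_positive": round(100.0 * n_positive / n_total, 2) if n_total else float("nan"),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    statistic: float
    pvalue: float
    test: str

    def __post_init__(self) -> None:
        if not (math.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def compare_groups(values_a, values_b, test: str = "student_t") -> GroupComparison:
    """Two-sided two-group comparison with medians and means reported.

    test: 'student_t' (pooled variance), 'welch_t', or 'mann_whitney'.
    t-tests require >= 2 values per group.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if test in ("student_t", "welch_t"):
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-tests need >= 2 values per group")
        res = stats.ttest_ind(a, b, equal_var=(test == "student_t"))
    elif test == "mann_whitney":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("empty group")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        test=test,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_differential(
    fold_changes: dict[str, float],
    adjusted_p: dict[str, float],
    min_fold: float = 2.0,
    alpha: float = 0.05,
) -> set[str]:
    """Genes with >= min_fold change in either direction and adjusted p < alpha."""
    if set(fold_changes) != set(adjusted_p):
        raise ValueError("fold_changes and adjusted_p must share the same gene keys")
    return {
        g
        for g, fold in fold_changes.items()
        if (fold >= min_fold or fold <= 1.0 / min_fold) and adjusted_p[g] < alpha
    }


def shannon_index(abundances, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log by default).

    Abundances are normalized to proportions; zeros contribute nothing.
    """
    x = np.asarray(list(abundances), dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be >= 0")
    total = x.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h
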