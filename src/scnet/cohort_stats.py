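"""Cohort-level demographic and genotyping statistics.

Hardy-Weinberg equilibrium testing of genotype counts, Fisher's exact test
on gender composition, Wilcoxon-Mann-Whitney rank tests on age/education,
and per-region two-sample t-tests on residualized thickness with
multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of the three genotypes at a biallelic locus (AA, AB, BB)."""

    n_AA: int
    n_AB: int
    n_BB: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_AB, self.n_BB) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.total < 1:
            raise ValueError("need at least one genotyped subject")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_AB + self.n_BB


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions.

    Allele frequencies are estimated from the counts, so the conventional
    test has 1 degree of freedom (3 cells - 1 - 1 estimated allele
    frequency); the 2-df p-value is also reported as a diagnostic because
    published tables sometimes use it.
    """

    chi2: float
    p_df1: float
    p_df2: float
    degenerate: bool

    @property
    def p_value(self) -> float:
        return self.p_df1


def hwe_chisq(counts: GenotypeCounts) -> HWEResult:
    """Uncorrected Pearson chi-square against Hardy-Weinberg proportions.

    Expected counts are n*p^2, 2npq, n*q^2 with p the estimated frequency of
    the A allele.  A monomorphic sample (one allele absent) is degenerate:
    the statistic is 0 by convention and flagged.
    """
    n = counts.total
    n_a = 2 * counts.n_AA + counts.n_AB
    p = n_a / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return HWEResult(chi2=0.0, p_df1=1.0, p_df2=1.0, degenerate=True)
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([counts.n_AA, counts.n_AB, counts.n_BB], float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return HWEResult(
        chi2=chi2,
        p_df1=float(stats.chi2.sf(chi2, df=1)),
        p_df2=float(stats.chi2.sf(chi2, df=2)),
        degenerate=False,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Two-sidedness by the probability-mass rule: sum the hypergeometric
    probabilities of every table with the same margins whose probability
    does not exceed that of the observed table (no mid-p adjustment).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0):
        raise ValueError("table entries must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact enumeration when both samples have n <= 10 and no ties across the
    pooled sample; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (x.size <= 10 and y.size <= 10 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def regional_group_ttests(
    residuals: pd.DataFrame,
    groups,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region two-sided two-sample t-tests between the two groups.

    Parameters
    ----------
    residuals : DataFrame
        Subjects x regions residualized thickness.
    groups : array-like
        Group label per subject (exactly two distinct labels).
    correction : {"bonferroni", "fdr_bh"}
        Multiple-testing correction over the testable regions.

    Returns a table with columns ``t``, ``p_raw``, ``p_adj``, ``sig_raw``,
    ``sig_adj`` and ``undefined`` (regions with zero within-group variance
    are flagged and excluded from the correction count).
    """
    if correction not in ("bonferroni", "fdr_bh"):
        raise ValueError("correction must be 'bonferroni' or 'fdr_bh'")
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    a = residuals.loc[groups == labels[0]].to_numpy(float)
    b = residuals.loc[groups == labels[1]].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0)
    t = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)
    # identical samples give 0/0 -> nan; by convention t=0, p=1 there
    zero_diff = np.isclose(a.mean(axis=0), b.mean(axis=0))
    degenerate = ~np.isfinite(t)
    convert = degenerate & zero_diff
    t[convert], p[convert] = 0.0, 1.0
    undefined = ~np.isfinite(t)

    p_adj = np.full_like(p, np.nan)
    testable = ~undefined
    if testable.any():
        _, adj, _, _ = multipletests(p[testable], alpha=alpha, method=correction)
        p_adj[testable] = adj

    out = pd.DataFrame(
        {
            "t": t,
            "p_raw": p,
            "p_adj": p_adj,
            "sig_raw": (p < alpha) & testable,
            "sig_adj": (p_adj < alpha) & testable,
            "undefined": undefined,
        },
        index=pd.Index(residuals.columns, name="region"),
    )
    return out
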