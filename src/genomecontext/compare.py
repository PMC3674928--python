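"""Statistical comparison of two genomic category distributions.

The global test is the Brandt-Snedecor test for homogeneity of k binomial
distributions, a computational shortcut form of the Pearson chi-square test
of homogeneity on the 2 x k contingency table of foreground and background
category counts:

    chi2 = n^2 / (n1 * n2) * ( sum_i n1i^2 / (n1i + n2i)  -  n1^2 / n )

with n1, n2 the two totals, n = n1 + n2, and n1i, n2i the per-category
counts.  The statistic is referred to a chi-square distribution with
k_eff - 1 degrees of freedom, where k_eff counts categories with a nonzero
combined count (empty categories are dropped).  The statistic is 0 and the
p-value 1 when the two distributions are proportional.

Per-category over/under-representation is assessed with the log-likelihood
G-test for independence on the 2 x 2 table of each category against the
union of the other categories, G = 2 * sum O * ln(O / E), referred to a
chi-square distribution with 1 df.  Raw p-values are Bonferroni-adjusted
over the seven categories, and significance stars are drawn from the
adjusted values.

The test assumes independent observations, a background at least twice the
foreground, and exhaustive, mutually exclusive categories; violations of
the size assumption and small expected counts produce warnings, never
errors.  Overlap of actual observations between the two sets (foreground a
subset of background) is not tested for: counts are compared as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .annotation import CATEGORY_ORDER, Category
from .context import CategoryDistribution

#: p-values below the double-precision floor are reported as this string.
PVALUE_FLOOR = 2.2e-16


@dataclass
class HomogeneityResult:
    """Result of the Brandt-Snedecor homogeneity test."""

    chi2: float
    df: int
    p_value: float
    n1: int
    n2: int
    n: int


@dataclass
class CategoryTestResult:
    """Per-category G-test of one category against the rest."""

    category: Category
    fg_count: int
    bg_count: int
    fg_freq: float
    bg_freq: float
    ratio: float | None
    g_statistic: float
    p_value: float
    p_adjusted: float
    direction: str  # "over" | "under" | "none"
    stars: str


@dataclass
class ComparisonReport:
    homogeneity: HomogeneityResult
    per_category: list
    warnings: list = field(default_factory=list)


def brandt_snedecor_counts(fg_counts, bg_counts) -> HomogeneityResult:
    """Brandt-Snedecor test on two parallel count vectors.

    Categories with zero combined count are dropped before computing the
    effective number of categories.  Raises ``ValueError`` when either
    total is zero or fewer than two categories remain.
    """
    n1i = np.asarray(fg_counts, dtype=float)
    n2i = np.asarray(bg_counts, dtype=float)
    if n1i.shape != n2i.shape:
        raise ValueError("count vectors must have equal length")
    if np.any(n1i < 0) or np.any(n2i < 0):
        raise ValueError("counts must be non-negative")
    n1, n2 = n1i.sum(), n2i.sum()
    if n1 == 0 or n2 == 0:
        raise ValueError("each distribution must have a positive total")
    keep = (n1i + n2i) > 0
    n1i, n2i = n1i[keep], n2i[keep]
    k_eff = int(keep.sum())
    if k_eff < 2:
        raise ValueError("fewer than two non-empty categories; no comparison possible")
    n = n1 + n2
    chi2 = n * n / (n1 * n2) * float((n1i**2 / (n1i + n2i)).sum() - n1 * n1 / n)
    chi2 = max(chi2, 0.0)  # guard tiny negative round-off
    df = k_eff - 1
    p = float(stats.chi2.sf(chi2, df))
    return HomogeneityResult(
        chi2=chi2, df=df, p_value=p, n1=int(n1), n2=int(n2), n=int(n)
    )


def brandt_snedecor(
    fg: CategoryDistribution, bg: CategoryDistribution
) -> HomogeneityResult:
    """Brandt-Snedecor test on two category distributions."""
    return brandt_snedecor_counts(
        [fg.counts[c] for c in CATEGORY_ORDER],
        [bg.counts[c] for c in CATEGORY_ORDER],
    )


def gtest_2x2(table) -> tuple[float, float]:
    """Log-likelihood G-test of independence on a 2 x 2 table.

    Uses the convention 0 * ln(0 / E) = 0; no Williams or Yates correction.
    Returns ``(G, p)`` with p from the chi-square upper tail at 1 df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("need a non-negative 2x2 table")
    n = obs.sum()
    if n == 0:
        return 0.0, 1.0
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    mask = obs > 0
    if np.any(expected[mask] == 0):  # impossible with non-negative margins
        raise ValueError("zero expected count for a nonzero cell")
    g = 2.0 * float((obs[mask] * np.log(obs[mask] / expected[mask])).sum())
    g = max(g, 0.0)
    return g, float(stats.chi2.sf(g, 1))


def significance_stars(p: float) -> str:
    """Star annotation: *** p<0.001, ** p<0.01, * p<0.05, else empty."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def per_category_gtest(
    fg: CategoryDistribution, bg: CategoryDistribution
) -> list[CategoryTestResult]:
    """G-test of each category against the union of the other categories.

    The enrichment ratio is foreground frequency over background frequency,
    undefined (``None``) when the background count is zero.  p-values are
    Bonferroni-adjusted over the seven categories; stars reflect the
    adjusted values.
    """
    n1, n2 = fg.total, bg.total
    if n1 == 0 or n2 == 0:
        raise ValueError("each distribution must have a positive total")
    results = []
    m = len(CATEGORY_ORDER)
    for cat in CATEGORY_ORDER:
        a, b = fg.counts[cat], bg.counts[cat]
        g, p = gtest_2x2([[a, n1 - a], [b, n2 - b]])
        fg_freq, bg_freq = a / n1, b / n2
        ratio = (fg_freq / bg_freq) if b > 0 else None
        if fg_freq > bg_freq:
            direction = "over"
        elif fg_freq < bg_freq:
            direction = "under"
        else:
            direction = "none"
        p_adj = min(1.0, m * p)
        results.append(
            CategoryTestResult(
                category=cat,
                fg_count=a,
                bg_count=b,
                fg_freq=fg_freq,
                bg_freq=bg_freq,
                ratio=ratio,
                g_statistic=g,
                p_value=p,
                p_adjusted=p_adj,
                direction=direction,
                stars=significance_stars(p_adj),
            )
        )
    return results


def check_assumptions(
    fg: CategoryDistribution, bg: CategoryDistribution
) -> list[str]:
    """Warnings for violated test assumptions (never aborts).

    Flags a background smaller than twice the foreground, and expected cell
    counts below 5 in the 2 x k table.
    """
    warnings = []
    n1, n2 = fg.total, bg.total
    if n2 < 2 * n1:
        warnings.append(
            f"background total ({n2}) is less than twice the foreground "
            f"total ({n1}); the homogeneity test assumes n_bg >= 2 * n_fg"
        )
    n = n1 + n2
    if n > 0:
        small = []
        for cat in CATEGORY_ORDER:
            col = fg.counts[cat] + bg.counts[cat]
            if col == 0:
                continue
            if min(n1 * col / n, n2 * col / n) < 5:
                small.append(cat.value)
        if small:
            warnings.append(
                "expected cell count below 5 in category(ies): "
                + ", ".join(small)
                + "; chi-square approximation may be poor"
            )
    return warnings


def compare_distributions(
    fg: CategoryDistribution, bg: CategoryDistribution
) -> ComparisonReport:
    """Full comparison: homogeneity test, per-category G-tests, warnings."""
    return ComparisonReport(
        homogeneity=brandt_snedecor(fg, bg),
        per_category=per_category_gtest(fg, bg),
        warnings=check_assumptions(fg, bg),
    )


def format_pvalue(p: float) -> str:
    """Scientific notation with 4 significant digits; tiny p as '< 2.2e-16'."""
    if p < PVALUE_FLOOR:
        return "< 2.2e-16"
    return f"{p:.3e}"
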