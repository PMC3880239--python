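"""Group-level comparisons of spiking signatures.

Three comparison families mirror the quantities the per-run report
produces: the fraction of actively responding cells per replicate
(two-sample t test when both groups pass a normality screen, otherwise
Wilcoxon-Mann-Whitney), per-cell peak counts across three or more groups
(Kruskal-Wallis with Dunn's pairwise post-hoc), and the distribution of
waiting-time autocorrelation classes (Pearson chi-square on the
group x class contingency table).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "compare_fraction_active",
    "compare_peak_counts",
    "compare_acf_classes",
    "dunn_posthoc",
]

logger = logging.getLogger("caspike")

#: significance level of the Shapiro-Wilk screen used to pick t vs rank test
NORMALITY_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Outcome of one group-level test."""

    test_name: str
    statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    ns: tuple[int, ...]
    post_hoc: dict[tuple[str, str], float] | None = None


def _is_normalish(x: np.ndarray, alpha: float) -> bool:
    # Shapiro-Wilk needs n >= 3 and non-degenerate data; anything it cannot
    # screen is routed to the rank test.
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def compare_fraction_active(
    group_a, group_b, labels: tuple[str, str] = ("A", "B"),
    normality_alpha: float = NORMALITY_ALPHA,
) -> GroupComparison:
    """Compare per-replicate responding fractions between two groups.

    Uses the unpaired Student t test when both groups pass a Shapiro-Wilk
    normality screen, otherwise the Wilcoxon-Mann-Whitney rank-sum test;
    the chosen test is recorded in ``test_name``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if _is_normalish(a, normality_alpha) and _is_normalish(b, normality_alpha):
        res = stats.ttest_ind(a, b, equal_var=True)
        name = "student_t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "wilcoxon_mann_whitney"
    return GroupComparison(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_labels=labels,
        ns=(len(a), len(b)),
    )


def dunn_posthoc(
    groups: list[np.ndarray], labels: tuple[str, ...]
) -> dict[tuple[str, str], float]:
    """Dunn's pairwise rank comparisons with tie correction, Bonferroni
    adjusted.  z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with tie term T = sum(t^3 - t) / (12 (N - 1))."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    pos = 0
    for g in groups:
        mean_ranks.append(ranks[pos:pos + len(g)].mean())
        sizes.append(len(g))
        pos += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = min(2.0 * stats.norm.sf(abs(z)) * m, 1.0)
        out[(labels[i], labels[j])] = float(p)
    return out


def compare_peak_counts(groups, labels: tuple[str, ...] | None = None) -> GroupComparison:
    """Kruskal-Wallis over >= 3 groups of per-cell peak counts, with
    Bonferroni-adjusted Dunn pairwise post-hoc p-values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError(
            "compare_peak_counts needs >= 3 groups; use compare_fraction_active's "
            "two-sample path for a pairwise comparison"
        )
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if labels is None:
        labels = tuple(f"group{i + 1}" for i in range(len(groups)))
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        # all observations tied: no evidence of any difference
        return GroupComparison(
            "kruskal_wallis_dunn_bonferroni", 0.0, 1.0, labels,
            tuple(len(g) for g in groups),
            post_hoc={pair: 1.0 for pair in itertools.combinations(labels, 2)},
        )
    kw = stats.kruskal(*groups)
    return GroupComparison(
        test_name="kruskal_wallis_dunn_bonferroni",
        statistic=float(kw.statistic),
        p_value=float(kw.pvalue),
        group_labels=labels,
        ns=tuple(len(g) for g in groups),
        post_hoc=dunn_posthoc(groups, labels),
    )


def compare_acf_classes(
    counts_a, counts_b, labels: tuple[str, str] = ("A", "B")
) -> GroupComparison:
    """Pearson chi-square on the 2 x 3 (negative, neutral, positive)
    contingency table; classes empty in both groups are dropped first.
    No continuity correction (classic Pearson form)."""
    table = np.array([counts_a, counts_b], dtype=float)
    if table.shape != (2, 3) or np.any(table < 0):
        raise ValueError("expected two (negative, neutral, positive) count triples")
    if table.sum(axis=1).min() <= 0:
        raise ValueError("each group needs a positive total count")
    table = table[:, table.sum(axis=0) > 0]
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if np.any(expected < 5):
        logger.warning(
            "chi-square expected count below 5 (min %.2f); the asymptotic "
            "p-value may be inaccurate", expected.min(),
        )
    statistic = float(np.sum((table - expected) ** 2 / expected))
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return GroupComparison(
        test_name="pearson_chi2",
        statistic=statistic,
        p_value=p,
        group_labels=labels,
        ns=(int(table[0].sum()), int(table[1].sum())),
    )
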