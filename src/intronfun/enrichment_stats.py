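"""Supporting statistics: group comparisons, enrichment, element repositioning.

* :func:`compare_groups` — two-sided equal-variance t-test and Mann-Whitney
  U per feature, Bonferroni-adjusted across the number of tests.
* :func:`hypergeom_enrich` — upper-tail hypergeometric P(X >= k) for an
  excess of predicted-functional patterns inside a group.
* :func:`repositioning_test` — the null model that a functional element is
  equally likely to sit anywhere inside any intron of its transcript: the
  element (length preserved) is placed uniformly over all start positions
  where it fits wholly inside one intron, and the test reports the fraction
  of placements landing in the actual host intron or one closer to the CDS
  start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "compare_groups",
    "hypergeom_enrich",
    "repositioning_test",
    "summarize_repositioning",
]


@dataclass
class GroupComparison:
    t_statistic: float | None
    t_pvalue: float | None
    t_pvalue_adjusted: float | None
    u_statistic: float
    u_pvalue: float
    u_pvalue_adjusted: float


def _bonferroni(p: float, n_tests: int) -> float:
    return min(1.0, p * n_tests)


def compare_groups(values_a, values_b, n_tests: int = 1) -> GroupComparison:
    """Equal-variance t-test and Mann-Whitney U, Bonferroni-adjusted.

    With zero pooled variance the t-test is undefined and only U is
    reported (t fields are None).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    u_stat, u_p = stats.mannwhitneyu(a, b, alternative="two-sided")
    t_stat = t_p = t_adj = None
    if a.size >= 2 and b.size >= 2:
        pooled_var = np.concatenate([a - a.mean(), b - b.mean()]).var()
        if pooled_var > 0:
            t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
            t_stat, t_p = float(t_stat), float(t_p)
            t_adj = _bonferroni(t_p, n_tests)
    return GroupComparison(
        t_statistic=t_stat, t_pvalue=t_p, t_pvalue_adjusted=t_adj,
        u_statistic=float(u_stat), u_pvalue=float(u_p),
        u_pvalue_adjusted=_bonferroni(float(u_p), n_tests),
    )


def hypergeom_enrich(k: int, group_size: int, n_predicted: int, total: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``k`` predicted-functional patterns inside a group of ``group_size``,
    with ``n_predicted`` predicted-functional among ``total`` patterns.
    """
    if not (0 <= k <= min(group_size, n_predicted) and
            group_size <= total and n_predicted <= total):
        raise ValueError("inconsistent hypergeometric counts")
    return float(stats.hypergeom.sf(k - 1, total, n_predicted, group_size))


def repositioning_test(
    intron_lengths: list[int],
    element: tuple[int, int],
    n_sims: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of uniform repositionings at or 5' of the actual host intron.

    ``element`` is (0-based host intron index, element length in nt).  Each
    simulation draws the element start uniformly over every position where
    the element fits wholly inside a single intron of the transcript.
    """
    host, elem_len = element
    lengths = np.asarray(intron_lengths, dtype=int)
    if not 0 <= host < len(lengths):
        raise ValueError("host intron index out of range")
    if elem_len < 1:
        raise ValueError("element length must be >= 1")
    if elem_len > lengths[host]:
        raise ValueError("element does not fit inside its host intron")
    valid = np.maximum(lengths - elem_len + 1, 0)
    if valid.sum() == 0:
        raise ValueError("element longer than every intron; no valid placement")
    rng = np.random.default_rng(seed)
    introns = rng.choice(len(lengths), size=n_sims, p=valid / valid.sum())
    return float((introns <= host).mean())


def summarize_repositioning(fractions, threshold: float = 0.95) -> dict:
    """Share of transcripts whose repositioning fraction is >= ``threshold``."""
    arr = np.asarray(list(fractions), float)
    return {
        "n_transcripts": int(arr.size),
        "share_at_or_above": float((arr >= threshold).mean()) if arr.size else float("nan"),
        "threshold": threshold,
        "mean_fraction": float(arr.mean()) if arr.size else float("nan"),
    }
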