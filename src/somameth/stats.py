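"""Shared nonparametric statistics.

Two-group comparisons use the Wilcoxon rank-sum test, paired/one-sample
comparisons the Wilcoxon signed-rank test.  Both switch between an exact
null distribution (small samples) and a normal approximation with tie
correction (large samples).  The exact path handles ties via mid-ranks and
enumerates the full permutation distribution, so small-sample p-values are
correct even with tied observations — scipy's exact methods decline ties,
which is why the enumeration lives here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankSumResult",
    "SignedRankResult",
    "rank_sum_test",
    "signed_rank_test",
    "bh_adjust",
    "fisher_exact_2x2",
    "hypergeom_sf",
]

# Above these sizes the exact enumerations become expensive and the normal
# approximation is already accurate.
_RANKSUM_ENUM_MAX_TOTAL = 16
_RANKSUM_SCIPY_EXACT_MAX = 25
_SIGNEDRANK_ENUM_MAX = 16


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank-sum W of the first sample
    pvalue: float
    median_x: float
    median_y: float
    method: str


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n_used: int
    median_diff: float
    method: str
    degenerate: bool = False


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when samples are small (enumeration with mid-ranks if ties are
    present, scipy's exact distribution otherwise); normal approximation
    with tie correction and continuity correction for larger samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[: x.size].sum())
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and max(x.size, y.size) <= _RANKSUM_SCIPY_EXACT_MAX:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(w, float(res.pvalue), float(np.median(x)),
                             float(np.median(y)), "exact")
    if has_ties and pooled.size <= _RANKSUM_ENUM_MAX_TOTAL:
        p = _ranksum_enumerated_p(ranks, x.size, w)
        return RankSumResult(w, p, float(np.median(x)), float(np.median(y)),
                             "exact-enumeration")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankSumResult(w, float(res.pvalue), float(np.median(x)),
                         float(np.median(y)), "normal-approx")


def _ranksum_enumerated_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Exact two-sided p over all rank assignments, symmetric-deviation form."""
    n = ranks.size
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def signed_rank_test(diffs, zero_method: str = "wilcox") -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on a vector of differences.

    ``zero_method='wilcox'`` drops zero differences (the default);
    ``'pratt'`` keeps them in the ranking but excludes them from W+.
    Exact by sign-flip enumeration for small n (ties handled by mid-ranks);
    normal approximation with tie correction otherwise.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("signed_rank_test requires non-empty differences")
    med = float(np.median(d))
    if zero_method == "wilcox":
        d_used = d[d != 0]
    elif zero_method == "pratt":
        d_used = d
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if d_used.size == 0 or np.all(d_used == 0):
        return SignedRankResult(0.0, 1.0, 0, med, "degenerate", degenerate=True)

    ranks = _midranks(np.abs(d_used))
    if zero_method == "pratt":
        nonzero = d_used != 0
        w_plus = float(ranks[(d_used > 0)].sum())
        ranks = ranks[nonzero]
        signs_n = int(nonzero.sum())
    else:
        w_plus = float(ranks[d_used > 0].sum())
        signs_n = d_used.size

    if signs_n <= _SIGNEDRANK_ENUM_MAX:
        p = _signedrank_enumerated_p(ranks, w_plus)
        return SignedRankResult(w_plus, p, signs_n, med, "exact-enumeration")

    res = sps.wilcoxon(d_used, zero_method=zero_method, correction=True,
                       alternative="two-sided", method="approx")
    return SignedRankResult(w_plus, float(res.pvalue), signs_n, med,
                            "normal-approx")


def _signedrank_enumerated_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p over all 2^n sign patterns (symmetric deviation)."""
    n = ranks.size
    mu = ranks.sum() / 2.0
    dev = abs(w_obs - mu)
    # vectorized: bit-pattern matrix (n <= 16 so at most 65536 rows)
    patterns = np.arange(2 ** n, dtype=np.uint32)
    bits = ((patterns[:, None] >> np.arange(n)) & 1).astype(float)
    w = bits @ ranks
    return float(np.mean(np.abs(w - mu) >= dev - 1e-12))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact p and sample odds ratio for a 2x2 table.

    The odds ratio is ad/bc with a Haldane 0.5 correction applied to every
    cell when any cell is zero; a zero denominator after correction cannot
    occur.  Returns (odds_ratio, pvalue).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("fisher_exact_2x2 requires a non-negative 2x2 table")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c)), float(p)


def hypergeom_sf(k: int, n_universe: int, n_set: int, n_hits: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Probability of drawing at least ``k`` members of a set of size
    ``n_set`` when sampling ``n_hits`` genes without replacement from a
    universe of ``n_universe``.
    """
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, n_universe, n_set, n_hits))
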