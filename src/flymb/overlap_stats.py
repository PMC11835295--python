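"""Set-overlap and enrichment statistics.

Hypergeometric upper tails are evaluated in log space (log-gamma sums) so that
extreme overlaps — p-values at the 1e-70 scale are routine when two large gene
sets drawn from a ~14k-gene genome share hundreds of members — do not
underflow intermediate terms.  The default universe size, 13,986, is the
number of protein-coding genes in the Drosophila melanogaster genome; it is a
default only and every caller can override it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

DEFAULT_UNIVERSE_SIZE = 13_986


@dataclass(frozen=True)
class OverlapQuery:
    """Sizes for a two-set overlap drawn from a finite universe.

    ``set_a_size`` (K) and ``set_b_size`` (n) are the two gene-set sizes,
    ``overlap`` (k) their intersection, ``universe_size`` (N) the population
    both sets were drawn from.
    """

    set_a_size: int
    set_b_size: int
    overlap: int
    universe_size: int = DEFAULT_UNIVERSE_SIZE

    def __post_init__(self) -> None:
        K, n, k, N = self.set_a_size, self.set_b_size, self.overlap, self.universe_size
        if min(K, n, N) <= 0 or k < 0:
            raise ValueError("set and universe sizes must be positive, overlap non-negative")
        if k > min(K, n):
            raise ValueError(f"overlap {k} exceeds min(set sizes) {min(K, n)}")
        if max(K, n) > N:
            raise ValueError("set sizes exceed universe size")


def hypergeom_upper_tail(query: OverlapQuery) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): the enrichment p of an overlap.

    Summed as ``logsumexp`` over per-count log-pmf terms so the tail is
    accurate far below double underflow thresholds for individual factors.
    """
    K, n, k, N = (query.set_a_size, query.set_b_size,
                  query.overlap, query.universe_size)
    if k == 0:
        return 1.0
    hi = min(K, n)
    support = np.arange(k, hi + 1)
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)`` with the sample (unconditional) odds ratio
    ``(a*d)/(b*c)`` and the probability-mass two-sided rule: sum the
    probabilities of all tables with the observed margins that are no more
    probable than the observed one.  A zero margin makes the table degenerate
    and p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative entries")
    a, b, c, d = t.ravel()
    row0, row1, col0, col1 = a + b, c + d, a + c, b + d
    if 0 in (row0, row1, col0, col1):
        return float("nan"), 1.0
    odds = float("inf") if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return odds, float(p)


def jaccard_index(set_a: Iterable, set_b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|.  Undefined (raises) when both sets are empty."""
    A, B = set(set_a), set(set_b)
    union = A | B
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(A & B) / len(union)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj[i] = min_{j: p_(j) >= p_(i)} p_(j) * m / rank(j)``, capped at 1 —
    the cumulative minimum taken from the largest rank downward.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


@dataclass(frozen=True)
class GenesetFilterParams:
    """Term-size window and significance level for gene-set enrichment."""

    min_term_size: int = 25
    max_term_size: int = 250
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_term_size > self.max_term_size:
            raise ValueError("min_term_size > max_term_size")


def geneset_enrichment(query: Set[str], terms: Mapping[str, Set[str]],
                       universe: Set[str],
                       params: GenesetFilterParams | None = None) -> pd.DataFrame:
    """Term-size-filtered over-representation analysis of a gene list.

    Terms whose universe-restricted size falls outside
    ``[min_term_size, max_term_size]`` are excluded *before* testing; the rest
    get a hypergeometric upper-tail p, BH-adjusted across the tested terms.
    Fold enrichment is ``(k/|query|) / (K/|universe|)``.
    """
    params = params or GenesetFilterParams()
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:10]}")
    rows = []
    for term, members in terms.items():
        members = set(members) & universe
        K = len(members)
        if not (params.min_term_size <= K <= params.max_term_size):
            continue
        k = len(members & query)
        p = hypergeom_upper_tail(OverlapQuery(K, len(query), k, len(universe)))
        fold = (k / len(query)) / (K / len(universe)) if query else 0.0
        rows.append({"term": term, "k": k, "K": K, "fold": fold, "p": p})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "fold", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else pd.Series(dtype=float)
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
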