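"""Agreement statistics between allocations.

Two complementary views of reproducibility across search runs:

* normalized Hamming similarity between the two allocation matrices, with an
  *exact* null distribution of the Hamming distance between two independent,
  uniformly random valid allocations — computed per gene in closed form and
  combined across genes by convolution;
* a fuzzy adjusted Rand index (FARI) that asks whether pairs of genes are
  placed together or apart, so it stays high when whole groups of genes are
  merely swapped between pathways while the Hamming similarity drops.

Plus the standard hypergeometric upper-tail enrichment p-value for asking
whether a pathway/cluster is enriched for affected genes.

Closed form of the single-gene null.  A gene belonging to ``n`` pathways has
``2**n - 1`` valid allocation rows (the all-zero row is forbidden).  Over all
ordered pairs of valid rows the number at Hamming distance ``r`` is::

    r = 0:       2**n - 1
    r >= 1:      C(n, r) * (2**n - 2)

since among all ``2**n`` strings there are ``2**n * C(n, r)`` ordered pairs at
distance r, of which ``2 * C(n, r)`` involve the zero string (for r >= 1).
The counts sum to ``(2**n - 1)**2`` as required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .core import AllocationMatrix, DiscreteState, MembershipMatrix
from .errors import InputError, ParameterError

__all__ = [
    "HammingNull",
    "EnrichmentQuery",
    "hamming_distance",
    "hamming_similarity",
    "gene_null_distribution",
    "combine_null_distributions",
    "allocation_null",
    "null_tail_probability",
    "fuzzy_adjusted_rand",
    "enrichment_pvalue",
]

#: Identifier of the implemented fuzzy-ARI variant, recorded in run metadata.
FARI_VARIANT = "pair-counting/min-agreement/split-difference"


@dataclass(frozen=True)
class HammingNull:
    """Exact distribution of the Hamming distance between two uniformly
    random valid allocations.

    ``counts[r]`` is the exact integer number of ordered allocation pairs at
    distance ``r``; ``total`` is the number of ordered pairs, so the
    probability of distance r is ``counts[r] / total`` (exact rational).
    """

    counts: tuple[int, ...]
    total: int

    def __post_init__(self):
        if not self.counts:
            raise ParameterError("null distribution needs at least one distance")
        if any(c < 0 for c in self.counts):
            raise ParameterError("combination counts must be non-negative")
        if sum(self.counts) != self.total:
            raise ParameterError("counts must sum to the total number of pairs")

    @property
    def max_distance(self) -> int:
        return len(self.counts) - 1

    @property
    def probabilities(self) -> np.ndarray:
        """Float probabilities over distances 0..max_distance."""
        return np.array([c / self.total for c in self.counts], dtype=np.float64)

    def probability(self, r: int) -> Fraction:
        """Exact probability of distance ``r``."""
        self._check_support(r)
        return Fraction(self.counts[r], self.total)

    def cdf(self, r: int) -> Fraction:
        """Exact lower-tail probability P(distance <= r)."""
        self._check_support(r)
        return Fraction(sum(self.counts[: r + 1]), self.total)

    @property
    def mean(self) -> float:
        return float(sum(r * c for r, c in enumerate(self.counts)) / self.total)

    @property
    def variance(self) -> float:
        m = self.mean
        return float(sum(c * (r - m) ** 2 for r, c in enumerate(self.counts)) / self.total)

    def _check_support(self, r: int) -> None:
        if not (0 <= r <= self.max_distance):
            raise ParameterError(
                f"distance {r} outside support [0, {self.max_distance}]"
            )


def gene_null_distribution(n: int) -> HammingNull:
    """Exact Hamming-distance null for one gene belonging to ``n`` pathways."""
    if n < 1:
        raise ParameterError(f"a gene must belong to at least one pathway, got n={n}")
    valid = (1 << n) - 1  # 2**n - 1 non-empty rows
    counts = [valid] + [math.comb(n, r) * (valid - 1) for r in range(1, n + 1)]
    return HammingNull(counts=tuple(counts), total=valid * valid)


def combine_null_distributions(nulls: Sequence[HammingNull]) -> HammingNull:
    """Distribution of the summed distance of independent genes, by exact
    sequential convolution of the integer combination counts."""
    if not nulls:
        raise ParameterError("need at least one per-gene null to combine")
    counts = list(nulls[0].counts)
    total = nulls[0].total
    for nxt in nulls[1:]:
        out = [0] * (len(counts) + len(nxt.counts) - 1)
        for r1, c1 in enumerate(counts):
            if c1 == 0:
                continue
            for r2, c2 in enumerate(nxt.counts):
                out[r1 + r2] += c1 * c2
        counts = out
        total *= nxt.total
    return HammingNull(counts=tuple(counts), total=total)


def allocation_null(membership: MembershipMatrix, state: DiscreteState) -> HammingNull:
    """Exact null for a whole experiment: convolution over the expressed
    multi-membership genes (all other rows are identical in any pair of valid
    allocations and contribute distance zero)."""
    free = np.flatnonzero(state.expressed_mask & membership.multi_mask)
    if len(free) == 0:
        return HammingNull(counts=(1,), total=1)
    return combine_null_distributions(
        [gene_null_distribution(int(membership.membership_counts[i])) for i in free]
    )


def null_tail_probability(null: HammingNull, observed: int) -> float:
    """Lower-tail p-value P(distance <= observed): the probability that two
    random valid allocations are at least as similar as the observed pair."""
    return float(null.cdf(observed))


# ---------------------------------------------------------------------------
# Allocation-to-allocation similarity


def _check_aligned(d: AllocationMatrix, e: AllocationMatrix) -> None:
    if d.shape != e.shape:
        raise InputError(f"allocation shapes differ: {d.shape} vs {e.shape}")


def hamming_distance(alloc_d: AllocationMatrix, alloc_e: AllocationMatrix) -> int:
    """Total number of differing entries between two allocations."""
    _check_aligned(alloc_d, alloc_e)
    return int((alloc_d.entries != alloc_e.entries).sum())


def hamming_similarity(alloc_d: AllocationMatrix, alloc_e: AllocationMatrix) -> float:
    """Normalized similarity ``1 - distance / (N * M)`` in [0, 1]; equal to 1
    iff the allocations are identical."""
    _check_aligned(alloc_d, alloc_e)
    n, m = alloc_d.shape
    return 1.0 - hamming_distance(alloc_d, alloc_e) / (n * m)


def fuzzy_adjusted_rand(alloc_d: AllocationMatrix, alloc_e: AllocationMatrix) -> float:
    """Fuzzy adjusted Rand index between two allocations.

    Each allocation is read as a fuzzy partition: a gene allocated to k
    pathways belongs to each with degree 1/k (equal weights).  For every gene
    pair the co-membership degree in a partition is
    ``s = sum_j min(u_ij, u_i'j)``.  Pair-counting cells are accumulated as

    * agreement-together ``a = min(s_D, s_E)``,
    * agreement-apart ``d = min(1 - s_D, 1 - s_E)``,
    * disagreement ``b, c`` = positive/negative parts of ``s_D - s_E``,

    which always sum to one per pair, and combined by the pair-count form of
    the adjusted Rand index ``2(ad - bc) / ((a+b)(b+d) + (a+c)(c+d))``.  For
    crisp partitions (every row-sum 1) this is exactly the classical adjusted
    Rand index; identical allocations score exactly 1; the value is invariant
    to consistent pathway relabelling.

    Genes allocated nowhere in *both* matrices (stable genes) are excluded
    from the comparison; a gene allocated in one matrix but not the other is
    an input error.
    """
    _check_aligned(alloc_d, alloc_e)
    rows_d = alloc_d.entries.sum(axis=1)
    rows_e = alloc_e.entries.sum(axis=1)
    if ((rows_d == 0) != (rows_e == 0)).any():
        raise InputError("a compared gene has an empty allocation row in one matrix only")
    keep = rows_d > 0
    if keep.sum() < 2:
        raise InputError("need at least two allocated genes to compare")
    u = alloc_d.entries[keep] / rows_d[keep, None]
    v = alloc_e.entries[keep] / rows_e[keep, None]
    s_d = _pairwise_comembership(u)
    s_e = _pairwise_comembership(v)
    a = np.minimum(s_d, s_e).sum()
    d = np.minimum(1.0 - s_d, 1.0 - s_e).sum()
    diff = s_d - s_e
    b = diff[diff > 0].sum()
    c = -diff[diff < 0].sum()
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        return 1.0
    return float(2.0 * (a * d - b * c) / denom)


def _pairwise_comembership(u: np.ndarray) -> np.ndarray:
    """Upper-triangle vector of sum_k min(u_i, u_j) over gene pairs."""
    n = u.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return np.minimum(u[iu], u[ju]).sum(axis=1)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment


@dataclass(frozen=True)
class EnrichmentQuery:
    """Counts for one enrichment question: of ``set_size`` genes in a pathway
    or cluster, ``overlap`` fall in a functional category of
    ``category_size`` genes, out of ``genome_size`` genes on the platform."""

    genome_size: int
    category_size: int
    set_size: int
    overlap: int

    def __post_init__(self):
        g, cat, n, k = self.genome_size, self.category_size, self.set_size, self.overlap
        if g < 1:
            raise ParameterError("genome_size must be positive")
        if not (0 <= cat <= g and 0 <= n <= g):
            raise ParameterError("category_size and set_size must lie in [0, genome_size]")
        if not (0 <= k <= min(cat, n)):
            raise ParameterError(
                f"overlap {k} impossible for category {cat} and set {n}"
            )
        if n - k > g - cat:
            raise ParameterError("more non-category genes in the set than exist")


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def enrichment_pvalue(query: EnrichmentQuery) -> float:
    """Probability of observing at least ``overlap`` category genes in the
    set by chance: the hypergeometric upper tail, evaluated in log space.

    The upper-tail sum over i = k..min(C, n) is mathematically identical to
    ``1 - sum_{i<k}`` and numerically far better behaved for small p.
    """
    g, cat, n, k = query.genome_size, query.category_size, query.set_size, query.overlap
    if k == 0:
        return 1.0
    log_denom = _log_comb(g, n)
    lo = max(k, n - (g - cat))
    hi = min(cat, n)
    terms = [
        _log_comb(cat, i) + _log_comb(g - cat, n - i) - log_denom
        for i in range(lo, hi + 1)
    ]
    if not terms:
        return 0.0
    m = max(terms)
    p = math.exp(m) * sum(math.exp(t - m) for t in terms)
    return float(min(1.0, p))
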