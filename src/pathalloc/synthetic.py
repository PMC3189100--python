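"""Desk-scale synthetic instances with planted structure.

The generator emulates the net-effect premise behind the allocation model:
each pathway has an activation direction (up, down or inactive), each gene
truly serves a subset of its member pathways (the *planted allocation*), and
the observed log2 ratio is the net of those contributions plus half-normal
noise on the magnitude.  Recovering the planted allocation from the
expression vector is then a well-posed benchmark for the searches.

Two planting rules are provided:

* ``"consensus"`` (default) — a gene's regulatory demand is the direction of
  one randomly chosen member pathway and the gene is planted in *every*
  member pathway sharing that direction.  Under this rule the planted
  allocation is the consensus-fitness optimum, so search recovery measures
  optimisation quality directly.
* ``"random"`` — the planted subset is a uniform non-empty subset of the
  member pathways; opposite directions may cancel, yielding stable genes
  (net zero), in which case the expression is drawn uniformly inside the
  stable band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AllocationMatrix,
    DiscreteState,
    ExpressionVector,
    MembershipMatrix,
    OpposingPairs,
    discretize,
    is_valid_allocation,
)
from .errors import ParameterError
from .fitness import FitnessValue, total_fitness
from .stats import (
    allocation_null,
    fuzzy_adjusted_rand,
    hamming_distance,
    hamming_similarity,
    null_tail_probability,
)

__all__ = [
    "SyntheticParams",
    "SyntheticInstance",
    "RecoveryReport",
    "generate_instance",
    "recovery_report",
    "tryptophan_fixture",
    "opposing_module_fixture",
]

# Expressed magnitudes exceed the threshold by this relative margin before
# noise is added, so the zero-noise limit is still strictly past the strict
# inequality of the discretization.
_MARGIN = 1e-6


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings.

    ``noise_sd`` is the standard deviation (log2-ratio units) of the
    half-normal magnitude noise added on top of the threshold; the default
    0.25 equals a quarter of the default threshold ``c = 1``.
    """

    n_genes: int = 60
    n_pathways: int = 8
    multi_fraction: float = 0.4
    max_memberships: int = 3
    noise_sd: float = 0.25
    threshold: float = 1.0
    seed: int | None = None
    planting: str = "consensus"
    zero_direction_fraction: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.multi_fraction <= 1.0):
            raise ParameterError("multi_fraction must lie in [0, 1]")
        if self.n_pathways < 2 and self.multi_fraction > 0:
            raise ParameterError("multi-membership needs at least 2 pathways")
        if self.max_memberships < 2:
            raise ParameterError("max_memberships must be >= 2")
        if self.max_memberships > self.n_pathways:
            raise ParameterError("max_memberships cannot exceed n_pathways")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if not (self.threshold > 0):
            raise ParameterError("threshold must be positive")
        if self.planting not in ("consensus", "random"):
            raise ParameterError("planting must be 'consensus' or 'random'")
        if not (0.0 <= self.zero_direction_fraction < 1.0):
            raise ParameterError("zero_direction_fraction must lie in [0, 1)")
        if self.n_genes < self.n_pathways:
            raise ParameterError("need at least one gene per pathway")


@dataclass(frozen=True)
class SyntheticInstance:
    """A generated benchmark instance with its ground truth."""

    membership: MembershipMatrix
    planted_allocation: AllocationMatrix
    pathway_directions: np.ndarray
    expression: ExpressionVector
    params: SyntheticParams

    @property
    def state(self) -> DiscreteState:
        return discretize(self.expression, self.params.threshold)


def generate_instance(params: SyntheticParams | None = None, **kwargs) -> SyntheticInstance:
    """Generate a reproducible instance from ``params`` (or keyword overrides)."""
    if params is None:
        params = SyntheticParams(**kwargs)
    elif kwargs:
        raise ParameterError("pass either a SyntheticParams or keyword overrides, not both")
    rng = np.random.default_rng(params.seed)
    n, m = params.n_genes, params.n_pathways

    directions = rng.choice((-1, 1), size=m).astype(np.int8)
    if params.zero_direction_fraction > 0:
        off = rng.random(m) < params.zero_direction_fraction
        directions[off] = 0

    # membership: first M genes anchor one pathway each so no column is empty
    membership = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        anchors = [i % m] if i < m else [int(rng.integers(m))]
        if rng.random() < params.multi_fraction:
            k = int(rng.integers(2, params.max_memberships + 1))
            extra = rng.choice([j for j in range(m) if j not in anchors],
                               size=k - len(anchors), replace=False)
            anchors = sorted(anchors + list(extra))
        membership[i, anchors] = 1

    gene_ids = tuple(f"g{i:03d}" for i in range(n))
    pathway_ids = tuple(f"pw{j}" for j in range(m))
    P = MembershipMatrix(gene_ids, pathway_ids, membership)

    planted = np.zeros_like(membership)
    nets = np.zeros(n, dtype=np.int64)
    for i in range(n):
        members = np.flatnonzero(membership[i])
        if params.planting == "consensus":
            demand = int(directions[members[int(rng.integers(len(members)))]])
            matching = members[directions[members] == demand]
            subset = matching if (demand != 0 and len(matching)) else \
                members[[int(rng.integers(len(members)))]]
        else:
            code = int(rng.integers(1, 1 << len(members)))
            subset = members[[k for k in range(len(members)) if (code >> k) & 1]]
        planted[i, subset] = 1
        nets[i] = int(directions[subset].sum())

    c = params.threshold
    values = np.empty(n, dtype=np.float64)
    for i in range(n):
        if nets[i] == 0:
            values[i] = rng.uniform(-c, c)
        else:
            magnitude = c * (1.0 + _MARGIN) + abs(rng.normal(0.0, params.noise_sd)) \
                if params.noise_sd > 0 else c * (1.0 + _MARGIN)
            values[i] = float(np.sign(nets[i])) * magnitude

    expression = ExpressionVector(values)
    state = discretize(expression, c)
    planted[~state.expressed_mask] = 0  # stable genes are not allocated
    instance = SyntheticInstance(
        membership=P,
        planted_allocation=AllocationMatrix(planted, mode="pathway"),
        pathway_directions=directions,
        expression=expression,
        params=params,
    )
    assert is_valid_allocation(instance.planted_allocation, P, state)
    return instance


@dataclass(frozen=True)
class RecoveryReport:
    """How closely a found allocation matches the planted truth."""

    hamming_similarity: float
    fuzzy_ari: float
    distance: int
    null_tail_p: float
    fitness_found: FitnessValue
    fitness_planted: FitnessValue


def recovery_report(found: AllocationMatrix, instance: SyntheticInstance) -> RecoveryReport:
    """Score ``found`` against the planted allocation: Hamming similarity,
    fuzzy adjusted Rand index, the exact-null lower-tail probability of the
    observed distance, and the fitness of both allocations."""
    state = instance.state
    planted = instance.planted_allocation
    dist = hamming_distance(found, planted)
    null = allocation_null(instance.membership, state)
    observed = min(dist, null.max_distance)
    return RecoveryReport(
        hamming_similarity=hamming_similarity(found, planted),
        fuzzy_ari=fuzzy_adjusted_rand(found, planted),
        distance=dist,
        null_tail_p=null_tail_probability(null, observed),
        fitness_found=total_fitness(found, state),
        fitness_planted=total_fitness(planted, state),
    )


# ---------------------------------------------------------------------------
# Bundled miniature fixtures


#: Log2 ratios of tryptophan-metabolism genes from an E. coli culture grown
#: in tryptophan-enriched medium (experiment GSM513): most genes are mildly
#: to strongly up-regulated, yqeF is clearly down-regulated.
TRYPTOPHAN_EXPRESSION: tuple[tuple[str, float], ...] = (
    ("atoB", 1.1150),
    ("yqeF", -1.8120),
    ("fadB", 2.6340),
    ("sucA", 1.8200),
    ("tnaA", 1.4660),
    ("trpS", 5.8490),
    ("katE", -0.4370),
    ("katG", 1.4110),
    ("tynA", -0.7870),
)


def tryptophan_fixture() -> tuple[MembershipMatrix, ExpressionVector]:
    """Nine tryptophan-metabolism genes with a synthetic miniature membership.

    The expression values are the real GSM513 log2 ratios above; the
    four-pathway membership is a synthetic stand-in (not the KEGG snapshot)
    shaped so the down-regulated yqeF is a multi-membership gene that can be
    reallocated from tryptophan metabolism to a degradation pathway, echoing
    the behaviour the method is designed to expose.
    """
    gene_ids = tuple(g for g, _ in TRYPTOPHAN_EXPRESSION)
    values = np.array([v for _, v in TRYPTOPHAN_EXPRESSION])
    pathway_ids = ("trp_metabolism", "fatty_acid_degradation",
                   "butanoate_metabolism", "peroxide_response")
    rows = {
        "atoB": ("trp_metabolism", "fatty_acid_degradation", "butanoate_metabolism"),
        "yqeF": ("trp_metabolism", "fatty_acid_degradation", "butanoate_metabolism"),
        "fadB": ("trp_metabolism", "fatty_acid_degradation"),
        "sucA": ("trp_metabolism", "butanoate_metabolism"),
        "tnaA": ("trp_metabolism",),
        "trpS": ("trp_metabolism",),
        "katE": ("trp_metabolism", "peroxide_response"),
        "katG": ("trp_metabolism", "peroxide_response"),
        "tynA": ("trp_metabolism", "peroxide_response"),
    }
    entries = np.zeros((len(gene_ids), len(pathway_ids)), dtype=np.int8)
    for i, g in enumerate(gene_ids):
        for pw in rows[g]:
            entries[i, pathway_ids.index(pw)] = 1
    return MembershipMatrix(gene_ids, pathway_ids, entries), ExpressionVector(values)


def opposing_module_fixture() -> tuple[MembershipMatrix, ExpressionVector, OpposingPairs]:
    """Synthetic glycolysis/gluconeogenesis-style module fixture.

    Twelve genes over four modules; glycolysis and gluconeogenesis form an
    opposing pair sharing several expressed genes, so module-mode searches
    must keep each shared gene out of one of the two.  Gene names and values
    are synthetic.
    """
    pathway_ids = ("glycolysis", "gluconeogenesis", "tca_cycle", "pentose_phosphate")
    rows = {
        "gA": (("glycolysis", "gluconeogenesis"), -1.8),
        "gB": (("glycolysis", "gluconeogenesis"), -1.5),
        "gC": (("glycolysis", "gluconeogenesis", "pentose_phosphate"), 1.7),
        "gD": (("glycolysis",), -2.1),
        "gE": (("gluconeogenesis",), 1.9),
        "gF": (("gluconeogenesis", "tca_cycle"), 1.4),
        "gG": (("tca_cycle",), 1.6),
        "gH": (("tca_cycle", "pentose_phosphate"), 1.2),
        "gI": (("pentose_phosphate",), -1.3),
        "gJ": (("glycolysis", "tca_cycle"), -1.1),
        "gK": (("gluconeogenesis", "pentose_phosphate"), 2.2),
        "gL": (("glycolysis", "pentose_phosphate"), 0.4),
    }
    gene_ids = tuple(rows)
    entries = np.zeros((len(gene_ids), len(pathway_ids)), dtype=np.int8)
    values = np.empty(len(gene_ids))
    for i, (g, (pws, v)) in enumerate(rows.items()):
        values[i] = v
        for pw in pws:
            entries[i, pathway_ids.index(pw)] = 1
    membership = MembershipMatrix(gene_ids, pathway_ids, entries)
    opposing = OpposingPairs([("glycolysis", "gluconeogenesis")])
    return membership, ExpressionVector(values), opposing
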