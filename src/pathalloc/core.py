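"""Allocation data model: membership snapshot, discretized expression and
valid gene-to-pathway allocations.

The central objects are three genes-by-pathways binary matrices.  ``P``
(:class:`MembershipMatrix`) is the immutable pathway-membership snapshot:
``P[i, j] = 1`` iff gene *i* is annotated to pathway *j*.  An allocation
``A`` (:class:`AllocationMatrix`) is a mutable sub-assignment ``A <= P``
stating which of its member pathways each gene is currently serving.  A
per-gene ternary state vector ``X`` (:class:`DiscreteState`) records whether
each gene is up-regulated (+1), down-regulated (-1) or stable (0) relative
to a log2-ratio threshold ``c``.

An allocation is *valid* when every expressed gene (state != 0) is allocated
to at least one of its member pathways, allocations never contradict the
membership snapshot, and -- in module mode -- no gene occupies both members
of a pair of mutually exclusive modules (e.g. glycolysis vs gluconeogenesis,
which are never simultaneously active).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "MembershipMatrix",
    "ExpressionVector",
    "DiscreteState",
    "AllocationMatrix",
    "OpposingPairs",
    "discretize",
    "is_valid_allocation",
    "random_valid_allocation",
    "random_valid_row",
]

#: RNG seed used when the caller supplies none; recorded here so runs remain
#: reproducible even without an explicit seed.
DEFAULT_SEED = 20110922


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        logger.info("no RNG seed supplied; using recorded default seed %d", DEFAULT_SEED)
        rng = DEFAULT_SEED
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class MembershipMatrix:
    """Immutable binary gene-by-pathway incidence snapshot ``P``.

    Parameters
    ----------
    gene_ids
        Ordered gene identifiers (rows).
    pathway_ids
        Ordered pathway/module identifiers (columns).
    entries
        ``(n_genes, n_pathways)`` array of 0/1.  Every gene must belong to at
        least one pathway and every pathway must contain at least one gene.
    """

    gene_ids: tuple[str, ...]
    pathway_ids: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self):
        genes = tuple(self.gene_ids)
        pathways = tuple(self.pathway_ids)
        entries = np.ascontiguousarray(self.entries, dtype=np.int8)
        if entries.ndim != 2 or entries.shape != (len(genes), len(pathways)):
            raise InputError(
                f"membership shape {entries.shape} does not match "
                f"{len(genes)} genes x {len(pathways)} pathways"
            )
        if len(set(genes)) != len(genes):
            raise InputError("duplicate gene identifiers in membership")
        if len(set(pathways)) != len(pathways):
            raise InputError("duplicate pathway identifiers in membership")
        if not np.isin(entries, (0, 1)).all():
            raise InputError("membership entries must be 0 or 1")
        if entries.shape[0] and (entries.sum(axis=1) < 1).any():
            raise InputError("every gene must belong to at least one pathway")
        if entries.shape[0] and (entries.sum(axis=0) < 1).any():
            raise InputError("every pathway must contain at least one gene")
        entries.setflags(write=False)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "pathway_ids", pathways)
        object.__setattr__(self, "entries", entries)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    @property
    def membership_counts(self) -> np.ndarray:
        """Per-gene number of member pathways (row sums of ``P``)."""
        return self.entries.sum(axis=1)

    @property
    def multi_mask(self) -> np.ndarray:
        """Boolean mask of multi-membership genes (>= 2 member pathways)."""
        return self.membership_counts >= 2

    def members_of(self, gene_index: int) -> np.ndarray:
        """Column indices of the pathways gene ``gene_index`` belongs to."""
        return np.flatnonzero(self.entries[gene_index])

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise InputError(f"unknown gene identifier {gene_id!r}") from None

    def pathway_index(self, pathway_id: str) -> int:
        try:
            return self.pathway_ids.index(pathway_id)
        except ValueError:
            raise InputError(f"unknown pathway identifier {pathway_id!r}") from None


@dataclass(frozen=True)
class ExpressionVector:
    """Per-gene log2 expression ratios aligned to a membership's gene order."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise InputError("expression values must form a 1-D vector")
        if not np.isfinite(values).all():
            raise InputError("expression values must all be finite")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DiscreteState:
    """Ternary up/down/stable call per gene.

    ``states[i]`` is +1 when the log2 ratio exceeds ``threshold``, -1 when it
    is below ``-threshold`` and 0 otherwise (strict inequalities, so values
    landing exactly on the cutoff are stable).
    """

    states: np.ndarray
    threshold: float

    def __post_init__(self):
        states = np.ascontiguousarray(self.states, dtype=np.int8)
        if states.ndim != 1:
            raise InputError("states must form a 1-D vector")
        if not np.isin(states, (-1, 0, 1)).all():
            raise InputError("states must be -1, 0 or +1")
        if not (float(self.threshold) > 0):
            raise ParameterError("threshold must be positive")
        states.setflags(write=False)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "threshold", float(self.threshold))

    @property
    def expressed_mask(self) -> np.ndarray:
        return self.states != 0

    def __len__(self) -> int:
        return len(self.states)


def discretize(expression: ExpressionVector | Sequence[float] | np.ndarray,
               threshold: float) -> DiscreteState:
    """Discretize log2 ratios into up (+1), down (-1) and stable (0) calls.

    A gene is up-regulated when its ratio is strictly above ``threshold``,
    down-regulated when strictly below ``-threshold``, stable otherwise.
    """
    if not (threshold > 0):
        raise ParameterError(f"threshold must be positive, got {threshold}")
    if not isinstance(expression, ExpressionVector):
        expression = ExpressionVector(np.asarray(expression, dtype=float))
    values = expression.values
    states = np.zeros(len(values), dtype=np.int8)
    states[values > threshold] = 1
    states[values < -threshold] = -1
    return DiscreteState(states=states, threshold=threshold)


@dataclass(frozen=True)
class OpposingPairs:
    """Unordered pairs of mutually exclusive modules.

    Opposing modules (glycolysis M00001 vs gluconeogenesis M00003, biosynthesis
    vs degradation of the same metabolite, ...) are never active together; an
    expressed gene shared by both may be allocated to at most one.
    """

    pairs: tuple[tuple[str, str], ...]

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        seen: list[tuple[str, str]] = []
        for a, b in pairs:
            if a == b:
                raise InputError(f"module {a!r} cannot oppose itself")
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.append(key)
        object.__setattr__(self, "pairs", tuple(seen))

    def __len__(self) -> int:
        return len(self.pairs)

    def __bool__(self) -> bool:
        return bool(self.pairs)

    def validate_against(self, membership: MembershipMatrix) -> None:
        known = set(membership.pathway_ids)
        for a, b in self.pairs:
            if a not in known or b not in known:
                raise InputError(f"opposing pair ({a!r}, {b!r}) references unknown module")

    def index_pairs(self, membership: MembershipMatrix) -> tuple[tuple[int, int], ...]:
        self.validate_against(membership)
        return tuple(
            (membership.pathway_index(a), membership.pathway_index(b)) for a, b in self.pairs
        )

    def opponents_by_column(self, membership: MembershipMatrix) -> Mapping[int, tuple[int, ...]]:
        """Map each column index to the columns it is opposed to."""
        out: dict[int, list[int]] = {}
        for a, b in self.index_pairs(membership):
            out.setdefault(a, []).append(b)
            out.setdefault(b, []).append(a)
        return {j: tuple(v) for j, v in out.items()}


@dataclass
class AllocationMatrix:
    """Mutable binary allocation ``A`` of expressed genes to member pathways.

    ``mode`` is ``"pathway"`` or ``"module"``; the latter additionally enforces
    opposing-pair exclusivity during validation.
    """

    entries: np.ndarray
    mode: str = "pathway"

    def __post_init__(self):
        entries = np.ascontiguousarray(self.entries, dtype=np.int8)
        if entries.ndim != 2:
            raise InputError("allocation entries must be a 2-D matrix")
        if not np.isin(entries, (0, 1)).all():
            raise InputError("allocation entries must be 0 or 1")
        if self.mode not in ("pathway", "module"):
            raise ParameterError(f"mode must be 'pathway' or 'module', got {self.mode!r}")
        self.entries = entries

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def copy(self) -> "AllocationMatrix":
        return AllocationMatrix(entries=self.entries.copy(), mode=self.mode)

    def row_sums(self) -> np.ndarray:
        return self.entries.sum(axis=1)


def is_valid_allocation(alloc: AllocationMatrix,
                        membership: MembershipMatrix,
                        state: DiscreteState,
                        opposing: OpposingPairs | None = None) -> bool:
    """Check all validity constraints of an allocation.

    Valid means: ``A <= P`` entrywise; every expressed gene has at least one
    allocated pathway; expressed single-membership genes keep their (single)
    membership; stable genes are not allocated; in module mode no gene holds
    both members of an opposing pair.
    """
    A, P = alloc.entries, membership.entries
    if A.shape != P.shape or len(state) != membership.n_genes:
        raise InputError(
            f"shape mismatch: allocation {A.shape}, membership {P.shape}, "
            f"{len(state)} states"
        )
    if (A > P).any():
        return False
    expressed = state.expressed_mask
    rows = A.sum(axis=1)
    if (rows[expressed] < 1).any():
        return False
    if (rows[~expressed] != 0).any():
        return False
    single = membership.membership_counts == 1
    fixed = expressed & single
    if fixed.any() and (A[fixed] != P[fixed]).any():
        return False
    if alloc.mode == "module" and opposing:
        for a, b in opposing.index_pairs(membership):
            if (A[:, a] & A[:, b]).any():
                return False
    return True


def random_valid_row(n_members: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one of the ``2**n - 1`` non-empty binary strings uniformly.

    The all-zero string (gene serving none of its pathways) is never a valid
    allocation of an expressed gene, so it is excluded from the draw.
    """
    if n_members < 1:
        raise ParameterError("a gene must belong to at least one pathway")
    if n_members <= 62:
        code = int(rng.integers(1, (1 << n_members)))
        bits = [(code >> k) & 1 for k in range(n_members)]
        return np.array(bits, dtype=np.int8)
    while True:  # pragma: no cover - memberships this wide do not occur in KEGG
        bits = rng.integers(0, 2, size=n_members).astype(np.int8)
        if bits.any():
            return bits


def random_valid_allocation(membership: MembershipMatrix,
                            state: DiscreteState,
                            opposing: OpposingPairs | None = None,
                            rng: np.random.Generator | int | None = None,
                            mode: str = "pathway") -> AllocationMatrix:
    """Draw a uniformly random valid allocation.

    Expressed single-membership genes keep their fixed row; each expressed
    multi-membership gene's row is drawn uniformly from the non-empty binary
    strings over its member pathways; stable genes get all-zero rows.  In
    module mode rows violating an opposing pair are resampled until valid,
    preserving uniformity over the remaining valid rows.
    """
    rng = _as_rng(rng)
    if len(state) != membership.n_genes:
        raise InputError("state length does not match membership")
    if opposing:
        mode = "module"
    A = np.zeros_like(membership.entries)
    expressed = state.expressed_mask
    opponents = opposing.opponents_by_column(membership) if (opposing and mode == "module") else {}
    for i in np.flatnonzero(expressed):
        members = membership.members_of(i)
        if len(members) == 1:
            A[i, members[0]] = 1
            continue
        while True:
            row = random_valid_row(len(members), rng)
            if _row_violates_opposing(members, row, opponents):
                continue
            A[i, members] = row
            break
    return AllocationMatrix(entries=A, mode=mode)


def _row_violates_opposing(members: np.ndarray, row: np.ndarray,
                           opponents: Mapping[int, tuple[int, ...]]) -> bool:
    if not opponents:
        return False
    on = {int(members[k]) for k in range(len(members)) if row[k]}
    return any(opp in on for j in on for opp in opponents.get(j, ()))
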