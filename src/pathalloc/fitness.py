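"""Per-pathway expression-consensus fitness.

A pathway's *net* is the number of allocated up-regulated genes minus the
number of allocated down-regulated genes.  The fitness of an allocation is
the sum over pathways of the absolute nets: it grows as each pathway fills
with genes of agreeing expression direction, regardless of whether the
consensus is up or down.  The signed per-pathway nets are kept on the result
so the plain signed sum is also recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AllocationMatrix, DiscreteState
from .errors import InputError

__all__ = ["FitnessValue", "pathway_nets", "pathway_net", "total_fitness"]


@dataclass(frozen=True)
class FitnessValue:
    """Total consensus fitness plus the signed net of each pathway."""

    total: int
    per_pathway_net: np.ndarray

    def __post_init__(self):
        nets = np.asarray(self.per_pathway_net, dtype=np.int64)
        nets.setflags(write=False)
        object.__setattr__(self, "per_pathway_net", nets)
        object.__setattr__(self, "total", int(self.total))

    @property
    def signed_total(self) -> int:
        """Plain signed sum of the nets (no absolute value per pathway)."""
        return int(self.per_pathway_net.sum())

    def __int__(self) -> int:
        return self.total


def pathway_nets(alloc: AllocationMatrix, state: DiscreteState) -> np.ndarray:
    """Signed net (up minus down allocated genes) for every pathway."""
    if alloc.entries.shape[0] != len(state):
        raise InputError("allocation and state are not aligned")
    return alloc.entries.T.astype(np.int64) @ state.states.astype(np.int64)


def pathway_net(alloc: AllocationMatrix, state: DiscreteState, pathway_index: int) -> int:
    """Signed net of a single pathway."""
    n_pathways = alloc.entries.shape[1]
    if not (0 <= pathway_index < n_pathways):
        raise InputError(f"pathway index {pathway_index} out of range [0, {n_pathways})")
    return int(alloc.entries[:, pathway_index].astype(np.int64) @ state.states)


def total_fitness(alloc: AllocationMatrix, state: DiscreteState) -> FitnessValue:
    """Consensus fitness: sum over pathways of |net|."""
    nets = pathway_nets(alloc, state)
    return FitnessValue(total=int(np.abs(nets).sum()), per_pathway_net=nets)
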