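"""Heuristic searches over valid allocations.

Three metaheuristics maximise the per-pathway consensus fitness by moving
multi-membership genes between their member pathways:

* hill climbing — accepts any move that does not decrease fitness;
* simulated annealing — additionally accepts worsening moves with
  probability ``exp(-dF / T)`` under a geometric cooling schedule from
  ``T0 = 1`` to ``T_final = 0.01`` over the run;
* a genetic algorithm — elitist truncation selection over a population of
  allocations, with per-gene mutation and single-point crossover on the
  gene order (rows are inherited whole, so offspring are always valid).

Single-membership genes are pinned to their only pathway and stable genes
are excluded from the search state entirely; only expressed multi-membership
genes carry free allocation bits.  In module mode an add to one member of an
opposing pair evicts the gene from the paired module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AllocationMatrix,
    DiscreteState,
    MembershipMatrix,
    OpposingPairs,
    DEFAULT_SEED,
    random_valid_allocation,
    random_valid_row,
)
from .errors import InputError, ParameterError, PathallocError
from .fitness import FitnessValue, pathway_nets, total_fitness

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "Move",
    "NothingToOptimize",
    "acceptance_probability",
    "temperature_schedule",
    "propose_move",
    "hill_climb",
    "anneal",
    "mutate",
    "crossover",
    "ga_search",
    "search",
]

METHODS = ("hill_climbing", "simulated_annealing", "genetic")


class NothingToOptimize(PathallocError):
    """Raised when no expressed multi-membership gene exists to move."""


@dataclass(frozen=True)
class SearchConfig:
    """Parameters shared by the three searches.

    ``iterations`` drives hill climbing and annealing; ``population_size``
    and ``generations`` drive the genetic algorithm.  ``t0``/``t_final``
    are the annealing temperatures (defaults 1 and 0.01, adequate for the
    default 10000 iterations).  ``threshold`` is the log2-ratio cutoff used
    when discretizing expression upstream.
    """

    method: str = "simulated_annealing"
    iterations: int = 10_000
    t0: float = 1.0
    t_final: float = 0.01
    population_size: int = 100
    generations: int = 400
    threshold: float = 1.0
    seed: int | None = None
    mode: str = "pathway"

    def __post_init__(self):
        if self.method not in METHODS:
            raise ParameterError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")
        if not (0 < self.t_final < self.t0):
            raise ParameterError("temperatures must satisfy 0 < t_final < t0")
        if self.population_size < 2:
            raise ParameterError("population_size must be >= 2")
        if self.generations < 1:
            raise ParameterError("generations must be >= 1")
        if not (self.threshold > 0):
            raise ParameterError("threshold must be positive")
        if self.mode not in ("pathway", "module"):
            raise ParameterError(f"mode must be 'pathway' or 'module', got {self.mode!r}")


@dataclass(frozen=True)
class Move:
    """A single proposed change to one gene's allocation row."""

    gene_index: int
    pathway_index: int
    action: str  # "add" | "remove"
    forced_reassignment: int | None = None


@dataclass(frozen=True)
class SearchResult:
    """Outcome of one search run."""

    best_allocation: AllocationMatrix
    best_fitness: FitnessValue
    fitness_trace: np.ndarray
    convergence_iteration: int
    seed: int | None
    method: str
    n_fitness_evaluations: int


def acceptance_probability(fitness_loss: float, temperature: float) -> float:
    """Probability of accepting a move that loses ``fitness_loss`` fitness.

    Improving or fitness-preserving moves (loss <= 0) are accepted with
    probability 1; a loss of dF is accepted with probability exp(-dF / T).
    """
    if not (temperature > 0):
        raise ParameterError(f"temperature must be positive, got {temperature}")
    if fitness_loss <= 0:
        return 1.0
    return math.exp(-fitness_loss / temperature)


def temperature_schedule(t: int, config: SearchConfig) -> float:
    """Geometric cooling: ``T_t = T0 * lambda**t`` with
    ``lambda = exp((ln T_final - ln T0) / iterations)`` so that ``T_0 = T0``
    and ``T_iterations = T_final``."""
    lam = math.exp((math.log(config.t_final) - math.log(config.t0)) / config.iterations)
    return config.t0 * lam ** t


# ---------------------------------------------------------------------------
# Internal search-state machinery


class _Problem:
    """Precomputed immutable context shared by all searches."""

    def __init__(self, membership: MembershipMatrix, state: DiscreteState,
                 opposing: OpposingPairs | None, mode: str):
        if len(state) != membership.n_genes:
            raise InputError("state length does not match membership")
        if opposing:
            opposing.validate_against(membership)
        self.membership = membership
        self.state = state
        self.opposing = opposing if (opposing and mode == "module") else None
        self.mode = mode
        self.states = state.states.astype(np.int64)
        expressed = state.expressed_mask
        multi = membership.multi_mask
        self.free_genes: list[int] = [int(i) for i in np.flatnonzero(expressed & multi)]
        self.members: dict[int, np.ndarray] = {
            i: membership.members_of(i) for i in self.free_genes
        }
        self.opponents: Mapping[int, tuple[int, ...]] = (
            self.opposing.opponents_by_column(membership) if self.opposing else {}
        )

    def initial_allocation(self, rng: np.random.Generator) -> AllocationMatrix:
        return random_valid_allocation(
            self.membership, self.state, self.opposing, rng, mode=self.mode
        )


class _AllocState:
    """Current allocation with incrementally maintained pathway nets."""

    __slots__ = ("entries", "nets", "total", "states")

    def __init__(self, entries: np.ndarray, states: np.ndarray):
        self.entries = entries
        self.states = states
        self.nets = entries.T.astype(np.int64) @ states
        self.total = int(np.abs(self.nets).sum())

    def apply(self, toggles: Sequence[tuple[int, int, int]]):
        """Apply ``(gene, pathway, new_value)`` toggles; return (delta, undo)."""
        delta = 0
        undo: list[tuple[int, int, int]] = []
        for i, j, v in toggles:
            cur = int(self.entries[i, j])
            if cur == v:
                continue
            x = int(self.states[i])
            old_net = int(self.nets[j])
            new_net = old_net + (x if v else -x)
            delta += abs(new_net) - abs(old_net)
            self.entries[i, j] = v
            self.nets[j] = new_net
            undo.append((i, j, cur))
        return delta, undo

    def revert(self, undo: Sequence[tuple[int, int, int]]):
        for i, j, v in reversed(undo):
            x = int(self.states[i])
            cur = int(self.entries[i, j])
            self.nets[j] += x if v > cur else (-x if v < cur else 0)
            self.entries[i, j] = v
        self.total = int(np.abs(self.nets).sum())


def _propose_toggles(entries: np.ndarray, problem: _Problem,
                     rng: np.random.Generator) -> tuple[Move, list[tuple[int, int, int]]]:
    """Draw one move: toggle a uniformly chosen (free gene, member pathway) bit.

    If the toggle would empty the gene's row, the gene is reassigned to a
    uniformly chosen member pathway.  Module mode: adds evict the gene from
    opposing modules.
    """
    if not problem.free_genes:
        raise NothingToOptimize("no expressed multi-membership gene to move")
    i = problem.free_genes[int(rng.integers(len(problem.free_genes)))]
    members = problem.members[i]
    j = int(members[int(rng.integers(len(members)))])
    toggles: list[tuple[int, int, int]]
    forced: int | None = None
    if entries[i, j]:
        action = "remove"
        toggles = [(i, j, 0)]
        if int(entries[i, members].sum()) == 1:
            # removal empties the row: reassign to a random member pathway
            # (possibly the same one, in which case the move is a no-op)
            forced = int(members[int(rng.integers(len(members)))])
            toggles.append((i, forced, 1))
            toggles.extend(_opposing_evictions(entries, problem, i, forced, exclude=j))
    else:
        action = "add"
        toggles = [(i, j, 1)]
        toggles.extend(_opposing_evictions(entries, problem, i, j))
    return Move(i, j, action, forced), toggles


def _opposing_evictions(entries: np.ndarray, problem: _Problem, gene: int,
                        added: int, exclude: int | None = None) -> list[tuple[int, int, int]]:
    out = []
    for opp in problem.opponents.get(added, ()):
        if opp != added and opp != exclude and entries[gene, opp]:
            out.append((gene, opp, 0))
    return out


def propose_move(alloc: AllocationMatrix, membership: MembershipMatrix,
                 state: DiscreteState, opposing: OpposingPairs | None,
                 rng: np.random.Generator) -> tuple[Move, AllocationMatrix]:
    """Propose one random move and return it with the resulting allocation."""
    problem = _Problem(membership, state, opposing, alloc.mode)
    move, toggles = _propose_toggles(alloc.entries, problem, rng)
    result = alloc.copy()
    for i, j, v in toggles:
        result.entries[i, j] = v
    return move, result


# ---------------------------------------------------------------------------
# Hill climbing and simulated annealing


def _climb(membership: MembershipMatrix, state: DiscreteState,
           opposing: OpposingPairs | None, config: SearchConfig,
           annealing: bool) -> SearchResult:
    problem = _Problem(membership, state, opposing, config.mode)
    root = np.random.default_rng(config.seed if config.seed is not None else DEFAULT_SEED)
    # separate streams so annealing's extra acceptance draws do not shift the
    # proposal sequence: at T -> 0 annealing replays hill climbing exactly
    init_rng, move_rng, accept_rng = root.spawn(3)
    alloc = problem.initial_allocation(init_rng)
    cur = _AllocState(alloc.entries.copy(), problem.states)
    best_entries = cur.entries.copy()
    best_total = cur.total
    trace = np.empty(config.iterations, dtype=np.int64)
    n_evals = 1
    lam = math.exp((math.log(config.t_final) - math.log(config.t0)) / config.iterations)
    temperature = config.t0

    if not problem.free_genes:
        logger.info("nothing to optimize: no expressed multi-membership genes")
        trace[:] = cur.total
        return SearchResult(
            best_allocation=AllocationMatrix(best_entries, mode=config.mode),
            best_fitness=total_fitness(AllocationMatrix(best_entries, mode=config.mode), state),
            fitness_trace=trace,
            convergence_iteration=0,
            seed=config.seed,
            method="simulated_annealing" if annealing else "hill_climbing",
            n_fitness_evaluations=n_evals,
        )

    for t in range(config.iterations):
        temperature *= lam
        _, toggles = _propose_toggles(cur.entries, problem, move_rng)
        delta, undo = cur.apply(toggles)
        n_evals += 1
        if delta < 0:
            accept = annealing and (
                accept_rng.random() < acceptance_probability(-delta, temperature)
            )
            if not accept:
                cur.revert(undo)
                delta = 0
        cur.total += delta
        if cur.total > best_total:
            best_total = cur.total
            best_entries = cur.entries.copy()
        trace[t] = best_total

    conv = int(np.argmax(trace == best_total))
    best_alloc = AllocationMatrix(best_entries, mode=config.mode)
    return SearchResult(
        best_allocation=best_alloc,
        best_fitness=total_fitness(best_alloc, state),
        fitness_trace=trace,
        convergence_iteration=conv,
        seed=config.seed,
        method="simulated_annealing" if annealing else "hill_climbing",
        n_fitness_evaluations=n_evals,
    )


def hill_climb(membership: MembershipMatrix, state: DiscreteState,
               opposing: OpposingPairs | None, config: SearchConfig) -> SearchResult:
    """Hill climbing: accept any move that does not strictly decrease fitness
    (plateau moves are accepted), so the current fitness is non-decreasing."""
    return _climb(membership, state, opposing, config, annealing=False)


def anneal(membership: MembershipMatrix, state: DiscreteState,
           opposing: OpposingPairs | None, config: SearchConfig) -> SearchResult:
    """Simulated annealing: like hill climbing but a fitness loss dF is
    accepted with probability exp(-dF / T) at the current temperature; the
    best-so-far allocation is tracked and returned."""
    return _climb(membership, state, opposing, config, annealing=True)


# ---------------------------------------------------------------------------
# Genetic algorithm


def _mutate_entries(entries: np.ndarray, problem: _Problem,
                    rng: np.random.Generator) -> None:
    """In-place per-gene mutation: each free gene mutates with probability
    1/(number of free genes); a flip emptying the row is redrawn."""
    n_free = len(problem.free_genes)
    if n_free == 0:
        return
    rate = 1.0 / n_free
    for i in problem.free_genes:
        if rng.random() >= rate:
            continue
        members = problem.members[i]
        while True:
            k = int(rng.integers(len(members)))
            j = int(members[k])
            if entries[i, j]:
                if int(entries[i, members].sum()) == 1:
                    continue  # flip would empty the row: redraw position
                entries[i, j] = 0
            else:
                entries[i, j] = 1
                for gi, gj, v in _opposing_evictions(entries, problem, i, j):
                    entries[gi, gj] = v
            break


def mutate(individual: AllocationMatrix, membership: MembershipMatrix,
           state: DiscreteState, rng: np.random.Generator,
           opposing: OpposingPairs | None = None) -> AllocationMatrix:
    """Return a mutated copy of ``individual`` (see :func:`_mutate_entries`)."""
    problem = _Problem(membership, state, opposing, individual.mode)
    out = individual.copy()
    _mutate_entries(out.entries, problem, rng)
    return out


def crossover(parent_a: AllocationMatrix, parent_b: AllocationMatrix,
              rng: np.random.Generator) -> tuple[AllocationMatrix, AllocationMatrix]:
    """Single-point crossover on the gene order.

    A cut point x is drawn in 1..N; child A takes gene rows 1..x from parent
    A and the rest from parent B, child B the complement.  Rows are inherited
    whole, so children are valid whenever the parents are.
    """
    if parent_a.shape != parent_b.shape or parent_a.mode != parent_b.mode:
        raise InputError("crossover parents must share shape and mode")
    n = parent_a.shape[0]
    x = int(rng.integers(1, n + 1))
    child_a = np.vstack([parent_a.entries[:x], parent_b.entries[x:]])
    child_b = np.vstack([parent_b.entries[:x], parent_a.entries[x:]])
    return (
        AllocationMatrix(child_a, mode=parent_a.mode),
        AllocationMatrix(child_b, mode=parent_a.mode),
    )


def _crossover_entries(a: np.ndarray, b: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    x = int(rng.integers(1, a.shape[0] + 1))
    return (
        np.vstack([a[:x], b[x:]]),
        np.vstack([b[:x], a[x:]]),
    )


def ga_search(membership: MembershipMatrix, state: DiscreteState,
              opposing: OpposingPairs | None, config: SearchConfig) -> SearchResult:
    """Elitist genetic algorithm.

    Each generation every parent is mutated; the mutated individuals are
    paired by a random permutation and crossed over pairwise; parents,
    mutated individuals and crossover offspring are pooled, sorted by fitness
    and truncated back to the population size.  Because parents stay in the
    pool, the per-generation best fitness never decreases.
    """
    problem = _Problem(membership, state, opposing, config.mode)
    rng = np.random.default_rng(config.seed if config.seed is not None else DEFAULT_SEED)
    states = problem.states

    def fit(entries: np.ndarray) -> int:
        return int(np.abs(entries.T.astype(np.int64) @ states).sum())

    population = [problem.initial_allocation(rng).entries.copy()
                  for _ in range(config.population_size)]
    fitnesses = [fit(e) for e in population]
    n_evals = len(population)
    trace = np.empty(config.generations, dtype=np.int64)

    if not problem.free_genes:
        logger.info("nothing to optimize: no expressed multi-membership genes")
        trace[:] = fitnesses[0]
        best = AllocationMatrix(population[0], mode=config.mode)
        return SearchResult(best, total_fitness(best, state), trace, 0,
                            config.seed, "genetic", n_evals)

    for gen in range(config.generations):
        mutated = []
        for entries in population:
            child = entries.copy()
            _mutate_entries(child, problem, rng)
            mutated.append(child)
        perm = rng.permutation(len(mutated))
        offspring = []
        for k in range(0, len(perm) - 1, 2):
            ca, cb = _crossover_entries(mutated[perm[k]], mutated[perm[k + 1]], rng)
            offspring.extend((ca, cb))
        pool = population + mutated + offspring
        pool_fit = fitnesses + [fit(e) for e in mutated + offspring]
        n_evals += len(mutated) + len(offspring)
        order = np.argsort(-np.asarray(pool_fit), kind="stable")[: config.population_size]
        population = [pool[k] for k in order]
        fitnesses = [pool_fit[k] for k in order]
        trace[gen] = fitnesses[0]

    conv = int(np.argmax(trace == trace[-1]))
    best = AllocationMatrix(population[0], mode=config.mode)
    return SearchResult(best, total_fitness(best, state), trace, conv,
                        config.seed, "genetic", n_evals)


def search(membership: MembershipMatrix, state: DiscreteState,
           config: SearchConfig,
           opposing: OpposingPairs | None = None) -> SearchResult:
    """Dispatch to the search named by ``config.method``."""
    if config.method == "hill_climbing":
        return hill_climb(membership, state, opposing, config)
    if config.method == "simulated_annealing":
        return anneal(membership, state, opposing, config)
    return ga_search(membership, state, opposing, config)
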