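"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pathalloc import (
    AllocationMatrix,
    DiscreteState,
    ExpressionVector,
    MembershipMatrix,
    OpposingPairs,
    discretize,
    opposing_module_fixture,
    tryptophan_fixture,
)


def brute_force_max_fitness(membership: MembershipMatrix, state: DiscreteState,
                            opposing: OpposingPairs | None = None) -> int:
    """Exhaustive enumeration of all valid allocations; returns the maximum
    consensus fitness.  Independent of the package's search machinery: it
    walks every combination of non-empty rows for the free genes directly."""
    states = state.states.astype(np.int64)
    expressed = state.expressed_mask
    counts = membership.membership_counts
    free = [int(i) for i in np.flatnonzero(expressed & (counts >= 2))]
    opponents = opposing.index_pairs(membership) if opposing else ()

    base = np.zeros(membership.n_pathways, dtype=np.int64)
    for i in np.flatnonzero(expressed & (counts == 1)):
        base[membership.members_of(int(i))[0]] += states[i]

    def rows_for(i: int):
        members = membership.members_of(i)
        out = []
        for code in range(1, 1 << len(members)):
            cols = [int(members[k]) for k in range(len(members)) if (code >> k) & 1]
            if opponents and any(a in cols and b in cols for a, b in opponents):
                continue
            out.append(cols)
        return out

    best = int(np.abs(base).sum())
    if not free:
        return best
    options = [rows_for(i) for i in free]
    for combo in itertools.product(*options):
        nets = base.copy()
        for i, cols in zip(free, combo):
            for j in cols:
                nets[j] += states[i]
        best = max(best, int(np.abs(nets).sum()))
    return best


def random_small_instance(seed: int, n_pathways: int = 4, max_free_bits: int = 12):
    """Random membership/state pair whose free allocation bits total <= 12,
    so exhaustive enumeration is the ground truth."""
    rng = np.random.default_rng(seed)
    m = n_pathways
    rows = []
    values = []
    # anchor genes keep every pathway non-empty
    for j in range(m):
        row = np.zeros(m, dtype=np.int8)
        row[j] = 1
        rows.append(row)
        values.append(float(rng.choice((-1, 1))) * 1.5)
    bits = 0
    while True:
        n_members = int(rng.integers(2, 4))
        if bits + n_members > max_free_bits:
            break
        row = np.zeros(m, dtype=np.int8)
        row[rng.choice(m, size=n_members, replace=False)] = 1
        rows.append(row)
        values.append(float(rng.choice((-1, 1))) * (1.0 + rng.random() * 3))
        bits += n_members
    # a couple of stable genes for realism
    for _ in range(2):
        row = np.zeros(m, dtype=np.int8)
        row[rng.choice(m, size=2, replace=False)] = 1
        rows.append(row)
        values.append(float(rng.uniform(-0.9, 0.9)))
    n = len(rows)
    membership = MembershipMatrix(
        tuple(f"g{i}" for i in range(n)),
        tuple(f"pw{j}" for j in range(m)),
        np.array(rows, dtype=np.int8),
    )
    expression = ExpressionVector(np.array(values))
    return membership, discretize(expression, 1.0)


@pytest.fixture(scope="session")
def trp():
    """Tryptophan-metabolism fixture: 9 genes, 4-pathway miniature membership."""
    membership, expression = tryptophan_fixture()
    return membership, expression, discretize(expression, 1.0)


@pytest.fixture(scope="session")
def modules():
    """Opposing-module fixture (glycolysis vs gluconeogenesis style)."""
    membership, expression, opposing = opposing_module_fixture()
    return membership, expression, opposing, discretize(expression, 1.0)


@pytest.fixture()
def two_gene_shared():
    """One up and one down gene, both members of exactly pathways {A, B}."""
    membership = MembershipMatrix(
        ("up1", "down1"), ("pwA", "pwB"),
        np.array([[1, 1], [1, 1]], dtype=np.int8),
    )
    state = discretize(ExpressionVector(np.array([2.0, -2.0])), 1.0)
    return membership, state


def full_allocation(membership: MembershipMatrix, state: DiscreteState,
                    mode: str = "pathway") -> AllocationMatrix:
    """Allocation equal to the membership restricted to expressed genes."""
    entries = membership.entries.copy()
    entries[~state.expressed_mask] = 0
    return AllocationMatrix(entries, mode=mode)
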