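"""Reading and writing the package's text formats.

Inputs: gene-set membership as Broad-style GMT (one set per line: set id,
description, then gene ids, tab-separated) or two-column TSV (gene id, set
id); expression as two-column TSV of gene id and log2 ratio; opposing module
pairs as two-column TSV.  Outputs are diff-friendly TSVs whose header
comments record the package version, seed and a configuration hash, so
identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import __version__
from .core import (
    AllocationMatrix,
    DiscreteState,
    ExpressionVector,
    MembershipMatrix,
    OpposingPairs,
)
from .errors import FormatError, InputError
from .fitness import pathway_nets
from .stats import HammingNull

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_sets",
    "read_expression",
    "read_opposing_pairs",
    "read_allocation",
    "write_gene_sets",
    "write_expression",
    "write_allocation",
    "write_pathway_report",
    "write_trace",
    "write_null_distribution",
    "config_hash",
]


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.splitlines()


def config_hash(config: dict | object) -> str:
    """Short stable hash of a configuration mapping (or dataclass)."""
    if not isinstance(config, dict):
        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed, config) -> list[str]:
    return [
        f"# pathalloc {__version__}",
        f"# seed: {seed}",
        f"# config: {config_hash(config) if config is not None else 'none'}",
    ]


# ---------------------------------------------------------------------------
# Readers


def read_gene_sets(path: str | Path, dialect: str | None = None) -> MembershipMatrix:
    """Read a membership matrix from a GMT or two-column TSV file.

    ``dialect`` is ``"gmt"`` or ``"tsv"``; when omitted it is inferred from
    the file extension (``.gmt`` → GMT, otherwise TSV).  Gene and set order
    follow first appearance; duplicate (gene, set) pairs collapse to one
    membership with a logged warning.
    """
    path = Path(path)
    if dialect is None:
        dialect = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    if dialect not in ("gmt", "tsv"):
        raise FormatError(f"unknown gene-set dialect {dialect!r}")
    pairs: list[tuple[str, str]] = []  # (gene, set) in appearance order
    lines = _read_lines(path)
    n_dup = 0
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if dialect == "gmt":
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line needs set id, description and >= 1 gene, got "
                    f"{len(fields)} fields", line=lineno)
            set_id, genes = fields[0], fields[2:]
        else:
            if len(fields) != 2:
                raise FormatError(
                    f"TSV line needs exactly 2 columns (gene, set), got "
                    f"{len(fields)}", line=lineno)
            set_id, genes = fields[1], [fields[0]]
        for g in genes:
            if not g:
                continue
            key = (g, set_id)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            pairs.append(key)
    if not pairs:
        raise FormatError(f"no gene-set memberships found in {path}")
    if n_dup:
        logger.warning("%d duplicate (gene, set) pairs collapsed in %s", n_dup, path)
    gene_ids: list[str] = []
    pathway_ids: list[str] = []
    for g, s in pairs:
        if g not in gene_ids:
            gene_ids.append(g)
        if s not in pathway_ids:
            pathway_ids.append(s)
    entries = np.zeros((len(gene_ids), len(pathway_ids)), dtype=np.int8)
    gi = {g: i for i, g in enumerate(gene_ids)}
    pi = {s: j for j, s in enumerate(pathway_ids)}
    for g, s in pairs:
        entries[gi[g], pi[s]] = 1
    return MembershipMatrix(tuple(gene_ids), tuple(pathway_ids), entries)


def _parse_expression_rows(path: str | Path) -> list[tuple[str, float]]:
    rows: list[tuple[str, float]] = []
    seen: set[str] = set()
    lines = _read_lines(path)
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"expression line needs 2 columns (gene, log2 ratio), got "
                f"{len(fields)}", line=lineno)
        gene, raw = fields
        try:
            value = float(raw)
        except ValueError:
            if not rows and lineno == _first_data_lineno(lines):
                continue  # header row: non-numeric second field
            raise FormatError(f"non-numeric log2 ratio {raw!r}", line=lineno) from None
        if not np.isfinite(value):
            raise FormatError(f"non-finite log2 ratio {raw!r}", line=lineno)
        if gene in seen:
            raise FormatError(f"duplicate gene identifier {gene!r}", line=lineno)
        seen.add(gene)
        rows.append((gene, value))
    if not rows:
        raise FormatError(f"no expression rows found in {path}")
    return rows


def _first_data_lineno(lines: Sequence[str]) -> int:
    for lineno, line in enumerate(lines, start=1):
        if line.strip() and not line.startswith("#"):
            return lineno
    return 0


def read_expression(path: str | Path,
                    membership: MembershipMatrix | None = None,
                    ) -> ExpressionVector | list[tuple[str, float]]:
    """Read a two-column expression TSV.

    With a ``membership``, returns an :class:`ExpressionVector` aligned to
    the membership's gene order: genes absent from the membership are dropped
    (logged count), genes without a measurement are treated as stable (ratio
    0, logged).  Without a membership the raw (gene, value) rows are
    returned.  An optional header row is auto-detected by its non-numeric
    second field.
    """
    rows = _parse_expression_rows(path)
    if membership is None:
        return rows
    values = np.zeros(membership.n_genes, dtype=np.float64)
    index = {g: i for i, g in enumerate(membership.gene_ids)}
    measured = set()
    n_dropped = 0
    for gene, value in rows:
        i = index.get(gene)
        if i is None:
            n_dropped += 1
            continue
        values[i] = value
        measured.add(gene)
    if n_dropped:
        logger.warning("%d expression genes absent from the membership were dropped",
                       n_dropped)
    n_missing = membership.n_genes - len(measured)
    if n_missing:
        logger.warning("%d membership genes without a measurement treated as stable",
                       n_missing)
    return ExpressionVector(values)


def read_opposing_pairs(path: str | Path) -> OpposingPairs:
    """Read a two-column TSV of opposing module id pairs."""
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"opposing-pair line needs 2 columns, got {len(fields)}", line=lineno)
        pairs.append((fields[0], fields[1]))
    return OpposingPairs(pairs)


def read_allocation(path: str | Path, membership: MembershipMatrix,
                    mode: str = "pathway") -> AllocationMatrix:
    """Read an allocation written by :func:`write_allocation` back into a
    matrix aligned to ``membership``."""
    entries = np.zeros((membership.n_genes, membership.n_pathways), dtype=np.int8)
    header_skipped = False
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 4:
            raise FormatError(f"allocation line needs 4 columns, got {len(fields)}",
                              line=lineno)
        if not header_skipped:
            header_skipped = True
            if fields[2] == "allocated":
                continue
        gene, pathway, allocated, _state = fields
        try:
            flag = int(allocated)
        except ValueError:
            raise FormatError(f"non-integer allocation flag {allocated!r}",
                              line=lineno) from None
        if flag not in (0, 1):
            raise FormatError(f"allocation flag must be 0 or 1, got {flag}", line=lineno)
        entries[membership.gene_index(gene), membership.pathway_index(pathway)] = flag
    return AllocationMatrix(entries, mode=mode)


# ---------------------------------------------------------------------------
# Writers


def _write(path: str | Path, lines: Iterable[str]) -> None:
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def write_gene_sets(path: str | Path, membership: MembershipMatrix,
                    dialect: str = "gmt") -> None:
    """Write a membership matrix as GMT or two-column TSV."""
    lines: list[str] = []
    if dialect == "gmt":
        for j, pw in enumerate(membership.pathway_ids):
            genes = [membership.gene_ids[i]
                     for i in np.flatnonzero(membership.entries[:, j])]
            lines.append("\t".join([pw, "na", *genes]))
    elif dialect == "tsv":
        for i, g in enumerate(membership.gene_ids):
            for j in membership.members_of(i):
                lines.append(f"{g}\t{membership.pathway_ids[j]}")
    else:
        raise InputError(f"unknown gene-set dialect {dialect!r}")
    _write(path, lines)


def write_expression(path: str | Path, membership: MembershipMatrix,
                     expression: ExpressionVector) -> None:
    lines = ["gene\tlog2_ratio"]
    for g, v in zip(membership.gene_ids, expression.values):
        lines.append(f"{g}\t{v:.6g}")
    _write(path, lines)


def write_allocation(path: str | Path, alloc: AllocationMatrix,
                     membership: MembershipMatrix, state: DiscreteState,
                     seed=None, config=None) -> None:
    """Long-format allocation TSV: one row per (gene, member pathway) with the
    allocation flag and the gene's up/down/stable state."""
    lines = _header(seed, config)
    lines.append("gene\tpathway\tallocated\tstate")
    for i, g in enumerate(membership.gene_ids):
        for j in membership.members_of(i):
            lines.append(
                f"{g}\t{membership.pathway_ids[j]}\t{int(alloc.entries[i, j])}"
                f"\t{int(state.states[i]):+d}"
            )
    _write(path, lines)


def write_pathway_report(path: str | Path, alloc: AllocationMatrix,
                         membership: MembershipMatrix, state: DiscreteState,
                         seed=None, config=None) -> None:
    """Per-pathway summary: allocated up/down counts, member stable count,
    signed net and |net|.

    Stable genes are never allocated, so their count is taken from the
    membership: a stable gene is reported in every pathway it belongs to.
    """
    nets = pathway_nets(alloc, state)
    up = (alloc.entries * (state.states == 1)[:, None]).sum(axis=0)
    down = (alloc.entries * (state.states == -1)[:, None]).sum(axis=0)
    stable = (membership.entries * (state.states == 0)[:, None]).sum(axis=0)
    lines = _header(seed, config)
    lines.append("pathway\tn_up\tn_down\tn_stable\tnet\tabs_net")
    for j, pw in enumerate(membership.pathway_ids):
        lines.append(f"{pw}\t{up[j]}\t{down[j]}\t{stable[j]}\t{nets[j]}\t{abs(nets[j])}")
    _write(path, lines)


def write_trace(path: str | Path, trace: np.ndarray, method: str,
                seed=None, config=None) -> None:
    """Fitness trace TSV (iteration or generation index, best fitness)."""
    unit = "generation" if method == "genetic" else "iteration"
    lines = _header(seed, config)
    lines.append(f"{unit}\tbest_fitness")
    for t, f in enumerate(trace):
        lines.append(f"{t}\t{int(f)}")
    _write(path, lines)


def write_null_distribution(path: str | Path, null: HammingNull,
                            seed=None, config=None) -> None:
    """Exact null table: distance, combination count, probability."""
    lines = _header(seed, config)
    lines.append("distance\tcount\tprobability")
    probs = null.probabilities
    for r, count in enumerate(null.counts):
        lines.append(f"{r}\t{count}\t{probs[r]:.12g}")
    _write(path, lines)
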