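"""Synchronous Boolean network dynamics: attractors and basins, exhaustively.

A network on n variables induces a functional graph on the 2^n states
(every state has exactly one successor), so every weakly connected
component contains exactly one cycle — an attractor — and the component
is that attractor's basin.  Enumeration is exhaustive over all 2^n
states with a flat successor array and iterative traversals; the
default size guard is n <= 24 (the successor array itself is the
memory bound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boolfunc import TruthTable
from .encoding import decode_assignment

__all__ = [
    "BooleanNetwork",
    "Attractor",
    "AttractorReport",
    "step",
    "transition_map",
    "attractors_and_basins",
    "brute_force_report",
    "count_attractors_of_length",
    "network_to_bnet",
]

MAX_EXHAUSTIVE_VARS = 24


@dataclass(frozen=True)
class BooleanNetwork:
    """An n-tuple of update rules, one truth table per coordinate.

    Coordinate i is updated synchronously to
    ``functions[i-1](x_1, ..., x_n)``.  States use the shared
    integer encoding (coordinate i in bit i-1).
    """

    n_vars: int
    functions: tuple[TruthTable, ...]

    def __init__(self, n_vars: int, functions: Sequence[TruthTable]):
        functions = tuple(functions)
        if len(functions) != n_vars:
            raise ValueError(f"expected {n_vars} functions, got {len(functions)}")
        for f in functions:
            if f.n_vars != n_vars:
                raise ValueError(
                    f"all update rules must have {n_vars} variables, "
                    f"got one with {f.n_vars}"
                )
        object.__setattr__(self, "n_vars", int(n_vars))
        object.__setattr__(self, "functions", functions)

    def to_json_dict(self) -> dict:
        return {
            "n": self.n_vars,
            "functions": [f.to_json_dict() for f in self.functions],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "BooleanNetwork":
        return cls(
            int(d["n"]), [TruthTable.from_json_dict(x) for x in d["functions"]]
        )


@dataclass(frozen=True)
class Attractor:
    """One cycle of the state map with its basin size.

    ``states`` is the cycle in trajectory order, rotated so the smallest
    state index comes first.
    """

    states: tuple[int, ...]
    basin_size: int

    @property
    def length(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class AttractorReport:
    """All attractors of a network, sorted by their smallest state."""

    n_vars: int
    attractors: tuple[Attractor, ...]

    @property
    def num_attractors(self) -> int:
        return len(self.attractors)

    @property
    def total_attractor_size(self) -> int:
        return sum(a.length for a in self.attractors)

    def lengths(self) -> list[int]:
        return [a.length for a in self.attractors]

    def basin_sizes(self) -> list[int]:
        return [a.basin_size for a in self.attractors]

    def to_json_dict(self) -> dict:
        return {
            "n": self.n_vars,
            "attractors": [
                {
                    "states": list(a.states),
                    "length": a.length,
                    "basin_size": a.basin_size,
                }
                for a in self.attractors
            ],
        }


def step(net: BooleanNetwork, state: int) -> int:
    """Successor of one encoded state under the synchronous update."""
    if not 0 <= state < (1 << net.n_vars):
        raise ValueError(f"state {state} out of range for n={net.n_vars}")
    succ = 0
    for i, f in enumerate(net.functions):
        succ |= int(f.bits[state]) << i
    return succ


def transition_map(
    net: BooleanNetwork, max_vars: int = MAX_EXHAUSTIVE_VARS
) -> np.ndarray:
    """Flat successor array over all 2^n states (the functional graph)."""
    if net.n_vars > max_vars:
        raise ValueError(
            f"n={net.n_vars} exceeds the exhaustive-enumeration guard "
            f"({max_vars}); the state space would not fit"
        )
    succ = np.zeros(1 << net.n_vars, dtype=np.int64)
    for i, f in enumerate(net.functions):
        succ |= f.bits.astype(np.int64) << i
    return succ


def _canonical_cycle(cycle: Sequence[int]) -> tuple[int, ...]:
    """Rotate so the smallest state is first, preserving trajectory order."""
    i = int(np.argmin(cycle))
    return tuple(cycle[i:]) + tuple(cycle[:i])


def attractors_and_basins(
    net: BooleanNetwork, max_vars: int = MAX_EXHAUSTIVE_VARS
) -> AttractorReport:
    """Exhaustive attractor/basin report.

    Walks the successor array from each unvisited state, marking the
    path; hitting the current path closes a new cycle, hitting an
    already-labelled state attaches the path to that attractor's basin.
    Wholly iterative, O(2^n) time and memory.
    """
    succ = transition_map(net, max_vars=max_vars)
    n_states = succ.size
    UNSEEN, ON_PATH = -1, -2
    label = np.full(n_states, UNSEEN, dtype=np.int64)
    cycles: list[tuple[int, ...]] = []
    for s in range(n_states):
        if label[s] != UNSEEN:
            continue
        path: list[int] = []
        v = s
        while label[v] == UNSEEN:
            label[v] = ON_PATH
            path.append(v)
            v = int(succ[v])
        if label[v] == ON_PATH:
            start = path.index(v)
            cycles.append(_canonical_cycle(path[start:]))
            aid = len(cycles) - 1
        else:
            aid = int(label[v])
        for u in path:
            label[u] = aid
    basin_sizes = np.bincount(label, minlength=len(cycles))
    attractors = sorted(
        (
            Attractor(states=cyc, basin_size=int(basin_sizes[i]))
            for i, cyc in enumerate(cycles)
        ),
        key=lambda a: a.states[0],
    )
    return AttractorReport(net.n_vars, tuple(attractors))


def brute_force_report(net: BooleanNetwork, max_vars: int = 10) -> AttractorReport:
    """Independent oracle: find each state's cycle by plain trajectory iteration.

    For every state, apply :func:`step` until a state repeats; the
    segment from its first occurrence is the cycle.  Quadratic in the
    worst case, intended for cross-checking on small n.
    """
    if net.n_vars > max_vars:
        raise ValueError(f"brute-force oracle limited to n <= {max_vars}")
    n_states = 1 << net.n_vars
    basin_of: dict[tuple[int, ...], int] = {}
    for s in range(n_states):
        seen: dict[int, int] = {}
        traj: list[int] = []
        v = s
        while v not in seen:
            seen[v] = len(traj)
            traj.append(v)
            v = step(net, v)
        cycle = _canonical_cycle(traj[seen[v] :])
        basin_of[cycle] = basin_of.get(cycle, 0) + 1
    attractors = sorted(
        (Attractor(states=cyc, basin_size=b) for cyc, b in basin_of.items()),
        key=lambda a: a.states[0],
    )
    return AttractorReport(net.n_vars, tuple(attractors))


def count_attractors_of_length(
    net: BooleanNetwork,
    length: int,
    transition: np.ndarray | None = None,
) -> int:
    """Number of attractors of length exactly ``length``.

    For length 1 and 2 a fast path counts fixed points of the iterated
    map directly (a 2-cycle contributes two fixed points of the square
    and no fixed point of the map itself); longer lengths go through the
    full report.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if length <= 2:
        succ = transition if transition is not None else transition_map(net)
        states = np.arange(succ.size, dtype=np.int64)
        fixed1 = int(np.count_nonzero(succ == states))
        if length == 1:
            return fixed1
        fixed2 = int(np.count_nonzero(succ[succ] == states))
        return (fixed2 - fixed1) // 2
    report = attractors_and_basins(net)
    return sum(1 for a in report.attractors if a.length == length)


def _dnf_expression(f: TruthTable) -> str:
    """Disjunctive normal form over x1..xn from the table's minterms."""
    ones = np.flatnonzero(f.bits)
    if ones.size == 0:
        return "0"
    if ones.size == f.bits.size:
        return "1"
    terms = []
    for m in ones:
        assign = decode_assignment(int(m), f.n_vars)
        lits = [
            f"x{i + 1}" if v else f"!x{i + 1}" for i, v in enumerate(assign)
        ]
        terms.append(" & ".join(lits))
    return " | ".join(terms)


def network_to_bnet(net: BooleanNetwork) -> str:
    """Export to BoolNet-style .bnet text (export only).

    One line per node, update rule as a DNF over the minterms; constant
    rules are written as 0 or 1.
    """
    lines = ["targets, factors"]
    for i, f in enumerate(net.functions):
        lines.append(f"x{i + 1}, {_dnf_expression(f)}")
    return "\n".join(lines) + "\n"
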