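"""Shared brute-force oracles for the test suite.

Everything here is deliberately naive — enumeration and direct
definition-chasing — so it stays independent of the library code paths
it is used to check.
"""

from __future__ import annotations

import numpy as np

from canalnet.boolfunc import TruthTable


def table_from_int(n: int, m: int) -> TruthTable:
    """The truth table whose bit vector is the binary expansion of ``m``."""
    return TruthTable(n, [(m >> i) & 1 for i in range(1 << n)])


def all_truth_tables(n: int):
    """Every Boolean function on n variables (2^(2^n) of them)."""
    for m in range(1 << (1 << n)):
        yield table_from_int(n, m)


def oracle_restrictions_constant(f: TruthTable, var: int, val: int) -> bool:
    """Directly check f(.., x_var = val, ..) is constant by scanning assignments."""
    values = set()
    for m in range(1 << f.n_vars):
        if (m >> (var - 1)) & 1 == val:
            values.add(int(f.bits[m]))
    return len(values) == 1


def oracle_depth(f: TruthTable) -> int:
    """Canalizing depth by definition: try every peeling order recursively.

    Returns the common depth of all peel sequences and asserts that every
    choice of canalizing (variable, value) leads to the same answer.
    """
    if f.is_constant():
        return 0
    options = [
        (i, a)
        for i in range(1, f.n_vars + 1)
        for a in (0, 1)
        if oracle_restrictions_constant(f, i, a)
    ]
    if not options:
        return 0
    depths = set()
    for i, a in options:
        # restrict x_i to the NON-canalizing value 1-a, by table surgery
        sub = []
        for m in range(1 << f.n_vars):
            if (m >> (i - 1)) & 1 == 1 - a:
                sub.append(int(f.bits[m]))
        g = TruthTable(f.n_vars - 1, sub)
        depths.add(1 + oracle_depth(g))
    assert len(depths) == 1, "peeling order changed the depth"
    return depths.pop()


def enumerate_ordered_partitions(items: tuple):
    """All ordered partitions of ``items``: pick the first block, recurse."""
    items = tuple(items)
    if not items:
        yield ()
        return
    n = len(items)
    for mask in range(1, 1 << n):
        block = tuple(items[i] for i in range(n) if (mask >> i) & 1)
        remaining = tuple(x for x in items if x not in block)
        for tail in enumerate_ordered_partitions(remaining):
            yield (tuple(sorted(block)),) + tail


def random_table(rng: np.random.Generator, n: int) -> TruthTable:
    return TruthTable(n, rng.integers(0, 2, size=1 << n, dtype=np.uint8))
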