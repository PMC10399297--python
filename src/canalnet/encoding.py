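"""Shared assignment/state <-> integer encoding convention.

One convention is used everywhere in the package: variable ``x_i``
(1-based) is stored in bit ``i - 1`` of the integer, so ``x_1`` is the
least significant bit.  A truth table's entry at index ``m`` is the
function value on the assignment encoded by ``m``, and a network state
is encoded the same way.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def encode_assignment(assignment: Sequence[int]) -> int:
    """Encode a 0/1 assignment ``(x_1, ..., x_n)`` as an integer index."""
    m = 0
    for i, v in enumerate(assignment):
        if v not in (0, 1):
            raise ValueError(f"assignment entries must be 0 or 1, got {v!r}")
        m |= int(v) << i
    return m


def decode_assignment(m: int, n: int) -> tuple[int, ...]:
    """Decode index ``m`` into the assignment ``(x_1, ..., x_n)``."""
    if not 0 <= m < (1 << n):
        raise ValueError(f"index {m} out of range for {n} variables")
    return tuple((m >> i) & 1 for i in range(n))


def variable_bits(n: int, i: int) -> np.ndarray:
    """Value of variable ``x_i`` (1-based) on every assignment 0..2^n-1."""
    idx = np.arange(1 << n, dtype=np.int64)
    return ((idx >> (i - 1)) & 1).astype(np.uint8)
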