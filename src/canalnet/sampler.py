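"""Uniform random generation of canalizing-depth-k functions and networks.

The sampler is exactly uniform over its target class.  It rests on the
uniqueness of the layered decomposition: a depth-k function on n
variables corresponds one-to-one to a tuple (b, a-bits, k-subset X,
ordered partition of X into layers, noncanalizing nonzero core on the
complement) satisfying the two exceptional-case constraints, so drawing
each ingredient uniformly and rejecting the (rare) invalid tuples gives
the uniform distribution.  Ordered partitions are drawn uniformly via
the Fubini-number recurrence; noncanalizing cores by rejection from the
uniform distribution on all truth tables (canalizing functions are rare,
so acceptance is fast).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .boolfunc import (
    HMDecomposition,
    TruthTable,
    canalizing_certificates,
    hm_recompose,
)
from .dynamics import BooleanNetwork

__all__ = [
    "OrderedPartition",
    "SamplerConfig",
    "fubini_numbers",
    "sample_ordered_partition",
    "sample_noncanalizing",
    "sample_depth_k_function",
    "sample_network",
]

DEFAULT_MAX_REJECTIONS = 10_000


@dataclass(frozen=True)
class OrderedPartition:
    """An ordered partition of a finite index set into nonempty blocks."""

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        seen: set[int] = set()
        for block in self.blocks:
            if not block:
                raise ValueError("blocks must be nonempty")
            if seen.intersection(block):
                raise ValueError("blocks must be pairwise disjoint")
            seen.update(block)

    @property
    def ground_set(self) -> frozenset[int]:
        return frozenset(x for block in self.blocks for x in block)


@dataclass(frozen=True)
class SamplerConfig:
    """Sampler knobs: RNG seed (None = nondeterministic) and rejection cap."""

    seed: int | None = None
    max_rejections: int = DEFAULT_MAX_REJECTIONS

    def __post_init__(self):
        if self.max_rejections < 1:
            raise ValueError("max_rejections must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def fubini_numbers(k: int) -> list[int]:
    """Counts p_0..p_k of ordered partitions of an i-element set.

    p_0 = 1 and p_j = sum_{m=1}^{j} C(j, m) * p_{j-m} (choose the first
    block, order the rest).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    p = [1]
    for j in range(1, k + 1):
        p.append(sum(comb(j, m) * p[j - m] for m in range(1, j + 1)))
    return p


def _uniform_int(rng: np.random.Generator, n: int) -> int:
    """Exact uniform integer in [0, n), valid for arbitrarily large n."""
    nbits = n.bit_length()
    nbytes = (nbits + 7) // 8
    mask = (1 << nbits) - 1
    while True:
        v = int.from_bytes(rng.bytes(nbytes), "big") & mask
        if v < n:
            return v


def sample_ordered_partition(
    X: Sequence[int], rng: np.random.Generator
) -> OrderedPartition:
    """Uniform ordered partition of ``X`` into nonempty blocks.

    The first-block size j is drawn with probability
    C(k, j) p_{k-j} / p_k via a cumulative-threshold search over a
    uniform integer N in [1, p_k]; the block itself is a uniform
    j-subset, and the remainder is partitioned recursively.
    """
    items = sorted(set(X))
    if len(items) != len(X):
        raise ValueError("X must not contain repeats")
    if not items:
        raise ValueError("X must be nonempty")
    p = fubini_numbers(len(items))
    blocks: list[tuple[int, ...]] = []
    while items:
        k = len(items)
        N = _uniform_int(rng, p[k]) + 1
        total = 0
        for j in range(1, k + 1):
            total += comb(k, j) * p[k - j]
            if total >= N:
                break
        chosen = rng.choice(k, size=j, replace=False)
        block = tuple(sorted(items[i] for i in chosen))
        blocks.append(block)
        items = [x for x in items if x not in block]
    return OrderedPartition(tuple(blocks))


def sample_noncanalizing(
    m: int,
    rng: np.random.Generator,
    exclude_zero: bool = False,
    max_rejections: int = DEFAULT_MAX_REJECTIONS,
) -> TruthTable:
    """Uniform noncanalizing function on ``m`` variables by rejection.

    Draws uniform truth tables until one has no canalizing variable
    (constants qualify: canalization is defined only for nonconstant
    functions).  With ``exclude_zero`` the identically-zero function is
    also rejected, as required for decomposition cores.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    for _ in range(max_rejections):
        bits = rng.integers(0, 2, size=1 << m, dtype=np.uint8)
        f = TruthTable(m, bits)
        if exclude_zero and f.is_zero():
            continue
        if not canalizing_certificates(f):
            return f
    raise RuntimeError(
        f"no noncanalizing function accepted after {max_rejections} draws"
    )


def sample_depth_k_function(
    n: int,
    k: int,
    rng: np.random.Generator,
    max_rejections: int = DEFAULT_MAX_REJECTIONS,
) -> TruthTable:
    """Uniform Boolean function on ``n`` variables of canalizing depth exactly ``k``.

    For k >= 1: draw the layered-form ingredients uniformly (bit b,
    per-variable canalizing inputs, uniform k-subset, uniform ordered
    partition, noncanalizing nonzero core) and restart whenever the
    exceptional cases reject the tuple — i.e. when the core is
    identically 1 and either the last of r >= 2 layers is a singleton,
    or r = k = 1 with b = 1.  For k = 0: a uniform noncanalizing
    function (constants included).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return sample_noncanalizing(n, rng, max_rejections=max_rejections)
    for _ in range(max_rejections):
        b = int(rng.integers(2))
        a = {i: int(bit) for i, bit in zip(range(1, n + 1), rng.integers(2, size=n))}
        X = sorted(int(v) + 1 for v in rng.choice(n, size=k, replace=False))
        partition = sample_ordered_partition(X, rng)
        core_vars = tuple(v for v in range(1, n + 1) if v not in X)
        core = sample_noncanalizing(
            n - k, rng, exclude_zero=True, max_rejections=max_rejections
        )
        core_is_one = bool(np.all(core.bits == 1))
        r = len(partition.blocks)
        if core_is_one and r != 1 and len(partition.blocks[-1]) == 1:
            continue  # exceptional case (E1)
        if core_is_one and r == 1 and k == 1 and b == 1:
            continue  # exceptional case (E2)
        d = HMDecomposition(
            n_vars=n,
            b=b,
            layers=tuple(
                tuple((v, a[v]) for v in block) for block in partition.blocks
            ),
            core=core,
            core_vars=core_vars,
        )
        return hm_recompose(d)
    raise RuntimeError(f"no valid depth-{k} tuple after {max_rejections} restarts")


def sample_network(
    n: int,
    k: int,
    rng: np.random.Generator,
    max_rejections: int = DEFAULT_MAX_REJECTIONS,
) -> BooleanNetwork:
    """A random Boolean network of canalizing depth ``k``: n independent draws."""
    return BooleanNetwork(
        n,
        [
            sample_depth_k_function(n, k, rng, max_rejections=max_rejections)
            for _ in range(n)
        ],
    )
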