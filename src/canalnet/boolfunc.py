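"""Boolean functions as truth tables, canalization, and the unique layered form.

A Boolean function ``f(x_1, ..., x_n)`` is stored as the vector of its
2^n values (:class:`TruthTable`).  The module provides

* restriction of a variable to a constant,
* detection of canalizing variables (a variable ``x_i`` and input bit
  ``a`` such that fixing ``x_i = a`` makes ``f`` constant),
* the canalizing *depth* — how many variables can be peeled off this way
  before a noncanalizing remainder is reached, and
* the unique He--Macaulay layered decomposition

      f = M_1 (M_2 ( ... (M_r * p_C + 1) ... ) + 1) + b      (over GF(2))

  where each layer ``M_i`` is a product of literals ``(x_ij + a_ij)``,
  ``p_C`` is a noncanalizing, not-identically-zero core on the remaining
  variables, and ``b`` is a constant bit.  Arithmetic is modulo 2, so
  ``+`` is XOR and the product is AND.

Depth 0 means noncanalizing (constants included); depth n means nested
canalizing.  The decomposition exists and is unique for every nonzero
function, subject to two exceptional-case constraints:

  (E1) if ``p_C = 1`` and ``r != 1`` then the last layer has >= 2 variables;
  (E2) if ``p_C = 1``, ``r = 1`` and the single layer has 1 variable,
       then ``b = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encoding import encode_assignment, variable_bits

__all__ = [
    "TruthTable",
    "CanalizationCertificate",
    "HMDecomposition",
    "restrict",
    "canalizing_certificates",
    "canalizing_depth",
    "is_nested_canalizing",
    "hm_decompose",
    "hm_recompose",
]


class TruthTable:
    """A Boolean function on ``n_vars`` variables as a 2^n_vars bit vector.

    ``bits[m]`` is the function value on the assignment encoded by ``m``
    (variable ``x_i`` in bit ``i - 1``; see :mod:`canalnet.encoding`).
    """

    __slots__ = ("n_vars", "bits")

    def __init__(self, n_vars: int, bits: Sequence[int] | np.ndarray):
        if n_vars < 0:
            raise ValueError("n_vars must be >= 0")
        arr = np.asarray(bits, dtype=np.uint8)
        if arr.ndim != 1 or arr.size != (1 << n_vars):
            raise ValueError(
                f"expected {1 << n_vars} bits for {n_vars} variables, got {arr.size}"
            )
        if not np.all((arr == 0) | (arr == 1)):
            raise ValueError("truth table entries must be 0 or 1")
        self.n_vars = int(n_vars)
        self.bits = arr
        self.bits.setflags(write=False)

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_callable(cls, n_vars: int, fn) -> "TruthTable":
        """Tabulate ``fn(x_1, ..., x_n) -> 0/1`` over all assignments."""
        bits = np.empty(1 << n_vars, dtype=np.uint8)
        for m in range(1 << n_vars):
            bits[m] = fn(*(((m >> i) & 1) for i in range(n_vars))) & 1
        return cls(n_vars, bits)

    @classmethod
    def constant(cls, n_vars: int, value: int) -> "TruthTable":
        return cls(n_vars, np.full(1 << n_vars, value & 1, dtype=np.uint8))

    # -- basic queries -------------------------------------------------------

    def evaluate(self, assignment: Sequence[int]) -> int:
        """Value of the function on one assignment ``(x_1, ..., x_n)``."""
        if len(assignment) != self.n_vars:
            raise ValueError(
                f"assignment has length {len(assignment)}, expected {self.n_vars}"
            )
        return int(self.bits[encode_assignment(assignment)])

    def is_constant(self) -> bool:
        return bool(np.all(self.bits == self.bits[0]))

    def is_zero(self) -> bool:
        return not self.bits.any()

    def negate(self) -> "TruthTable":
        """The function ``1 + f`` (output negation)."""
        return TruthTable(self.n_vars, self.bits ^ 1)

    # -- equality / hashing --------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, TruthTable):
            return NotImplemented
        return self.n_vars == other.n_vars and bool(
            np.array_equal(self.bits, other.bits)
        )

    def __hash__(self) -> int:
        return hash((self.n_vars, self.bits.tobytes()))

    def __repr__(self) -> str:
        return f"TruthTable(n_vars={self.n_vars}, bits={self.bits.tolist()})"

    # -- serialization -------------------------------------------------------

    def to_json_dict(self) -> dict:
        """JSON form ``{"n": n, "bits": "<hex>"}``.

        The hex string has ``ceil(2^n / 4)`` nibbles, most significant
        first; bit ``m`` of the underlying integer is ``bits[m]``.
        """
        value = 0
        for m in np.flatnonzero(self.bits):
            value |= 1 << int(m)
        width = max(1, -(-(1 << self.n_vars) // 4))
        return {"n": self.n_vars, "bits": format(value, f"0{width}x")}

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthTable":
        n = int(d["n"])
        value = int(d["bits"], 16)
        bits = np.array([(value >> m) & 1 for m in range(1 << n)], dtype=np.uint8)
        return cls(n, bits)


@dataclass(frozen=True)
class CanalizationCertificate:
    """Witness that fixing ``variable = canalizing_input`` forces the output.

    ``variable`` is 1-based.  ``canalized_output`` is the constant value
    of the restricted function.
    """

    variable: int
    canalizing_input: int
    canalized_output: int


@dataclass(frozen=True)
class HMDecomposition:
    """The unique layered form of a nonzero Boolean function.

    ``layers[i]`` is the ordered layer ``M_{i+1}`` as a tuple of pairs
    ``(variable, a)`` — the literal ``(x_variable + a)`` — outermost
    layer first, variables within a layer sorted ascending.  ``core`` is
    ``p_C`` on the complement variables ``core_vars`` (ascending), with
    core bit ``j`` of the core-table index holding the value of
    ``core_vars[j]``.
    """

    n_vars: int
    b: int
    layers: tuple[tuple[tuple[int, int], ...], ...]
    core: TruthTable
    core_vars: tuple[int, ...]

    @property
    def depth(self) -> int:
        """Total number of layer variables (the canalizing depth k)."""
        return sum(len(layer) for layer in self.layers)

    @property
    def r(self) -> int:
        """Number of layers."""
        return len(self.layers)

    def core_is_one(self) -> bool:
        return bool(np.all(self.core.bits == 1))

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        layer_vars = [v for layer in self.layers for v, _ in layer]
        all_vars = layer_vars + list(self.core_vars)
        if sorted(all_vars) != list(range(1, self.n_vars + 1)):
            raise ValueError(
                "layer and core variables must partition {1..n} without repeats"
            )
        if any(len(layer) == 0 for layer in self.layers):
            raise ValueError("layers must be nonempty")
        if self.core.n_vars != len(self.core_vars):
            raise ValueError("core variable count mismatch")
        if self.b not in (0, 1):
            raise ValueError("b must be a bit")
        for layer in self.layers:
            for _, a in layer:
                if a not in (0, 1):
                    raise ValueError("layer a-bits must be 0 or 1")
        if self.core.is_zero():
            raise ValueError("core must not be identically 0")
        if canalizing_certificates(self.core):
            raise ValueError("core must be noncanalizing")
        if self.r > 0:
            if self.core_is_one():
                if self.r != 1 and len(self.layers[-1]) < 2:
                    raise ValueError(
                        "exceptional case violated: constant-1 core with r != 1 "
                        "requires the last layer to have >= 2 variables"
                    )
                if self.r == 1 and len(self.layers[0]) == 1 and self.b != 0:
                    raise ValueError(
                        "exceptional case violated: constant-1 core with a single "
                        "1-variable layer requires b = 0"
                    )
        else:
            if self.b != 0:
                raise ValueError("layerless decomposition must have b = 0")


def restrict(f: TruthTable, variable: int, value: int) -> TruthTable:
    """Fix ``x_variable = value``; remaining variables keep relative order."""
    if not 1 <= variable <= f.n_vars:
        raise ValueError(f"variable {variable} out of range 1..{f.n_vars}")
    if value not in (0, 1):
        raise ValueError("value must be 0 or 1")
    # axis order of the reshaped cube is (x_n, ..., x_1)
    cube = f.bits.reshape((2,) * f.n_vars)
    sub = np.take(cube, value, axis=f.n_vars - variable)
    return TruthTable(f.n_vars - 1, np.ascontiguousarray(sub).ravel())


def canalizing_certificates(f: TruthTable) -> list[CanalizationCertificate]:
    """All (variable, input, output) canalization witnesses of ``f``.

    Empty for constants: canalization is defined only for nonconstant
    functions.
    """
    if f.is_constant():
        return []
    certs = []
    cube = f.bits.reshape((2,) * f.n_vars)
    for i in range(1, f.n_vars + 1):
        axis = f.n_vars - i
        for a in (0, 1):
            sub = np.take(cube, a, axis=axis)
            first = int(sub.flat[0])
            if bool(np.all(sub == first)):
                certs.append(CanalizationCertificate(i, a, first))
    return certs


def _peel_layer(
    g: TruthTable, var_map: list[int]
) -> tuple[list[tuple[int, int]], int, TruthTable]:
    """Remove the full outer layer of ``g``.

    Returns the layer as (original variable, a)-pairs sorted by variable,
    the shared canalized output, and the restricted remainder.  ``var_map``
    is updated in place (local index -> original variable).
    """
    certs = canalizing_certificates(g)
    if not certs:
        raise ValueError("function has no canalizing variable")
    by_var: dict[int, CanalizationCertificate] = {}
    for c in certs:
        if c.variable in by_var:
            # both inputs of one variable canalize: g is a single literal
            # x + c; the unique valid representation forces output 0 (E2)
            if len({c.variable for c in certs}) != 1:
                raise AssertionError(
                    "internal inconsistency: literal certificate mixed with others"
                )
            chosen = next(c for c in certs if c.canalized_output == 0)
            by_var = {chosen.variable: chosen}
            break
        by_var[c.variable] = c
    outputs = {c.canalized_output for c in by_var.values()}
    if len(outputs) > 1:
        raise AssertionError(
            "internal inconsistency: one layer with distinct canalized outputs"
        )
    output = outputs.pop()
    layer = sorted(
        (var_map[c.variable - 1], c.canalizing_input) for c in by_var.values()
    )
    # restrict at the NON-canalizing input, highest local index first so
    # the local indices of later restrictions stay valid
    for c in sorted(by_var.values(), key=lambda c: -c.variable):
        g = restrict(g, c.variable, 1 - c.canalizing_input)
        del var_map[c.variable - 1]
    return layer, output, g


def canalizing_depth(f: TruthTable, rng: np.random.Generator | None = None) -> int:
    """The canalizing depth ``k`` of ``f`` (0 for noncanalizing functions).

    Peels canalizing variables one at a time — restrict at the
    *non*-canalizing input and repeat until no variable canalizes.  The
    result is independent of the peeling order; pass ``rng`` to exercise
    a random order (used by the property tests), otherwise whole layers
    are peeled deterministically.
    """
    g = f
    depth = 0
    while True:
        certs = canalizing_certificates(g)
        if not certs:
            return depth
        if rng is not None:
            c = certs[int(rng.integers(len(certs)))]
            g = restrict(g, c.variable, 1 - c.canalizing_input)
            depth += 1
        else:
            var_map = list(range(1, g.n_vars + 1))
            layer, _, g = _peel_layer(g, var_map)
            depth += len(layer)


def is_nested_canalizing(f: TruthTable) -> bool:
    """True iff the depth equals the number of variables (constant core)."""
    return not f.is_constant() and canalizing_depth(f) == f.n_vars


def hm_decompose(f: TruthTable) -> HMDecomposition:
    """Compute the unique layered (He--Macaulay) form of a nonzero function.

    Layer 1 collects *all* canalizing variables of ``f`` (they provably
    share one canalized output, which is ``b``); subsequent layers come
    from the successive restrictions, whose canalized outputs alternate
    ``b, 1+b, b, ...``.  The core is the final noncanalizing remainder
    XOR-corrected by the last layer's output so that
    :func:`hm_recompose` is bit-exact.  Noncanalizing input: ``r = 0``,
    ``b = 0``, ``core = f``.
    """
    if f.is_zero():
        raise ValueError(
            "the identically-zero function has no layered decomposition"
        )
    g = f
    var_map = list(range(1, f.n_vars + 1))
    layers: list[tuple[tuple[int, int], ...]] = []
    outputs: list[int] = []
    while canalizing_certificates(g):
        layer, output, g = _peel_layer(g, var_map)
        if outputs and output != 1 - outputs[-1]:
            raise AssertionError(
                "internal inconsistency: canalized outputs must alternate"
            )
        layers.append(tuple(layer))
        outputs.append(output)
    if layers:
        b = outputs[0]
        core = TruthTable(g.n_vars, g.bits ^ outputs[-1])
    else:
        b = 0
        core = g
    d = HMDecomposition(
        n_vars=f.n_vars,
        b=b,
        layers=tuple(layers),
        core=core,
        core_vars=tuple(var_map),
    )
    d.validate()
    return d


def hm_recompose(d: HMDecomposition) -> TruthTable:
    """Evaluate ``M_1(M_2(...(M_r p_C + 1)...)+1) + b`` on every assignment."""
    d.validate()
    n = d.n_vars
    size = 1 << n
    # core value per global assignment: core-table index packs core_vars ascending
    if d.core_vars:
        core_idx = np.zeros(size, dtype=np.int64)
        for j, v in enumerate(d.core_vars):
            core_idx |= variable_bits(n, v).astype(np.int64) << j
        val = d.core.bits[core_idx]
    else:
        val = np.full(size, int(d.core.bits[0]), dtype=np.uint8)
    for i, layer in reversed(list(enumerate(d.layers))):
        m = np.ones(size, dtype=np.uint8)
        for v, a in layer:
            m &= variable_bits(n, v) ^ a
        val = m & val
        if i > 0:
            val = val ^ 1
    return TruthTable(n, val ^ d.b)
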