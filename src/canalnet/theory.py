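"""Transfer-matrix limits for attractor counts in depth-one networks.

As the number of variables n grows, the expected number of length-ℓ
attractors of a random Boolean network of canalizing depth one tends to
a constant A_ℓ.  The constant is governed by a 2^ℓ x 2^ℓ
column-stochastic matrix G_ℓ indexed by the length-ℓ binary traces a
single coordinate can exhibit along a candidate cycle ("cycle
strings").  For strings α, β of length ℓ,

    f(α, β) = 2^(-|β|)  if α OR β = β (componentwise), else 0,
    g(α, β) = (f(α,β) + f(ᾱ,β) + f(α,β̄) + f(ᾱ,β̄)) / 4,
    (G_ℓ)_{a,b} = g(a, s(b)),

with |β| the number of ones, overbar the componentwise negation and s
the cyclic shift to the right.  Eigenvalue 1 of G_ℓ is simple, and

    A_ℓ = 1 / (ℓ · P'_{G_ℓ}(1)),

where P_{G_ℓ} is the characteristic polynomial.  Everything here is
exact rational arithmetic: entries of G_ℓ are dyadic rationals, the
characteristic polynomial is computed from the 2^(ℓ+2)-scaled integer
matrix, and A_ℓ comes out as an exact fraction.

For comparison, a uniformly random map on 2^n states has exactly
(1/ℓ)·∏_{i<ℓ}(2^n - i)/2^(nℓ) expected length-ℓ attractors, which tends
to 1/ℓ; the depth-one limit satisfies A_ℓ > 1/ℓ for ℓ > 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import sqrt

import numpy as np
import sympy

from .dynamics import count_attractors_of_length, transition_map
from .sampler import sample_network

__all__ = [
    "TransferMatrix",
    "LimitResult",
    "negate_string",
    "shift_right",
    "weight_f",
    "weight_g",
    "build_transfer_matrix",
    "char_poly",
    "attractor_limit",
    "expected_attractors_random",
    "monte_carlo_expected",
]

DEFAULT_ELL_CAP = 10


def _check_string(alpha: int, ell: int) -> None:
    if not 0 <= alpha < (1 << ell):
        raise ValueError(f"{alpha} is not a binary string of length {ell}")


def negate_string(alpha: int, ell: int) -> int:
    """Componentwise negation of a length-ℓ cycle string."""
    _check_string(alpha, ell)
    return alpha ^ ((1 << ell) - 1)


def shift_right(alpha: int, ell: int) -> int:
    """Cyclic shift to the right: position t takes the value of position t-1.

    Positions are 1-based with position t stored in bit t-1, so the
    shift rotates the bits up towards the most significant end.
    """
    _check_string(alpha, ell)
    mask = (1 << ell) - 1
    return ((alpha << 1) & mask) | (alpha >> (ell - 1))


def weight_f(alpha: int, beta: int, ell: int) -> Fraction:
    """2^(-|β|) if α ∨ β = β componentwise, else 0."""
    _check_string(alpha, ell)
    _check_string(beta, ell)
    if (alpha | beta) != beta:
        return Fraction(0)
    return Fraction(1, 1 << bin(beta).count("1"))


def weight_g(alpha: int, beta: int, ell: int) -> Fraction:
    """The negation-symmetrized average of the four f-terms."""
    na, nb = negate_string(alpha, ell), negate_string(beta, ell)
    return (
        weight_f(alpha, beta, ell)
        + weight_f(na, beta, ell)
        + weight_f(alpha, nb, ell)
        + weight_f(na, nb, ell)
    ) / 4


@dataclass(frozen=True)
class TransferMatrix:
    """The exact 2^ℓ x 2^ℓ matrix G_ℓ; entries are dyadic rationals."""

    ell: int
    entries: tuple[tuple[Fraction, ...], ...]

    @property
    def size(self) -> int:
        return 1 << self.ell


@dataclass(frozen=True)
class LimitResult:
    """A_ℓ with its characteristic-polynomial provenance.

    ``char_poly`` lists the coefficients of P_{G_ℓ} in descending degree
    order (leading coefficient 1); ``one_multiplicity`` is the algebraic
    multiplicity of eigenvalue 1.
    """

    ell: int
    A: Fraction
    char_poly: tuple[Fraction, ...]
    one_multiplicity: int

    def decimal(self, digits: int) -> str:
        """Decimal expansion of A_ℓ truncated (not rounded) to ``digits`` places."""
        scaled = (self.A.numerator * 10**digits) // self.A.denominator
        s = str(scaled).rjust(digits + 1, "0")
        return s[:-digits] + "." + s[-digits:] if digits else s


def build_transfer_matrix(ell: int, cap: int = DEFAULT_ELL_CAP) -> TransferMatrix:
    """Construct G_ℓ exactly: entry (a, b) = g(a, s(b)), indices 0..2^ℓ-1."""
    if not 1 <= ell <= cap:
        raise ValueError(f"need 1 <= ell <= {cap}, got {ell}")
    size = 1 << ell
    shifted = [shift_right(b, ell) for b in range(size)]
    entries = tuple(
        tuple(weight_g(a, shifted[b], ell) for b in range(size))
        for a in range(size)
    )
    return TransferMatrix(ell, entries)


def char_poly(G: TransferMatrix) -> tuple[Fraction, ...]:
    """Exact characteristic polynomial det(tI - G_ℓ), descending coefficients.

    Entries of G_ℓ have denominators dividing 2^(ℓ+2), so the polynomial
    of the integer matrix 2^(ℓ+2)·G_ℓ is computed and rescaled.
    """
    N = G.size
    c = G.ell + 2
    scale = 1 << c
    H = sympy.Matrix(
        N, N, lambda i, j: int(G.entries[i][j] * scale)
    )
    q = [int(x) for x in H.charpoly().all_coeffs()]  # descending, leading 1
    # det(tI - G) = scale^(-N) det((scale t)I - H)
    return tuple(Fraction(q[i], scale**i) for i in range(len(q)))


def _poly_eval(coeffs: tuple[Fraction, ...], t: Fraction) -> Fraction:
    acc = Fraction(0)
    for a in coeffs:
        acc = acc * t + a
    return acc


def _divide_by_t_minus_one(
    coeffs: tuple[Fraction, ...]
) -> tuple[tuple[Fraction, ...], Fraction]:
    """Synthetic division by (t - 1): returns (quotient, remainder)."""
    out: list[Fraction] = []
    acc = Fraction(0)
    for a in coeffs:
        acc = acc + a
        out.append(acc)
    return tuple(out[:-1]), out[-1]


def attractor_limit(ell: int, cap: int = DEFAULT_ELL_CAP) -> LimitResult:
    """The limiting expected number of length-ℓ attractors, A_ℓ, exactly.

    Verifies that 1 is a simple eigenvalue of G_ℓ (divide the
    characteristic polynomial by (t-1); the quotient must not vanish at
    1) and returns A_ℓ = 1/(ℓ·P'(1)).  With P = (t-1)·q, the derivative
    at 1 is exactly q(1).
    """
    G = build_transfer_matrix(ell, cap=cap)
    P = char_poly(G)
    q, rem = _divide_by_t_minus_one(P)
    if rem != 0:
        raise ArithmeticError("1 is not an eigenvalue of G_ell (column sums broken)")
    multiplicity = 1
    qq = q
    while True:
        qq2, rem2 = _divide_by_t_minus_one(qq)
        if rem2 != 0:
            break
        multiplicity += 1
        qq = qq2
    q1 = _poly_eval(q, Fraction(1))
    if multiplicity != 1 or q1 == 0:
        raise ArithmeticError(
            f"eigenvalue 1 of G_{ell} is not simple (multiplicity {multiplicity})"
        )
    A = Fraction(1) / (ell * q1)
    return LimitResult(ell=ell, A=A, char_poly=P, one_multiplicity=multiplicity)


def expected_attractors_random(n: int, ell: int) -> Fraction:
    """Exact expected number of length-ℓ attractors of a uniform random map.

    Over all maps {0,1}^n -> {0,1}^n:
    (1/ℓ)·∏_{i=0}^{ℓ-1}(2^n - i) / 2^(nℓ); tends to 1/ℓ as n grows.
    """
    if ell < 1 or n < 1:
        raise ValueError("need ell >= 1 and n >= 1")
    num = 1
    for i in range(ell):
        num *= (1 << n) - i
    return Fraction(num, ell) / Fraction(1 << (n * ell))


def monte_carlo_expected(
    n: int,
    k: int,
    ell: int,
    samples: int,
    rng: np.random.Generator,
    max_vars: int = 16,
) -> tuple[float, float]:
    """Sample mean ± standard error of the number of length-ℓ attractors.

    Draws ``samples`` random depth-k networks on n variables and counts
    length-ℓ attractors in each.
    """
    if n > max_vars:
        raise ValueError(f"n={n} exceeds the Monte-Carlo guard ({max_vars})")
    if samples < 2:
        raise ValueError("need at least 2 samples for a standard error")
    counts = np.empty(samples, dtype=np.int64)
    for i in range(samples):
        net = sample_network(n, k, rng)
        if ell <= 2:
            counts[i] = count_attractors_of_length(
                net, ell, transition=transition_map(net)
            )
        else:
            counts[i] = count_attractors_of_length(net, ell)
    mean = float(np.mean(counts))
    se = float(np.std(counts, ddof=1) / sqrt(samples))
    return mean, se
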