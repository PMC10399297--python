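# Methods

## Model and conventions

A Boolean network is an n-tuple f = (f_1, …, f_n) of Boolean functions
on the same n variables, iterated synchronously: state a_{t+1} has
coordinate i equal to f_i(a_t). The state space {0,1}^n is identified
with the integers 0 … 2^n − 1 by one package-wide convention
(`canalnet.encoding`): variable/coordinate x_i occupies bit i − 1, so
x_1 is the least significant bit. Truth tables store the 2^n function
values indexed by this encoding; serialized tables pack the bit vector
into a hex string with bit m of the integer equal to entry m.

A nonconstant function is *canalizing* in x_i with input a if fixing
x_i = a makes it constant; the pair together with the forced output is
a canalization certificate. Constants have no certificates and depth 0
by convention — the definition applies only to nonconstant functions,
and this is stated rather than left implicit.

## The layered decomposition

Every f ≢ 0 has a unique representation over GF(2)

    f = M_1 (M_2 ( … (M_r · p_C + 1) … ) + 1) + b,

with layers M_i = Π_j (x_{i_j} + a_{i_j}), a noncanalizing core
p_C ≢ 0, and two exceptional-case constraints: (E1) if p_C ≡ 1 and
r ≠ 1 the last layer has at least two variables; (E2) if p_C ≡ 1,
r = 1 and the layer is a single variable, then b = 0. The canalizing
depth k is the total number of layer variables.

`hm_decompose` peels whole layers: layer 1 is the set of *all*
certificates of f (they provably share one canalized output, which is
b), and each subsequent layer is the full certificate set of the
restriction at the non-canalizing inputs. Two facts the implementation
asserts as internal invariants rather than assumes silently:

* successive layers' canalized outputs alternate b, 1 + b, b, …
  (unwrapping one "+1" per nesting level), so the core is the final
  remainder XOR the last layer's output;
* a remainder that is a single literal x + c (the one situation where
  one variable carries two certificates with different outputs) can
  only occur at the very first peel — in deeper positions the literal's
  variable would already have canalized the previous layer — and E2
  then forces the representation with output 0.

Within a layer variables are sorted ascending; this canonicalization
does not change the represented function (factors of a product
commute) but makes decompositions comparable in tests. Degenerate
functions are first-class: the core's variable set is the complement of
the layer variables whether or not the core truly depends on each of
them, which is the reading consistent with the uniform sampler below.
Constant-1 cores on nonempty variable sets are therefore legal; a
function has maximal depth n exactly when its core is the constant 1 on
the *empty* set.

`hm_recompose` evaluates the nested form vectorized over all 2^n
assignments and is the bit-exact inverse (verified exhaustively for
n ≤ 3 and on random 6-variable functions).

## Uniform sampling of depth-k functions

The decomposition's uniqueness turns uniform generation into uniform
generation of the ingredient tuple: a bit b, canalizing inputs a_i, a
uniform k-subset X of the variables, a uniform ordered partition of X
into layers, and a uniform noncanalizing nonzero core on the
complement. Tuples violating E1/E2 are discarded and the whole draw is
restarted, which preserves uniformity exactly; rejection happens only
when the core came out identically 1, so restarts are rare.

Ordered partitions are drawn with the Fubini numbers p_j (p_0 = 1,
p_j = Σ_{m=1}^{j} C(j, m) p_{j−m}): the first-block size j is selected
by locating a uniform integer N ∈ [1, p_k] in the cumulative sums
Σ_{i≤j} C(k, i) p_{k−i}, giving P(|X_1| = j) = C(k, j) p_{k−j}/p_k,
then a uniform j-subset is taken and the remainder partitioned
recursively. The uniform integer is drawn exactly (rejection on raw
random bytes), so the procedure is correct for arbitrarily large p_k.

Noncanalizing functions are drawn by rejection from the uniform
distribution on all 2^(2^m) truth tables; the acceptance probability is
3/16 at m = 2 and rises towards 1 with m, and the loop is capped at
10,000 attempts (configurable) to fail loudly rather than spin.

Depth 0 means "noncanalizing" with the constants included — the
depth-0 ensemble is the natural baseline ensemble and is nearly the
uniform ensemble, since canalizing functions are a vanishing fraction.
All randomness flows through one caller-supplied numpy `Generator`; no
global state is touched, so every experiment is reproducible from its
seed.

## Attractors and basins

The synchronous dynamics is a functional graph on 2^n states (stored as
one flat successor array; hard cap n ≤ 24, which is the memory limit of
the representation). Each weakly connected component contains exactly
one cycle — an attractor — whose basin is the whole component.
Enumeration walks from every unvisited state along successors, marking
the path: closing into the current path yields a new cycle, hitting a
labelled state attaches the path to that basin. All traversals are
iterative (no recursion, safe at 2^20+ states). Cycles are rotated so
their smallest state leads, and attractors are sorted by that state, so
reports are deterministic and comparable. An independent trajectory-
iteration oracle (`brute_force_report`) recomputes the same report
naively for n ≤ 10 and agrees on hundreds of random networks.

Counts of length-1 and length-2 attractors use a closed-form fast
path — fixed points of the map and of its square — which is what makes
the Monte-Carlo validation below cheap at n = 14.

## Ensemble statistics

For a network f, N(f) is its number of attractors, S(f) the summed
attractor lengths, AS(f) = S(f)/N(f) (kept as an exact fraction
per network; cell means are floating point; CSV emits 6 decimals).
`run_sweep` samples and summarizes every (n, depth) cell with a seed
stream derived from (seed, n, depth), so cells are reproducible
independently of the grid they appear in. The relative-decrease ratios
divide a cell's mean by the depth-0 mean of the same n. Histograms use
unit-width integer bins for N(f) and fixed 0.25-wide bins for AS(f) (a
documented choice; nothing downstream depends on it).

Default experiment scale is deliberately desk-sized: the shipped tests
and acceptance run use n = 8 with 2000 networks per depth cell
(depths 0, 1, 3, 8) and n = 12/14 with 2000/1000 networks for the
Monte-Carlo checks. At this scale the qualitative effects of
canalizing depth — fewer and smaller attractors, with most of the
change already realized at depth 1 — are clearly resolved (the means
separate by many standard errors), while a full run of millions of
networks at n up to 20 is left to users with more compute via the CLI
flags.

## Transfer-matrix limits

For depth-one networks the expected number of length-ℓ attractors
converges, as n → ∞, to a constant A_ℓ determined by a
2^ℓ × 2^ℓ matrix over the "cycle strings" — the binary trace one
coordinate shows along a candidate ℓ-cycle. With |β| the number of
ones, ᾱ the componentwise negation and s the cyclic shift to the right,

    f(α, β) = 2^(−|β|) if α ∨ β = β else 0,
    g(α, β) = (f(α,β) + f(ᾱ,β) + f(α,β̄) + f(ᾱ,β̄))/4,
    (G_ℓ)_{a,b} = g(a, s(b)),   indices 0 … 2^ℓ − 1,

and A_ℓ = 1/(ℓ · P'(1)) with P the characteristic polynomial of G_ℓ.
Strings are encoded with position t in bit t − 1; the convention is
pinned down by reproducing the known 4 × 4 matrix for ℓ = 2 entry for
entry and the closed fraction A_3 = 64/189.

Everything is exact: entries of G_ℓ are dyadic rationals with
denominators dividing 2^(ℓ+2), so the characteristic polynomial is
computed (via sympy) for the integer matrix 2^(ℓ+2)·G_ℓ and rescaled to
`Fraction` coefficients. Since columns sum to 1, (t − 1) divides P
exactly; synthetic division gives q with P'(1) = q(1), and the
implementation verifies that eigenvalue 1 is algebraically simple
(repeated division by (t − 1)) before reporting A_ℓ = 1/(ℓ·q(1)) as an
exact rational. An independent floating-point eigenvalue route
(1/(ℓ·Π_{λ≠1}(1 − λ))) cross-checks the values in the tests. The
default cap is ℓ ≤ 10 (a 1024 × 1024 exact characteristic polynomial is
the practical desk limit); ℓ = 6 takes well under a minute.

The resulting exact values begin A_1 = 1, A_2 = 2/3, A_3 = 64/189,
A_4 = 16384/57375, and satisfy A_ℓ > 1/ℓ for every ℓ > 1 — the
comparison point being a uniformly random map on 2^n states, whose
expected number of length-ℓ attractors is exactly
(1/ℓ)·Π_{i<ℓ}(2^n − i)/2^(nℓ) → 1/ℓ. The margin is tightest at ℓ = 5
(0.20039… vs 0.2), which the test suite checks exactly rather than in
floating point.

`monte_carlo_expected` validates the limit at finite n: sample means
over depth-one networks approach A_ℓ as n grows, and the package's
standard check uses 3 standard errors (plus a 0.03 finite-size
allowance for ℓ = 2 at n = 14, where the O(1/2^n)-type bias is not yet
negligible relative to the Monte-Carlo error).

## What the synthetic ensembles do and do not show

All inputs are self-generated: the random ensembles *are* the objects
of study, not stand-ins for data. Passing tests therefore certify the
mathematics (uniformity of the samplers against brute-force enumerated
classes, exactness of decomposition and enumeration, the analytic
limits) and the qualitative depth effects in those ensembles. They do
not certify anything about networks with biological in-degree
structure: real regulatory rules are sparse (few essential inputs per
gene), while these ensembles draw unrestricted n-input rules of given
depth. Combining canalizing depth with sparsity is out of scope here.

## Numerical and design choices

* Exact arithmetic (`fractions.Fraction`, integer sympy polynomials)
  everywhere a printed constant is reproduced; floats appear only in
  Monte-Carlo summaries and CSV output.
* Goodness-of-fit checks in the tests use chi-square at significance
  0.001 on ≥ 30,000 draws with fixed seeds; where several marginals are
  tested jointly their p-values are combined with Fisher's method.
* Degenerate inputs: constants are depth 0; the identically-zero
  function has no decomposition and raising on it is part of the
  contract; empty attractor reports are impossible for a functional
  graph and are rejected.
* The `.bnet` export writes each rule as the disjunction of its
  minterms (constants as `0`/`1`). It is export-only — a round-trip
  parser is not part of the package.
* Known limitations: no asynchronous/probabilistic update semantics, no
  symbolic (BDD/SAT) attractor detection for large n, no closed-form
  counting of depth-k classes, and no depth-k analogue of the ℓ-limit
  formula beyond k = 1 (none is known to us).
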