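# canalnet

Canalizing Boolean networks, exactly and at random.

Boolean networks are a standard modelling framework for gene regulatory
networks: n genes, each updated synchronously by a Boolean rule of the
current state, so the dynamics is a map on the 2^n states whose cycles
(attractors) are read as cell types and whose basins measure their
robustness. Published models are strongly enriched for *canalizing*
rules — rules with a variable and an input value that alone forces the
output. Applying canalization recursively assigns every Boolean
function a **canalizing depth** k: noncanalizing functions (XOR-like,
constants) have k = 0, and *nested canalizing* functions have the
maximal k = n. `canalnet` is a toolkit for studying how this depth
shapes network dynamics. For modellers it answers: how many attractors
should I expect from rules of a given depth, how large are they, and
how much does pushing depth beyond 1 actually buy?

## What is inside

* **`canalnet.boolfunc`** — truth-table functions, canalization
  certificates, exact canalizing depth, and the unique layered
  decomposition over GF(2)

      f = M1 (M2 ( … (Mr · pC + 1) … ) + 1) + b,

  with layers `Mi = Π (x_ij + a_ij)`, a noncanalizing nonzero core
  `pC`, and bit-exact recomposition.
* **`canalnet.sampler`** — *uniform* random generation of functions of
  exact depth k (via the decomposition's uniqueness), of noncanalizing
  functions (rejection), of ordered set partitions (Fubini-number
  thresholds), and of depth-k networks.
* **`canalnet.dynamics`** — exhaustive attractor and basin enumeration
  over all 2^n states (functional-graph cycle detection, basins =
  weakly connected components), plus a BoolNet-style `.bnet` export.
* **`canalnet.stats`** — ensemble sweeps over (n, depth) cells with the
  summary statistics N(f) (number of attractors), S(f) (total attractor
  size) and AS(f) = S(f)/N(f), per-cell means, relative-decrease ratios
  N_k(n), AS_k(n), and empirical distributions; CSV output.
* **`canalnet.theory`** — the exact transfer matrix G_ℓ (a 2^ℓ × 2^ℓ
  column-stochastic matrix over the length-ℓ binary cycle strings), its
  exact characteristic polynomial P, and the limiting expected number
  of length-ℓ attractors of a random depth-one network,

      A_ℓ = 1 / (ℓ · P'(1)),

  as an exact rational, together with the uniform-random-map baseline
  (1/ℓ)·Π_{i<ℓ}(2^n − i)/2^(nℓ) → 1/ℓ and Monte-Carlo validation.

## Worked example

```python
>>> import numpy as np
>>> from canalnet import (TruthTable, canalizing_depth, hm_decompose,
...                       sample_network, attractors_and_basins, attractor_limit)
>>> f = TruthTable.from_callable(3, lambda x1, x2, x3: (x1 ^ x2) & x3)
>>> canalizing_depth(f)          # x3 = 0 forces 0; remainder x1+x2 is XOR
1
>>> d = hm_decompose(TruthTable.from_callable(3, lambda a, b, c: a & b & c))
>>> d.layers, d.b, d.depth       # x1 x2 x3 is nested canalizing
((((1, 0), (2, 0), (3, 0)),), 0, 3)
>>> net = sample_network(12, 1, np.random.default_rng(0))
>>> rep = attractors_and_basins(net)
>>> rep.num_attractors, rep.lengths(), rep.basin_sizes()
(2, [13, 12], [931, 3165])
>>> res = attractor_limit(2)
>>> res.A, res.decimal(4)
(Fraction(2, 3), '0.6666')
```

The sampled 12-gene depth-one network above has two attractors — a
13-cycle and a 12-cycle — whose basins (931 + 3165 = 2^12 states)
partition the state space; the last line says that as n → ∞ a random
depth-one network carries on average exactly 2/3 attractors of length 2
(a uniformly random map would carry 1/2).

The same functionality is scriptable:

```bash
canalnet generate --n 12 --depth 1 --count 5 --seed 0 --out nets.json
canalnet attractors --in nets.json --out report.json
canalnet experiment --n 8 --depths 0,1,3,8 --samples 2000 --seed 42 --out sweep.csv
canalnet summary --in sweep.csv --out means.csv
canalnet theory --ell 3
```

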