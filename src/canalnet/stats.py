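"""Summary statistics of random-network ensembles and the experiment sweep.

For a network f, ``N(f)`` is its number of attractors, ``S(f)`` the sum
of the attractor lengths, and ``AS(f) = S(f)/N(f)`` the average
attractor size.  ``run_sweep`` samples networks of each requested
(n, depth) cell, records these per network, and the helpers compute
per-cell sample means, the relative-decrease ratios

    N_k(n) = mean N at depth k / mean N at depth 0

(and the analogue for AS), and binned empirical distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import AttractorReport, attractors_and_basins
from .sampler import sample_network

__all__ = [
    "NetworkSummary",
    "SweepResult",
    "summarize",
    "run_sweep",
    "sample_means",
    "relative_decrease",
    "histogram",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "n",
    "depth",
    "sample_id",
    "seed",
    "num_attractors",
    "total_attractor_size",
    "avg_attractor_size",
    "attractor_sizes",
    "basin_sizes",
]


@dataclass(frozen=True)
class NetworkSummary:
    """Attractor statistics of one network: N(f), S(f), AS(f) and the raw sizes."""

    n: int
    depth: int
    sample_id: int
    seed: int
    num_attractors: int
    total_attractor_size: int
    attractor_sizes: tuple[int, ...]
    basin_sizes: tuple[int, ...]

    @property
    def avg_attractor_size(self) -> Fraction:
        """AS(f) = S(f)/N(f), kept exact."""
        return Fraction(self.total_attractor_size, self.num_attractors)


@dataclass(frozen=True)
class SweepResult:
    """Rows of :class:`NetworkSummary`, one per sampled network."""

    rows: tuple[NetworkSummary, ...]

    def to_dataframe(self) -> pd.DataFrame:
        records = [
            {
                "n": r.n,
                "depth": r.depth,
                "sample_id": r.sample_id,
                "seed": r.seed,
                "num_attractors": r.num_attractors,
                "total_attractor_size": r.total_attractor_size,
                "avg_attractor_size": float(r.avg_attractor_size),
                "attractor_sizes": ";".join(map(str, r.attractor_sizes)),
                "basin_sizes": ";".join(map(str, r.basin_sizes)),
            }
            for r in self.rows
        ]
        return pd.DataFrame(records, columns=CSV_COLUMNS)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df["avg_attractor_size"] = df["avg_attractor_size"].map(
            lambda x: f"{x:.6f}"
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        df = pd.read_csv(path)
        rows = tuple(
            NetworkSummary(
                n=int(r.n),
                depth=int(r.depth),
                sample_id=int(r.sample_id),
                seed=int(r.seed),
                num_attractors=int(r.num_attractors),
                total_attractor_size=int(r.total_attractor_size),
                attractor_sizes=tuple(
                    int(x) for x in str(r.attractor_sizes).split(";")
                ),
                basin_sizes=tuple(int(x) for x in str(r.basin_sizes).split(";")),
            )
            for r in df.itertuples()
        )
        return cls(rows)

    def cell(self, n: int, depth: int) -> list[NetworkSummary]:
        return [r for r in self.rows if r.n == n and r.depth == depth]


def summarize(
    report: AttractorReport, n: int, depth: int, sample_id: int = 0, seed: int = 0
) -> NetworkSummary:
    """Condense an attractor report into N(f), S(f) and the size lists."""
    if report.num_attractors == 0:
        raise ValueError("a valid functional graph always has an attractor")
    return NetworkSummary(
        n=n,
        depth=depth,
        sample_id=sample_id,
        seed=seed,
        num_attractors=report.num_attractors,
        total_attractor_size=report.total_attractor_size,
        attractor_sizes=tuple(report.lengths()),
        basin_sizes=tuple(report.basin_sizes()),
    )


def _cell_rng(seed: int, n: int, depth: int) -> np.random.Generator:
    # per-cell stream: cells are reproducible independently of grid shape
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(n, depth))
    )


def run_sweep(
    ns: Sequence[int],
    depths: Sequence[int],
    samples: int,
    seed: int,
) -> SweepResult:
    """Sample and summarize ``samples`` networks for every (n, depth) cell.

    Cells with depth > n are invalid.  Deterministic for a fixed seed;
    each cell uses its own seed stream derived from (seed, n, depth).
    """
    for n in ns:
        for k in depths:
            if not 0 <= k <= n:
                raise ValueError(f"invalid cell: depth {k} with n={n}")
    rows: list[NetworkSummary] = []
    for n in ns:
        for k in depths:
            rng = _cell_rng(seed, n, k)
            logger.info("sweep cell n=%d depth=%d (%d samples)", n, k, samples)
            for i in range(samples):
                net = sample_network(n, k, rng)
                rows.append(
                    summarize(
                        attractors_and_basins(net), n, k, sample_id=i, seed=seed
                    )
                )
    return SweepResult(tuple(rows))


def sample_means(result: SweepResult) -> pd.DataFrame:
    """Per-cell means of N(f) and AS(f): columns n, depth, mean_n_attractors, mean_avg_size."""
    if not result.rows:
        raise ValueError("empty sweep result")
    df = result.to_dataframe()
    out = (
        df.groupby(["n", "depth"], as_index=False)
        .agg(
            mean_n_attractors=("num_attractors", "mean"),
            mean_avg_size=("avg_attractor_size", "mean"),
            samples=("num_attractors", "size"),
        )
        .sort_values(["n", "depth"], ignore_index=True)
    )
    return out


def relative_decrease(
    result: SweepResult, k: int, n: int
) -> tuple[float, float]:
    """(N_k(n), AS_k(n)): cell means at depth k divided by the depth-0 means."""
    base = result.cell(n, 0)
    cell = result.cell(n, k)
    if not base or not cell:
        raise ValueError(f"missing cell for n={n}: need depth 0 and depth {k}")
    mean = lambda rows, f: float(np.mean([f(r) for r in rows]))
    n_ratio = mean(cell, lambda r: r.num_attractors) / mean(
        base, lambda r: r.num_attractors
    )
    as_ratio = mean(cell, lambda r: float(r.avg_attractor_size)) / mean(
        base, lambda r: float(r.avg_attractor_size)
    )
    return n_ratio, as_ratio


# AS histograms use a fixed bin width so that distributions for different
# depths are directly comparable; the width is a documented choice.
AS_BIN_WIDTH = 0.25


def histogram(
    result: SweepResult, field: str, n: int, depth: int
) -> tuple[np.ndarray, np.ndarray]:
    """Binned empirical distribution of N(f) or AS(f) in one cell.

    ``field`` is ``"N"`` (unit-width integer bins) or ``"AS"``
    (fixed-width bins of :data:`AS_BIN_WIDTH`).  Returns
    ``(counts, bin_edges)``.
    """
    rows = result.cell(n, depth)
    if not rows:
        raise ValueError(f"empty cell n={n} depth={depth}")
    if field == "N":
        values = np.array([r.num_attractors for r in rows], dtype=float)
        edges = np.arange(0.5, values.max() + 1.5)
    elif field == "AS":
        values = np.array([float(r.avg_attractor_size) for r in rows])
        top = np.ceil(values.max() / AS_BIN_WIDTH) * AS_BIN_WIDTH
        edges = np.arange(0.0, top + AS_BIN_WIDTH, AS_BIN_WIDTH)
    else:
        raise ValueError(f"unknown field {field!r}; expected 'N' or 'AS'")
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges
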