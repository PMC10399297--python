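from __future__ import annotations

import numpy as np
import pytest

from canalnet.stats import run_sweep
from canalnet.theory import attractor_limit


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def limits():
    """Exact limiting attractor counts A_1..A_6, computed once per session."""
    return {ell: attractor_limit(ell) for ell in range(1, 7)}


@pytest.fixture(scope="session")
def sweep_n8():
    """Scaled-down ensemble sweep: n=8, depths 0/1/3/8, 2000 networks per cell."""
    return run_sweep([8], [0, 1, 3, 8], samples=2000, seed=42)
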