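import warnings

import numpy as np
import pytest

from introscan.simulate import SimParams, poolseq_noise
from introscan.poolstats import PoolSample
from introscan.windows import WindowSpec

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def design() -> SimParams:
    """The experimental design constants (carrying capacity 1500, 16
    generations, 80% bottleneck, 300 migrants, 30-diploid pools at 85x)."""
    return SimParams()


@pytest.fixture
def small_window() -> WindowSpec:
    sites = tuple(np.linspace(1, 150_000, 6).astype(int))
    return WindowSpec("2R", 1, 150_000, 2.0e-8, sites)


def make_pool(freqs, sample_id="P", role="wild", pool_diploids=30, depth=85, seed=0):
    """Pool with two-step binomial read noise at constant depth."""
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    d = np.full(freqs.size, depth)
    alt, total = poolseq_noise(freqs, pool_diploids, d, rng)
    return PoolSample(
        sample_id=sample_id,
        role=role,
        alt=alt,
        total=total,
        n_chromosomes=2 * pool_diploids,
        positions=np.arange(1, freqs.size + 1),
        arms=np.repeat("2R", freqs.size),
    )
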