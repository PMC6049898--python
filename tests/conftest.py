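import numpy as np
import pytest

from cpiem import PeakRecord
from cpiem.simulate import SimulationConfig, simulate_experiment


def peak(chrom="chr1", start=0, end=100, name=".", signal=1.0, summit=None):
    return PeakRecord(
        chrom=chrom, start=start, end=end, name=name, signal=signal,
        summit_offset=summit,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A 600-pair synthetic knockout experiment with total peak loss."""
    cfg = SimulationConfig(n_pairs=600, p_loss=1.0, genome_length=600 * 900)
    return simulate_experiment(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
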