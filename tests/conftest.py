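import numpy as np
import pytest

from circkit.config import PipelineConfig
from circkit.synthetic import (
    GenomeSpec,
    ReadSimConfig,
    generate_genome,
    plant_circrnas,
    plant_linear,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_genome():
    """A 20-kb single-chromosome genome for oracle comparisons."""
    spec = GenomeSpec(1, (20_000,), gc_fraction=0.42, seed=11)
    return generate_genome(spec)


@pytest.fixture(scope="session")
def planted():
    """Two-chromosome genome with planted circular and linear transcripts."""
    spec = GenomeSpec(2, (50_000, 30_000), gc_fraction=0.42, seed=21)
    genome = generate_genome(spec)
    genome, circs = plant_circrnas(genome, 8, (200, 1500), seed=22)
    linears = plant_linear(genome, 4, (500, 1500), seed=23, avoid=circs)
    return genome, circs, linears


@pytest.fixture(scope="session")
def planted_reads(planted):
    genome, circs, linears = planted
    reads, truth = simulate_reads(
        genome,
        circs + linears,
        ReadSimConfig(read_length=150, coverage=12.0, error_rate=0.0, seed=24),
    )
    return genome, circs, linears, reads, truth


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (no cross-test coupling)."""
    return np.random.default_rng(99)
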