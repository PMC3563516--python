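from __future__ import annotations

import pytest

from bovmir import pipeline, simulate
from bovmir.config import PipelineConfig, SimulationConfig


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


SMALL_SIM = dict(
    seed=7,
    library_sizes=(20_000, 20_000),
    genome_length=120_000,
    n_known_mirna=12,
    n_novel_mirna=5,
)


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic study shared by the cheap integration tests."""
    sim = SimulationConfig(**SMALL_SIM)
    genome, gt = simulate.generate_genome(sim)
    gt2, result = pipeline.run_synthetic(SimulationConfig(**SMALL_SIM))
    return sim, genome, gt2, result


@pytest.fixture(scope="session")
def default_study():
    """The full-scale synthetic study: 2e5 reads/library, 30 known and 10
    novel planted hairpins, 20 known miRNAs at a true 4-fold change."""
    sim = SimulationConfig(seed=1)
    genome, _ = simulate.generate_genome(sim)
    gt, result = pipeline.run_synthetic(SimulationConfig(seed=1))
    return sim, genome, gt, result
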