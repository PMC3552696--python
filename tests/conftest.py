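import numpy as np
import pytest

from lincmir import pipeline, simulate


def small_config(seed: int = 1) -> simulate.SimulationConfig:
    """A miniature study: 20 samples, 12 candidate regions, 3 planted pairs."""
    return simulate.SimulationConfig(
        seed=seed,
        genome_length=200_000,
        n_known_genes=3,
        n_candidate_regions=12,
        n_true_lincrnas=6,
        n_near_gene_regions=2,
        n_coding_regions=2,
        n_mirnas=6,
        n_planted_pairs=3,
        mean_depth=5000,
    )


@pytest.fixture(scope="session")
def small_cfg() -> simulate.SimulationConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_truth(small_cfg) -> simulate.SimulatedTruth:
    return simulate.simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_workdir(tmp_path_factory, small_cfg):
    """A complete pipeline run on the miniature study, shared by tests."""
    work = tmp_path_factory.mktemp("pipeline_run")
    report = pipeline.run_pipeline(work, small_cfg)
    return work, report


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
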