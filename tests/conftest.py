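import pytest

from mitoflux.config import SimulationConfig
from mitoflux import synthetic


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A reduced study: fast to generate, exercises every stage."""
    return SimulationConfig(
        seed=11,
        n_genes=150,
        promoter_length=200,
        n_metabolites=12,
        planted_motif="TGATGCAA",
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return synthetic.generate_all(small_cfg)


@pytest.fixture(scope="session")
def noiseless_cfg() -> SimulationConfig:
    """Zero-noise variant: every estimator must recover truth exactly."""
    return SimulationConfig(
        seed=5,
        n_genes=150,
        promoter_length=200,
        n_metabolites=12,
        expression_noise_cv=0.0,
        media_noise_cv=0.0,
        tracer_noise_cv=0.0,
        count_noise_cv=0.0,
        ct_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_cfg):
    return synthetic.generate_all(noiseless_cfg)
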