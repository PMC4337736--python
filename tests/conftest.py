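import numpy as np
import pytest

from gwsig import SimulationConfig, generate_multistudy_expression


@pytest.fixture
def tiny_config():
    # 80 shared genes, 3 small studies; fast enough for per-test regeneration
    return SimulationConfig(
        n_datasets=3,
        genes_per_dataset=[120, 110, 100],
        shared_gene_fraction=0.8,
        n_cases=4,
        n_controls=4,
        n_de=10,
        effect_size=2.0,
        effect_sd=0.3,
        noise_sd=0.5,
        seed=11,
    )


@pytest.fixture
def tiny_study(tiny_config):
    return generate_multistudy_expression(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
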