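import pytest

from mycotraits.config import ExperimentConfig, NoiseSpec
from mycotraits.synthetic import generate_experiment
from mycotraits.traits import build_trait_table


@pytest.fixture(scope="session")
def noiseless_experiment():
    cfg = ExperimentConfig(noise=NoiseSpec.noiseless(), seed=42)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def noiseless_derived(noiseless_experiment):
    tab = noiseless_experiment
    return build_trait_table(tab.microcosms, tab.microscopy,
                             tab.enzyme_plates, tab.config.assay,
                             tab.config.microscopy)


@pytest.fixture(scope="session")
def default_experiment():
    return generate_experiment(ExperimentConfig(seed=5))


@pytest.fixture(scope="session")
def default_derived(default_experiment):
    tab = default_experiment
    return build_trait_table(tab.microcosms, tab.microscopy,
                             tab.enzyme_plates, tab.config.assay,
                             tab.config.microscopy)
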