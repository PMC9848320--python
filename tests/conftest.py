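import numpy as np
import pytest

from astascan.simulate import GeneratorConfig, make_cohort, make_precursor
from astascan.zymogen import ValidatorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gen_cfg():
    return GeneratorConfig()


@pytest.fixture
def validator_cfg(gen_cfg):
    # generated precursors carry a fixed-length signal peptide
    return ValidatorConfig(signal_end=gen_cfg.signal_length)


@pytest.fixture
def basic_precursor(gen_cfg, rng):
    return make_precursor("basic", gen_cfg, rng, record_id="basic0")


@pytest.fixture(scope="session")
def small_cohort():
    cfg = GeneratorConfig(n_taxa=12)
    rng = np.random.default_rng(77)
    return make_cohort(cfg, rng, n_decoys=6)
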