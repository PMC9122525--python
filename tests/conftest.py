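import numpy as np
import pytest

from smcsim import (IntegratorSettings, assemble_system, build_dna,
                    build_smcc, thread_translocation_config)
from smcsim.model_builder import DNAParameters


@pytest.fixture(scope="session")
def smcc_default():
    return build_smcc()


@pytest.fixture(scope="session")
def small_threaded():
    """A threaded translocation state with the default 301-bead DNA."""
    return thread_translocation_config(build_dna(), build_smcc())


@pytest.fixture()
def perturbed_system(smcc_default):
    """Small DNA + SMCC system with a mild random perturbation."""
    dna = build_dna(DNAParameters(beads=12))
    state = assemble_system(dna, smcc_default)
    rng = np.random.default_rng(7)
    state.pos += rng.normal(0.0, 0.05, state.pos.shape)
    return state


@pytest.fixture()
def default_settings():
    return IntegratorSettings()
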