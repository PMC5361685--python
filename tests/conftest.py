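import numpy as np
import pytest

from dnaenm import (
    DnaSequence,
    HelicalParameterSet,
    build_basic_structure,
    build_hessian,
    build_model,
    default_connectivity,
    normal_modes,
    random_sequence,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def crystal_structure_30bp():
    """30-bp random-sequence basic structure with the packaged parameters."""
    seq = random_sequence(30, np.random.default_rng(7), id="fix30")
    return build_basic_structure(seq)


@pytest.fixture(scope="session")
def small_model(crystal_structure_30bp):
    """Fine-grained network on the 30-bp structure (60 particles)."""
    return build_model(crystal_structure_30bp, default_connectivity(1), 1)


@pytest.fixture(scope="session")
def small_modes(small_model):
    return normal_modes(build_hessian(small_model))


@pytest.fixture(scope="session")
def tiny_model():
    """Six-particle-pair coarse model, small enough for brute-force oracles."""
    seq = DnaSequence("ACGTTAGCATCAGGATCA")  # 18 bp -> 6 pairs at k=3
    struct = build_basic_structure(seq)
    return build_model(struct, default_connectivity(3), 3)


@pytest.fixture
def ideal_table():
    return HelicalParameterSet.ideal_b()
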