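import numpy as np
import pytest

from zippersim import (build_extended_strand, build_nanocrystal, EnergyModel,
                       PeptideSystem)


@pytest.fixture(scope="session")
def ilqins():
    return build_extended_strand("ILQINS")


@pytest.fixture(scope="session")
def p_sheet4():
    """Class-1 parallel single sheet of 4 strands."""
    return build_nanocrystal("ILQINS", 1, dims=(1, 1, 4))


@pytest.fixture(scope="session")
def ap_sheet4():
    """Class-5 antiparallel single sheet of 4 strands."""
    return build_nanocrystal("ILQINS", 5, dims=(1, 1, 4))


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
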