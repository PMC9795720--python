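import numpy as np
import pytest

from molelicit.chem_io import Molecule
from molelicit.library import generate_library
from molelicit.scoring import (
    DesirabilityParams,
    MPOScoringFunction,
    ScoringComponent,
)


@pytest.fixture(scope="session")
def small_library():
    """200 synthetic drug-like molecules (session-cached; descriptors warm)."""
    lib = generate_library(200, seed=11)
    for m in lib:
        m.descriptors  # warm the cache once
    return lib


@pytest.fixture(scope="session")
def tiny_library():
    return generate_library(40, seed=5)


@pytest.fixture
def ethanol():
    return Molecule.from_smiles("CCO")


@pytest.fixture
def benzene():
    return Molecule.from_smiles("c1ccccc1")


@pytest.fixture
def mw_scoring_function():
    """Single-component MPO over molecular weight."""
    return MPOScoringFunction(
        [ScoringComponent("MW", 1.0, DesirabilityParams(150.0, 350.0, 0.05, 0.05))]
    )


@pytest.fixture
def two_component_sf():
    return MPOScoringFunction(
        [
            ScoringComponent("MW", 0.6, DesirabilityParams(30.0, 60.0, 0.2, 0.2)),
            ScoringComponent("HBD", 0.4, DesirabilityParams(0.5, 2.5, 2.0, 2.0)),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
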