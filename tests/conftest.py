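import numpy as np
import pytest

from phasemap.energy_model import EnergyParams
from phasemap.fixtures import ToySpec, make_toy


@pytest.fixture
def params_nosalt():
    """Energy parameters with screening off (clean Coulomb checks)."""
    return EnergyParams(ionic_strength=0.0)


@pytest.fixture
def params_default():
    return EnergyParams()


@pytest.fixture
def sphere():
    return make_toy(ToySpec(kind="sphere", lj_sigma=4.0, lj_epsilon=0.2))


@pytest.fixture
def hard_sphere():
    """Purely steric sphere (no LJ attraction, no charge)."""
    return make_toy(ToySpec(kind="sphere", lj_sigma=4.0, lj_epsilon=0.0))


@pytest.fixture
def dumbbell():
    return make_toy(
        ToySpec(kind="charged_dumbbell", lj_sigma=3.0, lj_epsilon=0.2, charge=1.0, separation=4.0)
    )


@pytest.fixture
def tetramer():
    return make_toy(
        ToySpec(kind="tetramer", lj_sigma=3.0, lj_epsilon=0.15, charge=0.5, separation=4.0)
    )
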