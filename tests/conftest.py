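import numpy as np
import pytest

from thyrodose import (
    DesignSpec,
    design_controller,
    discretize_impulse_invariant,
    nominal_params,
)


@pytest.fixture(scope="session")
def params():
    return nominal_params()


@pytest.fixture(scope="session")
def design_spec():
    return DesignSpec()


@pytest.fixture(scope="session")
def plant(params, design_spec):
    return discretize_impulse_invariant(params, Td=design_spec.Td)


@pytest.fixture(scope="session")
def controller(plant, design_spec):
    return design_controller(plant, design_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240613)
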