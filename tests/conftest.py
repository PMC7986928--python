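import numpy as np
import pytest

from granudiff.model_system import (
    UncertaintySpec,
    default_design,
    make_system,
)

D_TRUE = 1.2e-9


@pytest.fixture(scope="session")
def system():
    return make_system()


@pytest.fixture(scope="session")
def designs(system):
    return {m: default_design(m, system) for m in range(1, 7)}


@pytest.fixture(scope="session")
def table2_spec():
    return UncertaintySpec()


@pytest.fixture(scope="session")
def uptake_times():
    return np.arange(0.0, 3600.0 + 1e-9, 60.0)
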