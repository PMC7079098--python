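import numpy as np
import pytest

from propnet.phantom import PhantomSpec, generate_patient, generate_phantom


DESK_SPEC = PhantomSpec(grid=(32, 32, 32), spacing=(6.25, 6.25, 3.75))


@pytest.fixture(scope="session")
def desk_spec():
    return DESK_SPEC


@pytest.fixture(scope="session")
def desk_phantom():
    return generate_phantom(DESK_SPEC, np.random.default_rng(5))


@pytest.fixture(scope="session")
def desk_patient():
    return generate_patient(DESK_SPEC, 3, np.random.default_rng(11), "p0")
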