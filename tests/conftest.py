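import numpy as np
import pytest

from traumasim import (
    build_schema,
    element_removal_weights,
    load_bone_ess,
    load_trauma_pool,
)


@pytest.fixture(scope="session")
def schema():
    return build_schema()


@pytest.fixture(scope="session")
def pool(schema):
    return load_trauma_pool(schema)


@pytest.fixture(scope="session")
def bone_ess(schema):
    return load_bone_ess(schema)


@pytest.fixture(scope="session")
def weights(schema, bone_ess):
    return element_removal_weights(schema, bone_ess)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
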