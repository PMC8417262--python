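import numpy as np
import pytest

from pbshift.synthcohort import PBSFieldSpec, PhantomSpec, generate_phantom, generate_pbs_field


@pytest.fixture(scope="session")
def phantom_default():
    """Default-geometry phantom (64³ @ 3.2 mm): volume, skull, brain, atlas."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def field_default(phantom_default):
    _, _, brain, _ = phantom_default
    return generate_pbs_field(PBSFieldSpec(), brain)


@pytest.fixture(scope="session")
def phantom_small():
    """Coarse phantom (40³ @ 5 mm) for cheap geometric tests."""
    return generate_phantom(PhantomSpec(shape=(40, 40, 40), spacing=5.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
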