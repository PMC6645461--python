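import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trenchroot import CubeObservation, generate_field, Isotropic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cube(cube_id="c1", ni=(10, 10, 10), depth=0.3, **kw):
    defaults = dict(
        cube_id=cube_id,
        depth_z=depth,
        ni_h=ni[0],
        ni_t=ni[1],
        ni_l=ni[2],
        variety="Souna3",
        das=60,
        distance_cm=10.0,
        replicate=1,
        root_class="all",
    )
    defaults.update(kw)
    return CubeObservation(**defaults)


@pytest.fixture
def cube_factory():
    return make_cube


@pytest.fixture(scope="session")
def isotropic_field():
    """A moderate isotropic field shared across tests (expensive to build)."""
    return generate_field(5000.0, Isotropic(), box=(1.0, 1.0, 1.0), seed=42)
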