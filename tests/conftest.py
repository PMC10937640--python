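import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: small phantom geometry used across tests: 48^3 grid at 2 mm with a heart
#: scaled to fit; fast to generate and fully inside the torso
SMALL_SPEC = dict(
    grid_shape=(48, 48, 48),
    spacing_mm=(2.0, 2.0, 2.0),
    heart_radii_mm=(24.0, 21.0, 16.0),
    fat_thickness_mm=6.0,
)


@pytest.fixture(scope="session")
def small_phantom():
    from pericfat.phantom import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(seed=7, **SMALL_SPEC))


@pytest.fixture(scope="session")
def small_cohort():
    from pericfat.simcohort import simulate_cohort

    return simulate_cohort(mode="allcause", n=20_000, seed=5)
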