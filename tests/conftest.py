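import numpy as np
import pytest
from hypothesis import settings

from cordcool import (AnatomyParams, BloodModel, build_anatomy,
                      default_blood, default_registry)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def blood(registry):
    return default_blood()


@pytest.fixture(scope="session")
def cord(registry):
    return registry["spinal_cord"]


def small_anatomy_params() -> AnatomyParams:
    """A shrunken torso (130 x 120 mm) around the unchanged spinal canal;
    keeps every tissue class and the exterior ring while staying cheap."""
    return AnatomyParams(
        domain_width=0.130,
        domain_height=0.120,
        viscera_center=(0.0, -0.040),
        viscera_semiaxes=(0.040, 0.007),
        torso_corner_radius=0.025,
    )


@pytest.fixture(scope="session")
def small_grid():
    return build_anatomy(small_anatomy_params(), spacing=0.001)


@pytest.fixture(scope="session")
def default_grid():
    """Default anatomy at desk resolution (1 mm)."""
    return build_anatomy(spacing=0.001)
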