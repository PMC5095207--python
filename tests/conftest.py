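import numpy as np
import pytest

from varfit import DataPoint, ModelSpec, PolySystem, TrackConfig
from varfit.synthdata import builtin_examples, ellipsoid_model


@pytest.fixture(scope="session")
def sphere_xy():
    """Unit sphere with (x, y) observed."""
    return ellipsoid_model()


@pytest.fixture(scope="session")
def sphere_full():
    """Unit sphere with all three coordinates observed."""
    return ellipsoid_model(outputs=("x", "y", "z"))


@pytest.fixture(scope="session")
def generic_ellipsoid():
    """Ellipsoid with distinct known axes, fully observed."""
    return ellipsoid_model(
        known={"a": 1.3, "b": 0.8, "c": 1.9}, outputs=("x", "y", "z")
    )


@pytest.fixture(scope="session")
def fig2_cases():
    return builtin_examples()


@pytest.fixture()
def config():
    return TrackConfig(seed=0)
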