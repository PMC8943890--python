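import numpy as np
import pytest

from srsphasor import (
    PhantomSpec,
    default_axis,
    default_templates,
    generate_phantom,
)


@pytest.fixture(scope="session")
def axis40():
    """Default 40-channel acquisition axis, 2800-3050 cm^-1."""
    return default_axis()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


def small_spec(**overrides) -> PhantomSpec:
    """A compact phantom spec that keeps unit tests fast."""
    params = dict(
        image_size=(96, 96),
        n_cells=2,
        droplet_density=4.0,
        droplet_radius_range=(2.0, 3.0),
        cell_axis_range=(12.0, 16.0),
        snr=np.inf,
        seed=42,
    )
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def noiseless_phantom(axis40):
    """Small noiseless phantom with droplets, shared across read-only tests."""
    return generate_phantom(small_spec(), axis40)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
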