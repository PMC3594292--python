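import numpy as np
import pytest

from talbotct import (
    AcquisitionConfig,
    acquire,
    build_phantom,
    retrieve,
    tube_design,
)


@pytest.fixture(scope="session")
def design():
    return tube_design()


@pytest.fixture(scope="session")
def cylinder_phantom():
    return build_phantom(256, pixel_size_um=30.0, scene="cylinder", seed=2)


@pytest.fixture(scope="session")
def cylinder_sinos(cylinder_phantom):
    """Noiseless retrieved sinograms of the cylinder scene, 360 angles."""
    cfg = AcquisitionConfig(n_projections=360, n_steps=4, noiseless=True)
    return retrieve(acquire(cylinder_phantom, cfg))


@pytest.fixture(scope="session")
def mouse_phantom():
    return build_phantom(192, pixel_size_um=30.0, scene="mouse_abdomen", seed=42)
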