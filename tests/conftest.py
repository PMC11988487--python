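import numpy as np
import pytest

from perfgrid import GridSpec
from perfgrid.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_grid() -> GridSpec:
    return GridSpec()


@pytest.fixture(scope="session")
def phantom():
    """Small phantom whose grid fits fully inside the image (all cells on-field)."""
    return generate_phantom(
        PhantomSpec(
            image_size=(384, 384),
            seed=11,
            n_blobs=3,
            artifact_bands=3,
            fovea_disc_px=34.0,
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
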