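import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from busseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(20240516)


@pytest.fixture(scope="session")
def disk_phantom():
    """Sharp-edged disk lesion with light speckle, plus its truth mask."""
    spec = PhantomSpec(
        image_height=128, image_width=128, lesion_center=(64.0, 64.0),
        lesion_radii=(30.0, 30.0), contrast=0.35, speckle_scale=0.15,
        margin_irregularity=0.0, rng_seed=7,
    )
    return generate_phantom(spec)


def random_mask(rng: np.random.Generator, shape) -> np.ndarray:
    return (rng.random(shape) > rng.uniform(0.2, 0.8)).astype(np.uint8)
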