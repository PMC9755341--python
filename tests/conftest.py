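import numpy as np
import pytest

from hmquant.io import PlanarImage
from hmquant.phantom import PhantomParams, _PhantomModel, generate_phantom


@pytest.fixture(scope="session")
def noise_free_params() -> PhantomParams:
    return PhantomParams(poisson_noise=False)


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_params):
    """(early, late, ground_truth) for the default geometry without noise."""
    return generate_phantom(noise_free_params, seed=0)


@pytest.fixture(scope="session")
def default_model(noise_free_params) -> _PhantomModel:
    return _PhantomModel(noise_free_params)


@pytest.fixture()
def uniform_image():
    return PlanarImage(np.full((32, 32), 100.0), phase="early", subject_id="u")
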