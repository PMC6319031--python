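import numpy as np
import pytest

from vesseltrees.kernels import GaussianSwirlParams, build_slogs_kernel
from vesseltrees.synthetic import SyntheticTreeSpec, generate_tree, straight_tube_phantom


@pytest.fixture(scope="session")
def tube_params():
    return GaussianSwirlParams((2.0, 0.7, 0.7))


@pytest.fixture(scope="session")
def tube_kernel(tube_params):
    return build_slogs_kernel(tube_params)


@pytest.fixture(scope="session")
def curved_kernel():
    return build_slogs_kernel(GaussianSwirlParams((2.0, 0.7, 0.7), (0.3, 0.1, 0.02)))


@pytest.fixture(scope="session")
def tube_phantom():
    """Clean straight tube with exact centerline, small enough for unit tests."""
    return straight_tube_phantom(length=40, radius=2, shape=(48, 48, 48),
                                 blur_sigma=0.5)


@pytest.fixture(scope="session")
def small_tree():
    """A clean 4-terminal synthetic tree in a 48^3 volume."""
    spec = SyntheticTreeSpec(
        terminal_branches=4, volume_shape=(48, 48, 48), noise_sigma=0.0, rng_seed=7
    )
    return generate_tree(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
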