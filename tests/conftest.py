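import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from probereg import PhantomConfig, RigidTransform, estimate_normals, make_phantom

#: Small dense cloud for structural tests where registration accuracy is not
#: under test; keeps the unit suite fast.
FAST_DENSE_N = 8_000


def random_rigid(rng: np.random.Generator, trans_scale: float = 50.0) -> RigidTransform:
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.uniform(-trans_scale, trans_scale, 3))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default-geometry phantom (all sigmas and outliers zero)."""
    return make_phantom(PhantomConfig(seed=7, probe_noise_sigma=0.0,
                                      landmark_noise_sigma=0.0))


@pytest.fixture(scope="session")
def clean_target_normals(clean_phantom):
    return estimate_normals(clean_phantom.target_cloud, 30)


@pytest.fixture(scope="session")
def study_phantom():
    """Phantom at the study conditions: 0.2 mm probe noise, 20% outliers."""
    return make_phantom(PhantomConfig(seed=7, probe_noise_sigma=0.2,
                                      outlier_fraction=0.2))


@pytest.fixture(scope="session")
def fast_config():
    return PhantomConfig(dense_n=FAST_DENSE_N, probe_noise_sigma=0.2,
                         outlier_fraction=0.2)
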