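import numpy as np
import pytest

from swefuse.phantom import PhantomParams, generate_dataset, generate_phantom_pair


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Phantom parameters sized for fast unit tests."""
    return PhantomParams(image_height=96, image_width=120,
                         lesion_radius_range=(10.0, 16.0),
                         n_patients=6, images_per_patient_range=(2, 5))


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """A 20-sample phantom cohort shared across tests (read-only)."""
    samples, manifest = generate_dataset(small_params, 20, seed=11)
    return samples, manifest


@pytest.fixture(scope="session")
def one_pair(small_params):
    return generate_phantom_pair(small_params, label=1, seed=7)


@pytest.fixture(scope="session")
def separable_images():
    """Bright-vs-dark 64x64 stacks a classifier must separate perfectly."""
    rng = np.random.default_rng(3)
    n = 40
    y = np.array([0, 1] * (n // 2))
    x = np.where(y[:, None, None, None] == 1, 0.8, 0.2)
    x = (x + 0.05 * rng.standard_normal((n, 64, 64, 3))).astype(np.float32)
    return x, y
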