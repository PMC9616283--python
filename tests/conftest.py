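import numpy as np
import pytest

from pvsquant.io_formats import Volume


def make_affine(spacing=0.35):
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = spacing
    return a


@pytest.fixture
def affine():
    return make_affine()


@pytest.fixture
def cylinder_volume():
    """Bright Gaussian-profile cylinder along z on a 0.35 mm grid."""
    n, sp = 48, 0.35
    x, y, _ = np.meshgrid(*[np.arange(n) * sp] * 3, indexing="ij")
    c = n * sp / 2
    data = 100 + 150 * np.exp(-((x - c) ** 2 + (y - c) ** 2) / (2 * 0.4**2))
    return Volume(data, make_affine(sp))


@pytest.fixture(scope="session")
def straight_tube_subject():
    """One noise-free straight tube (radius 0.4 mm, length 20 mm)."""
    from pvsquant.phantom import PhantomConfig, generate_subject

    cfg = PhantomConfig(
        shape=(96, 96, 96), n_tubes=1, noise_sigma=0.0, curve_fractions=(1, 0, 0),
        radius_range=(0.4, 0.4), length_range=(20.0, 20.0),
    )
    return generate_subject(cfg, seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    """Three modest phantom subjects for pipeline-level tests."""
    from pvsquant.phantom import PhantomConfig, generate_cohort

    cfg = PhantomConfig(shape=(96, 96, 96), n_tubes=20, seed=3)
    return generate_cohort(cfg, 3, master_seed=3)
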