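import numpy as np
import pytest

from quasarfield.dipole import build_dipole_kernel
from quasarfield.volumes import Volume3D


@pytest.fixture(scope="session")
def kernel32():
    return build_dipole_kernel((32, 32, 32))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_volume(rng):
    return Volume3D(rng.standard_normal((32, 32, 32)), unit="ppm")


def sphere_setup(n=128, a=8.0, dchi=1.0):
    """Shared anti-aliased sphere scene for forward-model oracle tests."""
    from quasarfield.dipole import rasterize_sphere

    tpl = Volume3D(np.zeros((n, n, n)), unit="ppm")
    center = (n / 2.0, n / 2.0, n / 2.0)
    chi = tpl.with_data(rasterize_sphere(tpl, center, a, value=dchi))
    coords = [np.arange(n, dtype=float) for _ in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    r = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
    return tpl, chi, center, r
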