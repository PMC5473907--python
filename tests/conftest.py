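import numpy as np
import pytest

from placentabold import preprocess
from placentabold.paradigm import OxygenParadigm


def brute_force_smooth(vol, width, sigma):
    """Triple-loop separable-Gaussian smoothing oracle with edge renormalization."""
    k1 = preprocess.gaussian_kernel_1d(width, sigma)
    r = width // 2
    K = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    nx, ny, nz = vol.shape
    out = np.zeros_like(vol)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                acc = w = 0.0
                for dx in range(-r, r + 1):
                    for dy in range(-r, r + 1):
                        for dz in range(-r, r + 1):
                            xx, yy, zz = x + dx, y + dy, z + dz
                            if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                                kk = K[dx + r, dy + r, dz + r]
                                acc += kk * vol[xx, yy, zz]
                                w += kk
                out[x, y, z] = acc / w
    return out


@pytest.fixture(scope="session")
def paradigm():
    return OxygenParadigm()


@pytest.fixture(scope="session")
def tr6_grid(paradigm):
    """Acquisition time grid at TR = 6 s over the full 30-min paradigm."""
    return np.arange(0.0, paradigm.total + 1e-9, 0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
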