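import numpy as np
import pytest

from csiirr import (
    Image2D,
    PhantomSpec,
    TiltGeometry,
    make_sparse_phantom,
    simulate_tilt_series,
)


@pytest.fixture(scope="session")
def disk64():
    """Centered uniform disk of radius 20 on a 64x64 grid."""
    n, r = 64, 20
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    disk = ((xx - c) ** 2 + (yy - c) ** 2 <= r * r).astype(float)
    return Image2D(disk), r


@pytest.fixture(scope="session")
def phantom64():
    """Small sparse phantom with its support, shared across modules."""
    return make_sparse_phantom(PhantomSpec(size=64, sparsity_target=0.05,
                                           seed=7))


@pytest.fixture(scope="session")
def wedge_sino64(phantom64):
    truth, _ = phantom64
    return simulate_tilt_series(truth, -60, 60, 1)


@pytest.fixture(scope="session")
def full_sino64(phantom64):
    truth, _ = phantom64
    return simulate_tilt_series(truth, -89, 89, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def ray_oracle(values: np.ndarray, angle_deg: float, s: float,
               step: float = 0.1) -> float:
    """Brute-force supersampled ray integral with bilinear interpolation —
    an independent oracle for the discrete Radon transform."""
    th = np.deg2rad(angle_deg)
    n = values.shape[0]
    c = (n - 1) / 2.0
    t = np.arange(-n, n, step)
    x1 = s * np.cos(th) - t * np.sin(th)
    x2 = s * np.sin(th) + t * np.cos(th)
    col = x1 + c
    row = x2 + c
    i0 = np.floor(row).astype(int)
    j0 = np.floor(col).astype(int)
    fr = row - i0
    fc = col - j0

    def at(i, j):
        ok = (i >= 0) & (i < n) & (j >= 0) & (j < n)
        out = np.zeros_like(fr)
        out[ok] = values[i[ok], j[ok]]
        return out

    val = (at(i0, j0) * (1 - fr) * (1 - fc)
           + at(i0 + 1, j0) * fr * (1 - fc)
           + at(i0, j0 + 1) * (1 - fr) * fc
           + at(i0 + 1, j0 + 1) * fr * fc)
    return float(val.sum() * step)
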