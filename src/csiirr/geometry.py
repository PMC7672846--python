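"""Projection geometry and the shared operator core.

Every reconstruction method in this package is built from three discrete
operators on 2-D density images:

* :func:`radon` — the forward projector, mapping an image to its sinogram
  of line integrals ``p(s, alpha)``;
* :func:`backproject` — the adjoint-style smear of a sinogram back across
  the image grid;
* :func:`ramp_filter` — the 1-D ``|omega|`` filter applied per projection
  column before backprojection in filtered backprojection.

The forward projector is pixel-driven ("splat"): each pixel deposits its
value into the two detector bins bracketing its signed distance
``s = x1 cos(alpha) + x2 sin(alpha)`` with linear weights.  The
backprojector gathers from the same two bins with the same weights, so the
two dense operator matrices are exact transposes of each other (up to the
angular weighting applied in :func:`backproject`).  That exact adjoint
pairing is what makes the greedy matching-pursuit reconstruction behave
like a proper frame expansion rather than an ad-hoc heuristic.

Angles are degrees in every public interface; ``alpha`` is the angle
between the projection line's normal and the ``x1`` axis.  The missing
wedge is represented explicitly: a :class:`TiltGeometry` carries the full
angular grid together with a boolean ``known`` mask, and unmeasured angles
simply have ``known=False`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class GeometryError(ValueError):
    """Invalid tilt geometry (empty angle list, bad ordering, ...)."""


class ShapeError(ValueError):
    """Array shapes inconsistent with the declared geometry."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SupportMask:
    """Boolean mask of pixels the specimen may occupy (the set T)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ShapeError("support mask must be 2-D")
        if not m.any():
            raise ValueError("support mask must contain at least one pixel")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def inscribed_disk(cls, n: int, radius: Optional[float] = None) -> "SupportMask":
        """Disk inscribed in an ``n x n`` grid — the default specimen support."""
        if radius is None:
            radius = n / 2.0
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        return cls((xx - c) ** 2 + (yy - c) ** 2 <= radius**2)


@dataclass
class Image2D:
    """Square grid of real-valued densities (the reconstruction target f)."""

    values: np.ndarray
    pixel_size: float = 1.0
    support: Optional[SupportMask] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError(f"image must be square 2-D, got shape {v.shape}")
        if v.shape[0] < 2:
            raise ShapeError("image side must be >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        if self.support is not None and self.support.mask.shape != v.shape:
            raise ShapeError("support mask shape does not match image")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def masked(self) -> "Image2D":
        """Zero everything outside the attached support mask."""
        if self.support is None:
            return self
        v = np.where(self.support.mask, self.values, 0.0)
        return Image2D(v, self.pixel_size, self.support)

    @classmethod
    def zeros(cls, n: int, pixel_size: float = 1.0,
              support: Optional[SupportMask] = None) -> "Image2D":
        return cls(np.zeros((n, n)), pixel_size, support)


@dataclass(frozen=True)
class TiltGeometry:
    """Angular sampling grid with the measured/missing-wedge mask.

    ``known[j]`` is True when angle ``angles[j]`` was actually measured;
    False columns form the missing wedge Omega-complement.
    """

    angles: np.ndarray
    known: np.ndarray
    n_bins: int
    bin_spacing: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=np.float64)
        k = np.asarray(self.known, dtype=bool)
        if a.ndim != 1 or a.size == 0:
            raise GeometryError("angle list must be 1-D and non-empty")
        if k.shape != a.shape:
            raise GeometryError("known mask length must match angle count")
        if np.any(np.diff(a) <= 0):
            raise GeometryError("angles must be strictly increasing")
        if a[0] <= -90.0 or a[-1] > 90.0:
            raise GeometryError("angles must lie in (-90, 90] degrees")
        if self.n_bins < 1:
            raise GeometryError("n_bins must be >= 1")
        if self.bin_spacing <= 0:
            raise GeometryError("bin_spacing must be positive")
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "known", k)

    @property
    def n_angles(self) -> int:
        return self.angles.size

    @property
    def angular_spacing_rad(self) -> float:
        """Angular quadrature weight d(alpha) in radians."""
        if self.n_angles < 2:
            return float(np.pi)
        return float(np.deg2rad(np.median(np.diff(self.angles))))

    def with_known(self, known: np.ndarray) -> "TiltGeometry":
        return replace(self, known=np.asarray(known, dtype=bool).copy())

    @classmethod
    def all_known(cls, angles: np.ndarray, n_bins: int,
                  bin_spacing: float = 1.0) -> "TiltGeometry":
        angles = np.asarray(angles, dtype=np.float64)
        return cls(angles, np.ones(angles.size, dtype=bool), n_bins, bin_spacing)


@dataclass
class Sinogram:
    """Projection data p(s, alpha) on the detector-bin x tilt-angle grid."""

    values: np.ndarray
    geometry: TiltGeometry

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ShapeError("sinogram must be 2-D (n_bins, n_angles)")
        if v.shape != (self.geometry.n_bins, self.geometry.n_angles):
            raise ShapeError(
                f"sinogram shape {v.shape} does not match geometry "
                f"({self.geometry.n_bins}, {self.geometry.n_angles})"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("sinogram contains non-finite values")
        self.values = v

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.geometry)

    @classmethod
    def zeros(cls, geometry: TiltGeometry) -> "Sinogram":
        return cls(np.zeros((geometry.n_bins, geometry.n_angles)), geometry)


# --------------------------------------------------------------------------
# cached sparse projector
# --------------------------------------------------------------------------

# The discrete Radon operator for one (grid size, geometry) pair is a sparse
# matrix with two entries per (pixel, angle).  Iterative methods apply it and
# its transpose hundreds of times on a fixed geometry, so the matrix is built
# once and cached.
_MATRIX_CACHE: dict = {}
_MATRIX_CACHE_MAX = 4


def _radon_matrix(n: int, geom: TiltGeometry):
    key = (n, geom.n_bins, float(geom.bin_spacing), geom.angles.tobytes())
    hit = _MATRIX_CACHE.get(key)
    if hit is not None:
        return hit
    from scipy import sparse

    c = (n - 1) / 2.0
    idx = np.arange(n, dtype=np.float64) - c
    # x1 along columns, x2 along rows
    x1 = np.tile(idx, n)
    x2 = np.repeat(idx, n)
    th = np.deg2rad(geom.angles)
    s = np.outer(x1, np.cos(th)) + np.outer(x2, np.sin(th))
    t = s / geom.bin_spacing + (geom.n_bins - 1) / 2.0
    i0 = np.floor(t).astype(np.int64)
    w = t - i0
    n_ang = geom.n_angles
    n_bins = geom.n_bins
    cols_px = np.broadcast_to(np.arange(n * n, dtype=np.int64)[:, None],
                              i0.shape)
    ang = np.broadcast_to(np.arange(n_ang, dtype=np.int64)[None, :], i0.shape)
    rows, cols, data = [], [], []
    for lo, wgt in ((i0, 1.0 - w), (i0 + 1, w)):
        valid = (lo >= 0) & (lo < n_bins)
        rows.append((lo[valid] * n_ang + ang[valid]))
        cols.append(cols_px[valid])
        data.append(wgt[valid])
    mat = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_bins * n_ang, n * n),
    )
    mat_t = mat.T.tocsr()
    entry = (mat, mat_t)
    if len(_MATRIX_CACHE) >= _MATRIX_CACHE_MAX:
        _MATRIX_CACHE.pop(next(iter(_MATRIX_CACHE)))
    _MATRIX_CACHE[key] = entry
    return entry


# --------------------------------------------------------------------------
# operators
# --------------------------------------------------------------------------


def radon(image: Image2D, geometry: TiltGeometry) -> Sinogram:
    """Discrete Radon transform: line integrals along
    ``(cos a) x1 + (sin a) x2 = s`` for every detector bin and tilt angle.

    Pixel-driven: every pixel splats ``value * pixel_size`` onto the two
    bins bracketing its signed distance s, with linear weights.  Linear in
    the image and deterministic.
    """
    n = image.n
    mat, _ = _radon_matrix(n, geometry)
    out = mat @ image.values.ravel()
    out = out.reshape(geometry.n_bins, geometry.n_angles) * image.pixel_size
    return Sinogram(out, geometry)


def backproject(sino: Sinogram, size: Optional[int] = None,
                weighted: bool = True, pixel_size: float = 1.0) -> Image2D:
    """Smear projections back across the image grid.

    With ``weighted=True`` the angular sum is multiplied by the angular
    spacing in radians, approximating the integral over alpha so that
    filtered backprojection is quantitatively correct.  With
    ``weighted=False`` the result is the exact matrix transpose of
    :func:`radon` (used by the adjointness tests).
    """
    geom = sino.geometry
    n = geom.n_bins if size is None else size
    _, mat_t = _radon_matrix(n, geom)
    img = (mat_t @ sino.values.ravel()).reshape(n, n) * pixel_size
    if weighted:
        img *= geom.angular_spacing_rad
    return Image2D(img, pixel_size)


def _ramp_kernel(pad: int, bin_spacing: float) -> np.ndarray:
    """Discrete band-limited ramp kernel, wrapped onto a length-``pad`` grid.

    h[0] = 1/(4 tau^2), h[k] = -1/(pi^2 k^2 tau^2) for odd k, 0 for even k —
    the exact inverse transform of the |omega| ramp truncated at the detector
    Nyquist frequency.
    """
    h = np.zeros(pad)
    tau2 = bin_spacing**2
    h[0] = 1.0 / (4.0 * tau2)
    k = np.arange(1, pad // 2 + 1, 2)
    v = -1.0 / (np.pi**2 * k.astype(np.float64) ** 2 * tau2)
    h[k] = v
    h[pad - k] = v
    return h


def ramp_filter(sino: Sinogram, min_pad: Optional[int] = None) -> Sinogram:
    """Filter each column with the |omega| ramp in the 1-D Fourier domain.

    Columns are zero-padded to a power of two >= 2 * n_bins so the circular
    convolution equals the linear one; the result is therefore independent
    of any further padding.  The DC component of each filtered column is
    near zero (the ramp kills constants).
    """
    n_bins = sino.geometry.n_bins
    if n_bins < 2:
        raise ShapeError("ramp filter needs at least 2 detector bins")
    pad = 64
    target = max(2 * n_bins, min_pad or 0)
    while pad < target:
        pad *= 2
    tau = sino.geometry.bin_spacing
    h = _ramp_kernel(pad, tau)
    ramp = np.fft.rfft(h).real  # kernel is symmetric -> real transform
    spec = np.fft.rfft(sino.values, n=pad, axis=0)
    out = np.fft.irfft(spec * ramp[:, None], n=pad, axis=0)[:n_bins]
    # convolution integral approximated by tau * discrete convolution
    return Sinogram(out * tau, sino.geometry)


def split_projections(sino: Sinogram) -> tuple[Sinogram, Sinogram]:
    """Known/unknown decomposition ``p = chi_Omega p + (1 - chi_Omega) p``.

    Both halves keep the full angular grid with the complementary columns
    zeroed, so ``p_known + p_unknown`` reconstitutes the input exactly.
    """
    known = sino.geometry.known
    p_known = sino.values * known[None, :]
    p_unknown = sino.values * (~known)[None, :]
    return (Sinogram(p_known, sino.geometry), Sinogram(p_unknown, sino.geometry))
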