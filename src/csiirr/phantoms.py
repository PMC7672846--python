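"""Synthetic specimens and tilt-series simulation.

Biological ultrastructure imaged by electron tomography is sparse: bright
macromolecular features sit in a mostly empty solvent background.  The
phantom generator reproduces exactly that property — randomly placed
soft-edged ellipses inside an inscribed circular support — so the whole
benchmark suite runs without downloading any density map.

The tilt-series simulator builds the full angular grid at the requested
increment across the open interval (-90, 90) degrees, marks the angles
inside the measured range as known, and zeroes the missing-wedge columns;
noise is injected only into measured columns, calibrated to a target
signal-to-noise ratio defined as var(signal) / var(noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    GeometryError,
    Image2D,
    Sinogram,
    SupportMask,
    TiltGeometry,
    radon,
)


class PhantomGenerationError(RuntimeError):
    """Sparsity target unreachable with the requested feature sizes."""


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a sparse blob phantom.

    ``n_features=None`` lets the generator derive a feature count from the
    sparsity target and mean feature area.
    """

    size: int = 128
    n_features: int | None = None
    density_range: tuple[float, float] = (0.4, 1.0)
    feature_radius_range: tuple[float, float] = (2.5, 7.0)
    sparsity_target: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sparsity_target < 1.0:
            raise ValueError("sparsity_target must be in (0, 1)")
        if self.n_features is not None and self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        lo, hi = self.feature_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid feature_radius_range")


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise level expressed as a signal-to-noise variance ratio."""

    snr: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def _auto_n_features(spec: PhantomSpec) -> int:
    """Feature count whose expected ellipse union hits the sparsity target."""
    n = spec.size
    r_mean = 0.5 * (spec.feature_radius_range[0] + spec.feature_radius_range[1])
    area_mean = np.pi * r_mean**2
    place_radius = 0.40 * n
    place_area = np.pi * place_radius**2
    want = spec.sparsity_target * n * n
    if want >= place_area:
        raise PhantomGenerationError(
            "sparsity target exceeds the available placement area"
        )
    # union of k random ellipses over the placement disk:
    # covered ~ A_p (1 - exp(-k a / A_p))
    k = -place_area / area_mean * np.log(1.0 - want / place_area)
    return max(1, int(round(k)))


def make_sparse_phantom(spec: PhantomSpec) -> tuple[Image2D, SupportMask]:
    """Generate a sparse, nonnegative phantom plus its disk support mask.

    The nonzero pixel fraction is required to land within +-20% of
    ``spec.sparsity_target``; placements are re-drawn (bounded retries)
    until it does.
    """
    n = spec.size
    rng = np.random.default_rng(spec.seed)
    n_feat = spec.n_features if spec.n_features is not None else _auto_n_features(spec)
    support = SupportMask.inscribed_disk(n)
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    place_radius = 0.40 * n
    lo_frac = 0.8 * spec.sparsity_target
    hi_frac = 1.2 * spec.sparsity_target

    for _ in range(60):
        img = np.zeros((n, n))
        for _f in range(n_feat):
            rad = np.sqrt(rng.uniform(0.0, 1.0)) * place_radius
            phi = rng.uniform(0.0, 2.0 * np.pi)
            cx = c + rad * np.cos(phi)
            cy = c + rad * np.sin(phi)
            a, b = rng.uniform(*spec.feature_radius_range, size=2)
            theta = rng.uniform(0.0, np.pi)
            dens = rng.uniform(*spec.density_range)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            m = (u / a) ** 2 + (v / b) ** 2
            feat = dens * np.clip(1.0 - m, 0.0, None) ** 0.7  # soft edge
            np.maximum(img, feat, out=img)
        img[~support.mask] = 0.0
        frac = np.count_nonzero(img) / img.size
        if lo_frac <= frac <= hi_frac:
            return Image2D(img, support=support), support
    raise PhantomGenerationError(
        f"could not reach nonzero fraction {spec.sparsity_target:+.3f} +-20% "
        f"with {n_feat} features of radius {spec.feature_radius_range}"
    )


def tilt_grid(angle_min: float, angle_max: float, increment: float,
              n_bins: int, bin_spacing: float = 1.0) -> TiltGeometry:
    """Full angular grid over (-90, 90) at ``increment``, anchored so the
    measured range [angle_min, angle_max] is sampled exactly; angles inside
    that range are marked known, the rest form the missing wedge."""
    if increment <= 0:
        raise GeometryError("increment must be positive")
    if angle_min >= angle_max:
        raise GeometryError("angle_min must be < angle_max")
    if increment > (angle_max - angle_min):
        raise GeometryError("increment larger than the measured range")
    eps = 1e-9
    n_down = int(np.floor((angle_min + 90.0 - eps) / increment))
    n_up = int(np.floor((90.0 - eps - angle_min) / increment))
    angles = angle_min + increment * np.arange(-n_down, n_up + 1)
    known = (angles >= angle_min - eps) & (angles <= angle_max + eps)
    return TiltGeometry(angles, known, n_bins, bin_spacing)


def simulate_tilt_series(image: Image2D, angle_min: float, angle_max: float,
                         increment: float) -> Sinogram:
    """Project the image on the full (-90, 90) grid and zero the wedge.

    The returned sinogram carries measured data only at known angles: the
    simulator never leaks missing-wedge projections.
    """
    geom = tilt_grid(angle_min, angle_max, increment, n_bins=image.n,
                     bin_spacing=image.pixel_size)
    sino = radon(image, geom)
    sino.values[:, ~geom.known] = 0.0
    return sino


def add_noise(sino: Sinogram, noise: NoiseSpec) -> Sinogram:
    """Add zero-mean Gaussian noise to the known columns only.

    Noise variance is var(known signal) / snr; wedge columns carry no data
    and are left untouched.
    """
    known = sino.geometry.known
    if not known.any():
        raise ValueError("no known columns to add noise to")
    signal = sino.values[:, known]
    var = float(np.var(signal))
    if var == 0.0:
        raise ValueError("known signal has zero variance; SNR undefined")
    rng = np.random.default_rng(noise.seed)
    sigma = np.sqrt(var / noise.snr)
    out = sino.values.copy()
    out[:, known] += rng.normal(0.0, sigma, size=signal.shape)
    return Sinogram(out, sino.geometry)
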