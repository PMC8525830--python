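"""Cone-mosaic density mapping and hexagonal-packing sampling limits.

A marked cone mosaic (a list of cone-center coordinates, in arcmin) is
turned into a binary raster, convolved with a circular window (default
diameter 8 arcmin) to obtain a continuous density field in cones/deg^2,
and the field's maximum inside the fully-covered region defines the cone
density peak.  Under the assumption of hexagonal packing, a density D
corresponds to a center-to-center spacing a with D = 2/(sqrt(3) a^2), and
the highest resolvable spatial frequency (the Nyquist, or sampling, limit)
is N_c = 1/(sqrt(3) a) cycles/deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

ARCMIN_PER_DEG = 60.0

__all__ = [
    "ConeMosaic",
    "DensityMap",
    "SamplingLimit",
    "rasterize_cones",
    "density_map",
    "nyquist_limit",
    "density_at",
    "mosaic_density_map",
]


class ConeCollisionError(ValueError):
    """Two cones map to the same raster pixel."""


@dataclass
class ConeMosaic:
    """Cone center coordinates with rasterization geometry.

    Parameters
    ----------
    cones : (n, 2) array
        Cone centers, arcmin, columns (x, y).
    pixel_scale : float
        Rasterization scale, arcmin per pixel.  Default 0.1 arcmin/px is
        well below a foveal cone diameter, so distinct cones map to
        distinct pixels.
    origin : (2,) array, optional
        Arcmin coordinate of pixel (0, 0).  Defaults to the cone bounding
        box minimum minus a half-window margin of 5 arcmin.
    """

    cones: np.ndarray
    pixel_scale: float = 0.1
    origin: np.ndarray | None = None
    _margin: float = field(default=5.0, repr=False)

    def __post_init__(self) -> None:
        self.cones = np.atleast_2d(np.asarray(self.cones, dtype=float))
        if self.cones.size == 0:
            self.cones = self.cones.reshape(0, 2)
        if self.cones.shape[1] != 2:
            raise ValueError("cones must be an (n, 2) array")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        if self.origin is None:
            if len(self.cones):
                self.origin = self.cones.min(axis=0) - self._margin
            else:
                self.origin = np.zeros(2)
        self.origin = np.asarray(self.origin, dtype=float)
        if len(self.cones) > 1:
            # cheap duplicate guard: identical grid cells at 1e-6 arcmin
            key = np.round(self.cones / 1e-6).astype(np.int64)
            _, counts = np.unique(key, axis=0, return_counts=True)
            if np.any(counts > 1):
                raise ValueError("duplicate cone coordinates (closer than 1e-6 arcmin)")

    @property
    def n_cones(self) -> int:
        return len(self.cones)


@dataclass
class DensityMap:
    """Cone density field (cones/deg^2) on a pixel grid.

    ``D[i, j]`` is the density at pixel row i, column j; the arcmin
    coordinate of pixel (i, j) is ``origin + pixel_scale * (j, i)``.
    ``peak`` is the argmax restricted to pixels whose circular window lies
    fully inside the image (``valid_margin = window/2`` arcmin from every
    edge).
    """

    D: np.ndarray
    window: float
    pixel_scale: float
    origin: np.ndarray
    peak: np.ndarray
    valid_margin: float
    peak_density: float

    def extent_arcmin(self) -> tuple[float, float, float, float]:
        ny, nx = self.D.shape
        x0, y0 = self.origin
        return (x0, x0 + (nx - 1) * self.pixel_scale, y0, y0 + (ny - 1) * self.pixel_scale)


@dataclass
class SamplingLimit:
    """Hexagonal-packing sampling limit at a retinal location."""

    N_c: float  # cycles/deg
    density: float  # cones/deg^2
    location: np.ndarray  # arcmin

    def __post_init__(self) -> None:
        if self.N_c <= 0:
            raise ValueError("N_c must be positive")


def rasterize_cones(mosaic: ConeMosaic, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Binary image with exactly one 1-valued pixel per cone.

    The pixel index of a cone at (x, y) arcmin is
    ``(round((y - origin_y)/scale), round((x - origin_x)/scale))``.

    Raises
    ------
    ConeCollisionError
        If two cones fall on the same pixel at this ``pixel_scale``.
    """
    scale = mosaic.pixel_scale
    if shape is None:
        if len(mosaic.cones):
            span = mosaic.cones.max(axis=0) - mosaic.origin + mosaic._margin
        else:
            span = np.array([1.0, 1.0])
        nx, ny = (np.ceil(span / scale).astype(int) + 1)
        shape = (ny, nx)
    img = np.zeros(shape, dtype=np.uint8)
    if not len(mosaic.cones):
        return img
    idx = np.rint((mosaic.cones - mosaic.origin) / scale).astype(int)
    cols, rows = idx[:, 0], idx[:, 1]
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]:
        raise ValueError("cone falls outside the raster; enlarge shape or move origin")
    flat = rows * shape[1] + cols
    uniq, first, counts = np.unique(flat, return_index=True, return_counts=True)
    if np.any(counts > 1):
        bad = uniq[counts > 1][0]
        pair = np.flatnonzero(flat == bad)[:2]
        raise ConeCollisionError(
            f"cones {pair[0]} at {mosaic.cones[pair[0]]} and {pair[1]} at "
            f"{mosaic.cones[pair[1]]} map to the same pixel "
            f"(row {bad // shape[1]}, col {bad % shape[1]}) at pixel_scale={scale}"
        )
    img[rows, cols] = 1
    return img


def _disk_kernel(radius_px: float) -> np.ndarray:
    r = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (xx * xx + yy * yy <= radius_px * radius_px).astype(float)


def density_map(
    binary: np.ndarray,
    pixel_scale: float,
    window: float = 8.0,
    origin: np.ndarray | None = None,
) -> DensityMap:
    """Circular-window density of a binary cone map, in cones/deg^2.

    Each grid value is the count of 1-pixels whose centers lie within
    ``window/2`` arcmin of the pixel center, divided by the window area in
    deg^2.  The peak is the maximum over pixels whose window lies fully
    inside the image; ties are broken by the smallest row-major index with
    a warning.
    """
    if origin is None:
        origin = np.zeros(2)
    origin = np.asarray(origin, dtype=float)
    radius_px = (window / 2.0) / pixel_scale
    if 2 * radius_px < 3:
        raise ValueError("window must span at least 3 pixels")
    kernel = _disk_kernel(radius_px)
    area_deg2 = kernel.sum() * (pixel_scale / ARCMIN_PER_DEG) ** 2
    counts = fftconvolve(binary.astype(float), kernel, mode="same")
    counts = np.rint(counts)  # binary counts are integers; remove FFT noise
    counts[counts < 0] = 0.0
    D = counts / area_deg2

    margin_px = int(np.ceil(radius_px))
    ny, nx = D.shape
    if ny <= 2 * margin_px or nx <= 2 * margin_px:
        raise ValueError("image smaller than the convolution window")
    interior = D[margin_px:ny - margin_px, margin_px:nx - margin_px]
    if binary.sum() == 0:
        raise ValueError("all-zero cone image: density peak undefined")
    flat_idx = int(np.argmax(interior))
    best = interior.flat[flat_idx]
    n_ties = int(np.sum(interior == best))
    if n_ties > 1:
        warnings.warn(f"density peak tie ({n_ties} pixels); smallest row-major index used")
    pr, pc = np.unravel_index(flat_idx, interior.shape)
    pr += margin_px
    pc += margin_px
    peak = origin + pixel_scale * np.array([pc, pr], dtype=float)
    return DensityMap(
        D=D,
        window=window,
        pixel_scale=pixel_scale,
        origin=origin,
        peak=peak,
        valid_margin=window / 2.0,
        peak_density=float(best),
    )


def mosaic_density_map(mosaic: ConeMosaic, window: float = 8.0) -> DensityMap:
    """Convenience: rasterize a mosaic and compute its density map."""
    binary = rasterize_cones(mosaic)
    return density_map(binary, mosaic.pixel_scale, window=window, origin=mosaic.origin)


def nyquist_limit(density: float) -> float:
    """Hexagonal-packing sampling limit, cycles/deg, for ``density`` cones/deg^2.

    With D = 2/(sqrt(3) a^2) cones/deg^2 at spacing a deg, the highest
    resolvable frequency is N_c = 1/(sqrt(3) a) = sqrt(D/(2 sqrt(3))).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    return float(np.sqrt(density / (2.0 * np.sqrt(3.0))))


def density_at(dmap: DensityMap, location) -> float:
    """Bilinearly interpolated density (cones/deg^2) at an arcmin location.

    ``location`` must lie in the valid region (at least ``valid_margin``
    arcmin from every image edge).
    """
    loc = np.asarray(location, dtype=float)
    gx = (loc[0] - dmap.origin[0]) / dmap.pixel_scale
    gy = (loc[1] - dmap.origin[1]) / dmap.pixel_scale
    ny, nx = dmap.D.shape
    m = dmap.valid_margin / dmap.pixel_scale
    if not (m - 1e-9 <= gx <= nx - 1 - m + 1e-9 and m - 1e-9 <= gy <= ny - 1 - m + 1e-9):
        raise ValueError(f"location {loc} outside the valid density region")
    x0, y0 = int(np.floor(gx)), int(np.floor(gy))
    x1, y1 = min(x0 + 1, nx - 1), min(y0 + 1, ny - 1)
    fx, fy = gx - x0, gy - y0
    d00, d01 = dmap.D[y0, x0], dmap.D[y0, x1]
    d10, d11 = dmap.D[y1, x0], dmap.D[y1, x1]
    return float((1 - fy) * ((1 - fx) * d00 + fx * d01) + fy * ((1 - fx) * d10 + fx * d11))


def sampling_limit_at(dmap: DensityMap, location) -> SamplingLimit:
    """Sampling limit at an arbitrary location of a density map."""
    d = density_at(dmap, location)
    return SamplingLimit(N_c=nyquist_limit(d), density=d, location=np.asarray(location, float))
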