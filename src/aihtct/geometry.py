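"""Limited-angle parallel-beam geometry, forward/back projection, FBP.

The forward projector realizes the discrete line-integral operator Z of
the limited-angle acquisition.  Rays are discretized with Joseph-style
linear interpolation along the ray's dominant axis, assembled once per
(geometry, image shape) into a sparse system matrix and cached; the
backprojector applies the exact transpose, so the pair is a matched
adjoint (required for the convergence properties of SART).

Angle convention: degrees, 0 deg = rays running along image rows,
angles increasing counter-clockwise.  Detector offsets are centered on
the rotation axis (image center) with uniform spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .phantoms import Image2D, as_image

__all__ = [
    "ProjectionGeometry",
    "Sinogram",
    "limited_angle_geometry",
    "default_detector_count",
    "forward_project",
    "back_project",
    "add_noise",
    "fbp_reconstruct",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam acquisition over an ordered set of view angles."""

    angles: tuple[float, ...]
    n_detectors: int
    detector_spacing: float = 1.0
    angular_range: tuple[float, float] = (0.0, 180.0)

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles, dtype=np.float64)
        if ang.size == 0:
            raise ValueError("geometry needs at least one view angle")
        if ang.size > 1 and not np.all(np.diff(ang) > 0):
            raise ValueError("angles must be strictly increasing")
        start, end = self.angular_range
        if np.any(ang < start) or np.any(ang >= end):
            raise ValueError("all angles must lie in [start, end)")
        if self.n_detectors < 1:
            raise ValueError("n_detectors must be positive")
        if self.detector_spacing <= 0:
            raise ValueError("detector_spacing must be positive")

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def detector_offsets(self) -> np.ndarray:
        """Physical detector-bin center offsets from the rotation axis."""
        n = self.n_detectors
        return (np.arange(n) - (n - 1) / 2.0) * self.detector_spacing


@dataclass
class Sinogram:
    """Projection data: line integrals indexed by (angle, detector bin)."""

    values: np.ndarray
    geometry: ProjectionGeometry
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_angles, self.geometry.n_detectors)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


def default_detector_count(image_size: int | tuple[int, int]) -> int:
    """ceil(image diagonal in pixels) + 1: full object coverage."""
    if isinstance(image_size, int):
        rows = cols = image_size
    else:
        rows, cols = image_size
    return int(np.ceil(np.hypot(rows, cols))) + 1


def limited_angle_geometry(
    range_deg: tuple[float, float],
    n_angles: int,
    n_detectors: int,
    detector_spacing: float = 1.0,
) -> ProjectionGeometry:
    """Uniformly spaced views on [start, end) with step (end-start)/n_angles.

    The span must not exceed 180 deg (parallel-beam half turn).
    """
    start, end = float(range_deg[0]), float(range_deg[1])
    if end <= start:
        raise ValueError("angular range must satisfy end > start")
    if end - start > 180.0:
        raise ValueError("angular span must not exceed 180 degrees")
    if n_angles < 1:
        raise ValueError("n_angles must be positive")
    step = (end - start) / n_angles
    angles = tuple(start + step * i for i in range(n_angles))
    return ProjectionGeometry(
        angles=angles,
        n_detectors=n_detectors,
        detector_spacing=detector_spacing,
        angular_range=(start, end),
    )


def _angle_entries(
    theta_deg: float,
    image_shape: tuple[int, int],
    offsets: np.ndarray,
    pixel_spacing: float,
):
    """COO entries (detector, pixel, weight) of one view of the Joseph projector."""
    nrows, ncols = image_shape
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    n_det = offsets.size
    if abs(c) >= abs(s):
        # march along columns; interpolate between rows
        x = (np.arange(ncols) - (ncols - 1) / 2.0) * pixel_spacing
        y = offsets[None, :] / c + x[:, None] * (s / c)  # (ncols, n_det)
        row_f = (nrows - 1) / 2.0 - y / pixel_spacing
        dl = pixel_spacing / abs(c)
        fixed = np.broadcast_to(np.arange(ncols)[:, None], row_f.shape)
        det = np.broadcast_to(np.arange(n_det)[None, :], row_f.shape)
        i0 = np.floor(row_f).astype(np.int64)
        frac = row_f - i0
        pix0 = i0 * ncols + fixed
        pix1 = (i0 + 1) * ncols + fixed
        ok0 = (i0 >= 0) & (i0 < nrows)
        ok1 = (i0 + 1 >= 0) & (i0 + 1 < nrows)
    else:
        # march along rows; interpolate between columns
        y = ((nrows - 1) / 2.0 - np.arange(nrows)) * pixel_spacing
        x = (y[:, None] * c - offsets[None, :]) / s  # (nrows, n_det)
        col_f = x / pixel_spacing + (ncols - 1) / 2.0
        dl = pixel_spacing / abs(s)
        fixed = np.broadcast_to(np.arange(nrows)[:, None], col_f.shape)
        det = np.broadcast_to(np.arange(n_det)[None, :], col_f.shape)
        i0 = np.floor(col_f).astype(np.int64)
        frac = col_f - i0
        pix0 = fixed * ncols + i0
        pix1 = fixed * ncols + i0 + 1
        ok0 = (i0 >= 0) & (i0 < ncols)
        ok1 = (i0 + 1 >= 0) & (i0 + 1 < ncols)
    w0 = (1.0 - frac) * dl
    w1 = frac * dl
    return (
        np.concatenate([det[ok0], det[ok1]]),
        np.concatenate([pix0[ok0], pix1[ok1]]),
        np.concatenate([w0[ok0], w1[ok1]]),
    )


_MATRIX_CACHE: dict[tuple, tuple[sparse.csr_array, sparse.csr_array]] = {}
_CACHE_LIMIT = 8


def system_matrix(
    geometry: ProjectionGeometry,
    image_shape: tuple[int, int],
    pixel_spacing: float = 1.0,
) -> tuple[sparse.csr_array, sparse.csr_array]:
    """The sparse projector matrix Z and its transpose, cached.

    Z has one row per (angle, detector) ray and one column per pixel in
    row-major order.
    """
    key = (geometry.angles, geometry.n_detectors, geometry.detector_spacing,
           tuple(image_shape), float(pixel_spacing))
    hit = _MATRIX_CACHE.get(key)
    if hit is not None:
        return hit
    offsets = geometry.detector_offsets
    n_det = geometry.n_detectors
    rows_all, cols_all, vals_all = [], [], []
    for a, ang in enumerate(geometry.angles):
        det, pix, w = _angle_entries(ang, image_shape, offsets, pixel_spacing)
        rows_all.append(det + a * n_det)
        cols_all.append(pix)
        vals_all.append(w)
    Z = sparse.csr_array(
        (
            np.concatenate(vals_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(geometry.n_angles * n_det, image_shape[0] * image_shape[1]),
    )
    Zt = sparse.csr_array(Z.T)
    if len(_MATRIX_CACHE) >= _CACHE_LIMIT:
        _MATRIX_CACHE.pop(next(iter(_MATRIX_CACHE)))
    _MATRIX_CACHE[key] = (Z, Zt)
    return Z, Zt


def _check_coverage(image: Image2D, geometry: ProjectionGeometry) -> None:
    diag = np.hypot(*image.shape) * image.pixel_spacing
    row_len = geometry.n_detectors * geometry.detector_spacing
    if row_len < diag:
        raise ValueError(
            f"detector row ({row_len:g}) shorter than image diagonal ({diag:g}); "
            "truncated projections are not modeled"
        )


def forward_project(image, geometry: ProjectionGeometry) -> Sinogram:
    """Discrete line integrals of the image along every ray of the geometry."""
    image = as_image(image)
    _check_coverage(image, geometry)
    Z, _ = system_matrix(geometry, image.shape, image.pixel_spacing)
    vals = (Z @ image.pixels.ravel()).reshape(geometry.n_angles, geometry.n_detectors)
    return Sinogram(vals, geometry, noise_level=0.0)


def back_project(
    sino: Sinogram,
    image_shape: int | tuple[int, int] | None = None,
    pixel_spacing: float = 1.0,
) -> Image2D:
    """Exact adjoint of :func:`forward_project`.

    If ``image_shape`` is omitted, the largest square grid whose diagonal
    fits the detector row is used.
    """
    if image_shape is None:
        n = int((sino.geometry.n_detectors - 1) / np.sqrt(2.0))
        image_shape = (n, n)
    elif isinstance(image_shape, int):
        image_shape = (image_shape, image_shape)
    _, Zt = system_matrix(sino.geometry, image_shape, pixel_spacing)
    pix = (Zt @ sino.values.ravel()).reshape(image_shape)
    return Image2D(pix, pixel_spacing)


def add_noise(sino: Sinogram, sigma: float, seed: int) -> Sinogram:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Sinogram(sino.values.copy(), sino.geometry, noise_level=0.0)
    rng = np.random.default_rng(seed)
    noisy = sino.values + rng.normal(0.0, sigma, size=sino.values.shape)
    return Sinogram(noisy, sino.geometry, noise_level=float(sigma))


def _ramp_filter(sino_values: np.ndarray, detector_spacing: float) -> np.ndarray:
    n_det = sino_values.shape[1]
    n_fft = 1 << int(np.ceil(np.log2(max(2 * n_det, 16))))
    freqs = np.fft.fftfreq(n_fft, d=detector_spacing)
    filt = np.abs(freqs)
    spec = np.fft.fft(sino_values, n=n_fft, axis=1) * filt[None, :]
    return np.real(np.fft.ifft(spec, axis=1))[:, :n_det]


def fbp_reconstruct(
    sino: Sinogram, size: int, pixel_spacing: float = 1.0
) -> Image2D:
    """Filtered backprojection with a Ram-Lak (ramp) filter.

    Each projection is ramp-filtered in the frequency domain (zero-padded
    to the next power of two), then smeared back over the image by
    pixel-driven linear interpolation; the sum is scaled by the angular
    step in radians.  On limited ranges this is the classic artifact-laden
    baseline.
    """
    geom = sino.geometry
    q = _ramp_filter(sino.values, geom.detector_spacing)
    offsets = geom.detector_offsets
    coords = (np.arange(size) - (size - 1) / 2.0) * pixel_spacing
    X = coords[None, :]
    Y = -coords[:, None]  # y up, row 0 at top
    recon = np.zeros((size, size))
    for a, ang in enumerate(geom.angles):
        th = np.deg2rad(ang)
        t = -X * np.sin(th) + Y * np.cos(th)
        recon += np.interp(t.ravel(), offsets, q[a], left=0.0, right=0.0).reshape(
            size, size
        )
    span = geom.angular_range[1] - geom.angular_range[0]
    recon *= np.deg2rad(span / geom.n_angles)
    return Image2D(recon, pixel_spacing)
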