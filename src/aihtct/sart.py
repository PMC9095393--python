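"""Simultaneous algebraic reconstruction technique (SART).

One sweep visits the views in their fixed ascending angular order; for
each view a the pixels are updated simultaneously from all rays of that
view:

    h <- h + g * V_a^-1 Z_a^T B_a (l_a - Z_a h)

where Z_a is the block of projector rows belonging to view a,
B_a = diag(1 / ray row sums) and V_a^-1 = diag(1 / per-view pixel
column sums), and g in (0, 2] is a relaxation factor.  This is the
classical SART scheme: simultaneous within a view, sequential across
views, which converges far faster per sweep than fully simultaneous
(SIRT-style) iteration while remaining deterministic because the view
order is fixed.  Rays that miss the image and pixels unseen by a view
get weight 0 rather than infinity and never contribute.

Fixed points are exactly the images whose per-view reprojection
residuals are annihilated by the corresponding Z_a^T B_a; in particular
any image consistent with the data (Z h = l) is a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .geometry import ProjectionGeometry, Sinogram, system_matrix
from .phantoms import Image2D, as_image

__all__ = ["SARTWeights", "compute_sart_weights", "sart_step", "run_sart"]


def _safe_inverse(sums: np.ndarray) -> np.ndarray:
    out = np.zeros_like(sums)
    nz = sums > 1e-12
    out[nz] = 1.0 / sums[nz]
    return out


@dataclass
class SARTWeights:
    """Diagonal SART weights plus the cached per-view projector blocks.

    ``row_weights`` are the inverse ray row sums (diagonal of B) over
    all rays; ``col_weights`` the inverse global pixel column sums
    (diagonal of V^-1 for the whole projector).  The per-view update
    uses ``view_col_weights``, the per-view column sums' inverses.
    """

    row_weights: np.ndarray  # flattened (n_angles * n_det)
    col_weights: np.ndarray  # flattened (rows * cols), global
    view_col_weights: np.ndarray  # (n_angles, rows * cols)
    geometry: ProjectionGeometry
    image_shape: tuple[int, int]
    _blocks: list = field(default_factory=list, repr=False)


def compute_sart_weights(
    geometry: ProjectionGeometry,
    image_shape: int | tuple[int, int],
    pixel_spacing: float = 1.0,
) -> SARTWeights:
    """Row/column sums of the projector, obtained by projecting ones.

    Projecting the all-ones image gives the ray row sums; backprojecting
    the all-ones sinogram (per view, and in total) gives the column sums.
    """
    if isinstance(image_shape, int):
        image_shape = (image_shape, image_shape)
    Z, Zt = system_matrix(geometry, image_shape, pixel_spacing)
    n_det = geometry.n_detectors
    n_pix = image_shape[0] * image_shape[1]
    row_sums = Z @ np.ones(n_pix)
    row_weights = _safe_inverse(row_sums)
    col_sums = Zt @ np.ones(Z.shape[0])
    view_col = np.empty((geometry.n_angles, n_pix))
    blocks = []
    for a in range(geometry.n_angles):
        Za = sparse.csr_array(Z[a * n_det:(a + 1) * n_det])
        Zat = sparse.csr_array(Za.T)
        cs = Zat @ np.ones(n_det)
        view_col[a] = _safe_inverse(cs)
        blocks.append((Za, Zat, row_weights[a * n_det:(a + 1) * n_det], view_col[a]))
    return SARTWeights(
        row_weights=row_weights,
        col_weights=_safe_inverse(col_sums),
        view_col_weights=view_col,
        geometry=geometry,
        image_shape=image_shape,
        _blocks=blocks,
    )


def _sart_update(
    h: np.ndarray,
    Z: sparse.csr_array,
    Zt: sparse.csr_array,
    row_w: np.ndarray,
    col_w: np.ndarray,
    b: np.ndarray,
    g: float,
) -> np.ndarray:
    """One simultaneous update from one ray block, on flattened arrays."""
    residual = b - Z @ h
    return h + g * (col_w * (Zt @ (row_w * residual)))


def sart_step(
    h,
    sino: Sinogram,
    weights: SARTWeights,
    g: float = 1.0,
) -> Image2D:
    """One SART sweep: sequential pass over all views in angular order."""
    if not (0.0 < g <= 2.0):
        raise ValueError("relaxation factor g must lie in (0, 2]")
    h = as_image(h)
    if h.shape != weights.image_shape:
        raise ValueError("image shape does not match SART weights")
    n_det = weights.geometry.n_detectors
    b = sino.values.reshape(weights.geometry.n_angles, n_det)
    x = h.pixels.ravel().copy()
    for a, (Za, Zat, rw, cw) in enumerate(weights._blocks):
        x = _sart_update(x, Za, Zat, rw, cw, b[a], g)
    return Image2D(x.reshape(weights.image_shape), h.pixel_spacing)


def run_sart(
    sino: Sinogram,
    size: int | tuple[int, int],
    n_iters: int = 100,
    g: float = 1.0,
    nonneg: bool = True,
) -> Image2D:
    """Iterate SART sweeps from the zero image.

    If ``nonneg``, negatives are clipped to zero after every sweep
    (projection onto the physical constraint set of non-negative
    attenuation).
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    weights = compute_sart_weights(sino.geometry, size)
    h = Image2D(np.zeros(weights.image_shape))
    for _ in range(n_iters):
        h = sart_step(h, sino, weights, g)
        if nonneg:
            h = Image2D(np.maximum(h.pixels, 0.0), h.pixel_spacing)
    return h
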