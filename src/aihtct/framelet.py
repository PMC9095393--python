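"""Piecewise-linear B-spline tight-framelet transform.

The filter bank holds the three 1D filters

    k0 = [1, 2, 1] / 4          (low pass)
    k1 = sqrt(2) [1, 0, -1] / 4 (first difference)
    k2 = [-1, 2, -1] / 4        (second difference)

which satisfy the unitary condition |k0^(w)|^2 + |k1^(w)|^2 + |k2^(w)|^2 = 1
for every frequency w, so the undecimated separable 2D transform A built
from the nine outer-product kernels k_i (rows) x k_j (cols) is a tight
frame with frame bound 1: A^T A = I.  Analysis uses periodic boundary
extension and no decimation; synthesis is the exact transpose, so
synthesize(analyze(x)) == x to machine precision and coefficients may be
modified (thresholded) in between without any reconstruction bias from
the transform itself.

Subband ordering is row-filter-major: (0,0), (0,1), (0,2), (1,0), ...,
(2,2); (0,0) is the low-pass approximation, the other eight are detail
subbands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantoms import Image2D, as_image

__all__ = [
    "FrameletBank",
    "FrameletCoefficients",
    "build_filter_bank",
    "analyze",
    "synthesize",
    "DETAIL_INDEX",
]

#: The eight detail subband index pairs in row-filter-major order.
DETAIL_INDEX: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(3) for j in range(3) if (i, j) != (0, 0)
)


@dataclass(frozen=True)
class FrameletBank:
    """The three 1D spline framelet filters (immutable)."""

    filters_1d: tuple[np.ndarray, np.ndarray, np.ndarray]

    def kernel(self, i: int, j: int) -> np.ndarray:
        """Separable 2D kernel k_i (rows) x k_j (cols)."""
        return np.outer(self.filters_1d[i], self.filters_1d[j])


def _dtft_mag2(filt: np.ndarray, omega: np.ndarray) -> np.ndarray:
    n = np.arange(filt.size)
    resp = np.exp(-1j * np.outer(omega, n)) @ filt
    return np.abs(resp) ** 2


def build_filter_bank() -> FrameletBank:
    """Construct the bank and verify the tight-frame (unitary) condition."""
    k0 = np.array([1.0, 2.0, 1.0]) / 4.0
    k1 = np.sqrt(2.0) * np.array([1.0, 0.0, -1.0]) / 4.0
    k2 = np.array([-1.0, 2.0, -1.0]) / 4.0
    omega = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
    total = _dtft_mag2(k0, omega) + _dtft_mag2(k1, omega) + _dtft_mag2(k2, omega)
    if not np.allclose(total, 1.0, atol=1e-12):
        raise AssertionError("framelet filters violate the unitary condition")
    return FrameletBank(filters_1d=(k0, k1, k2))


@dataclass
class FrameletCoefficients:
    """Nine undecimated subbands of one image, stacked as (3, 3, rows, cols)."""

    data: np.ndarray
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (3, 3, *self.source_shape):
            raise ValueError("subband stack inconsistent with source_shape")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("framelet coefficients must be finite")

    def subband(self, i: int, j: int) -> np.ndarray:
        return self.data[i, j]

    @property
    def lowpass(self) -> np.ndarray:
        return self.data[0, 0]

    def detail_count_nonzero(self) -> int:
        """Number of nonzero detail coefficients (the l0 regularizer value)."""
        return int(np.count_nonzero(self.data) - np.count_nonzero(self.data[0, 0]))

    def copy(self) -> "FrameletCoefficients":
        return FrameletCoefficients(self.data.copy(), self.source_shape)


def analyze(image, bank: FrameletBank) -> FrameletCoefficients:
    """Undecimated tight-frame decomposition (operator A).

    Subband (i, j) is the periodic cross-correlation of the image with
    the separable kernel k_i x k_j.  Linear in the image.
    """
    image = as_image(image)
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("framelet analysis requires an image of at least 3x3")
    x = image.pixels
    data = np.empty((3, 3, *x.shape))
    for i in range(3):
        for j in range(3):
            data[i, j] = ndimage.correlate(x, bank.kernel(i, j), mode="wrap")
    return FrameletCoefficients(data, x.shape)


def synthesize(coeffs: FrameletCoefficients, bank: FrameletBank) -> Image2D:
    """Transpose of :func:`analyze` (operator A^T); exact inverse on range(A)."""
    out = np.zeros(coeffs.source_shape)
    for i in range(3):
        for j in range(3):
            out += ndimage.convolve(coeffs.data[i, j], bank.kernel(i, j), mode="wrap")
    return Image2D(out)
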