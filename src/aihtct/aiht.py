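"""Adaptive iterative hard thresholding (AIHT) reconstruction.

The algorithm alternates three stages from the zero image:

1. a SART data-fidelity sweep,
2. framelet analysis of the iterate followed by hard thresholding of
   the eight detail subbands (the low pass is never thresholded),
3. framelet synthesis back to the image domain, optionally followed by
   projection onto the non-negative orthant.

Hard thresholding is the l0 proximal map: a coefficient y is zeroed
when |y| <= beta* and kept unchanged otherwise (the boundary case is
resolved to 0 for determinism).

The threshold beta* is either fixed (the "WF" wavelet-frame baseline)
or selected adaptively by a discrete L-curve: for each candidate t on a
grid, the thresholded-and-synthesized iterate is reprojected and the
point (log10 data misfit, log10 surviving detail-coefficient count) is
formed; the candidate at the corner of this trade-off curve — maximum
three-point Menger curvature, ties and degenerate flat curves broken
toward the smallest threshold — is chosen.  A single global threshold
is applied to all eight detail subbands by default; per-subband values
are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .framelet import (
    DETAIL_INDEX,
    FrameletBank,
    FrameletCoefficients,
    analyze,
    build_filter_bank,
    synthesize,
)
from .geometry import Sinogram, system_matrix
from .phantoms import Image2D
from .sart import compute_sart_weights, sart_step

__all__ = [
    "AIHTConfig",
    "TraceEntry",
    "hard_threshold",
    "select_threshold_lcurve",
    "run_aiht",
    "run_wf_baseline",
]


def _default_grid() -> np.ndarray:
    return np.geomspace(1e-4, 0.2, 12)


@dataclass
class AIHTConfig:
    """Iteration, relaxation, thresholding and constraint parameters."""

    n_iters: int = 200
    g: float = 1.0
    threshold_mode: str = "adaptive_lcurve"  # or "fixed"
    beta_star: float | Sequence[float] = 0.05
    lcurve_grid: np.ndarray = field(default_factory=_default_grid)
    lcurve_every: int = 10
    nonneg: bool = True
    seed: int = 0
    stop_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if not (0.0 < self.g <= 2.0):
            raise ValueError("relaxation g must lie in (0, 2]")
        if self.threshold_mode not in ("adaptive_lcurve", "fixed"):
            raise ValueError("threshold_mode must be 'adaptive_lcurve' or 'fixed'")
        if np.any(np.asarray(self.beta_star, dtype=float) < 0):
            raise ValueError("thresholds must be >= 0")
        grid = np.asarray(self.lcurve_grid, dtype=float)
        if self.threshold_mode == "adaptive_lcurve":
            if grid.size < 3 or np.any(np.diff(grid) <= 0):
                raise ValueError(
                    "lcurve_grid must be strictly increasing with >= 3 candidates"
                )
        self.lcurve_grid = grid
        if self.lcurve_every < 1:
            raise ValueError("lcurve_every must be >= 1")
        if self.stop_tol < 0:
            raise ValueError("stop_tol must be >= 0")


class TraceEntry(NamedTuple):
    """Per-iteration diagnostics of the AIHT loop."""

    iteration: int
    misfit: float
    n_surviving: int
    threshold: float


def _beta_vector(beta_star: float | Sequence[float]) -> np.ndarray:
    beta = np.asarray(beta_star, dtype=float)
    if beta.ndim == 0:
        beta = np.full(len(DETAIL_INDEX), float(beta))
    if beta.shape != (len(DETAIL_INDEX),):
        raise ValueError(
            f"beta_star must be a scalar or one value per detail subband "
            f"({len(DETAIL_INDEX)})"
        )
    if np.any(beta < 0):
        raise ValueError("thresholds must be >= 0")
    return beta


def hard_threshold(
    coeffs: FrameletCoefficients, beta_star: float | Sequence[float]
) -> FrameletCoefficients:
    """Zero detail coefficients of magnitude <= beta*; keep the rest.

    The low-pass subband always passes through unchanged.  Idempotent.
    """
    beta = _beta_vector(beta_star)
    out = coeffs.copy()
    for b, (i, j) in zip(beta, DETAIL_INDEX):
        band = out.data[i, j]
        band[np.abs(band) <= b] = 0.0
    return out


def _menger_curvature(p0, p1, p2) -> float:
    a = np.hypot(p1[0] - p0[0], p1[1] - p0[1])
    b = np.hypot(p2[0] - p1[0], p2[1] - p1[1])
    c = np.hypot(p2[0] - p0[0], p2[1] - p0[1])
    if a == 0.0 or b == 0.0 or c == 0.0:
        return 0.0
    cross = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0])
    return 2.0 * abs(cross) / (a * b * c)


def select_threshold_lcurve(
    h,
    sino: Sinogram,
    bank: FrameletBank,
    grid: Sequence[float],
) -> np.ndarray:
    """Pick the hard threshold at the corner of the misfit/sparsity L-curve.

    Returns one threshold per detail subband (all equal to the selected
    grid candidate).  Deterministic; the result is always a grid member.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3:
        raise ValueError("the L-curve grid needs at least 3 candidates")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("the L-curve grid must be strictly increasing")
    coeffs = analyze(h, bank)
    points = []
    for t in grid:
        thr = hard_threshold(coeffs, t)
        n_surv = thr.detail_count_nonzero()
        Z, _ = system_matrix(sino.geometry, coeffs.source_shape)
        resid = Z @ synthesize(thr, bank).pixels.ravel() - sino.values.ravel()
        misfit = float(np.linalg.norm(resid))
        points.append(
            (np.log10(max(misfit, 1e-300)), np.log10(max(n_surv, 1)))
        )
    curv = np.array(
        [
            _menger_curvature(points[k - 1], points[k], points[k + 1])
            for k in range(1, len(points) - 1)
        ]
    )
    if curv.size == 0 or np.max(curv) <= 0.0:
        best = grid[0]  # flat or degenerate curve: smallest threshold
    else:
        best = grid[int(np.argmax(curv)) + 1]  # argmax takes the first = smallest
    return np.full(len(DETAIL_INDEX), float(best))


def run_aiht(
    sino: Sinogram,
    size: int | tuple[int, int],
    config: AIHTConfig | None = None,
) -> tuple[Image2D, list[TraceEntry]]:
    """The full AIHT loop; returns the reconstruction and its trace."""
    config = config if config is not None else AIHTConfig()
    bank = build_filter_bank()
    weights = compute_sart_weights(sino.geometry, size)
    shape = weights.image_shape
    Z, _ = system_matrix(sino.geometry, shape)
    h = Image2D(np.zeros(shape))
    beta = (
        _beta_vector(config.beta_star)
        if config.threshold_mode == "fixed"
        else None
    )
    trace: list[TraceEntry] = []
    for m in range(config.n_iters):
        h_s = sart_step(h, sino, weights, config.g)
        if config.threshold_mode == "adaptive_lcurve" and m % config.lcurve_every == 0:
            beta = select_threshold_lcurve(h_s, sino, bank, config.lcurve_grid)
        coeffs = analyze(h_s, bank)
        thr = hard_threshold(coeffs, beta)
        h_new = synthesize(thr, bank)
        if config.nonneg:
            h_new = Image2D(np.maximum(h_new.pixels, 0.0))
        misfit = float(np.linalg.norm(Z @ h_new.pixels.ravel() - sino.values.ravel()))
        trace.append(
            TraceEntry(m, misfit, thr.detail_count_nonzero(), float(np.max(beta)))
        )
        delta = float(np.linalg.norm(h_new.pixels - h.pixels))
        scale = float(np.linalg.norm(h.pixels))
        h = h_new
        if scale > 0 and delta / scale < config.stop_tol:
            break
    return h, trace


def run_wf_baseline(
    sino: Sinogram,
    size: int | tuple[int, int],
    config: AIHTConfig | None = None,
) -> tuple[Image2D, list[TraceEntry]]:
    """Fixed-threshold wavelet-frame baseline: AIHT without adaptivity."""
    if config is None:
        config = AIHTConfig(threshold_mode="fixed")
    if config.threshold_mode != "fixed":
        raise ValueError("the WF baseline requires threshold_mode='fixed'")
    return run_aiht(sino, size, config)
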