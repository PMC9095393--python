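"""Reconstruction quality metrics: global RMSE and PSNR.

RMSE is computed over all pixels, RMSE = sqrt(sum_i (P_i - Q_i)^2 / M)
with M the total pixel count; PSNR = 10 log10(max|Q|^2 / RMSE^2) with
the peak taken from the reference image Q, so PSNR is deliberately
asymmetric in (P, Q).  Identical images give RMSE 0 and PSNR +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phantoms import as_image

__all__ = ["MetricsReport", "rmse", "psnr", "evaluate"]


@dataclass
class MetricsReport:
    rmse: float
    psnr: float
    n_pixels: int
    peak_value: float


def _pair(P, Q) -> tuple[np.ndarray, np.ndarray]:
    P, Q = as_image(P).pixels, as_image(Q).pixels
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    return P, Q


def rmse(P, Q) -> float:
    """Root mean square error between reconstruction P and reference Q."""
    P, Q = _pair(P, Q)
    return float(np.sqrt(np.mean((P - Q) ** 2)))


def psnr(P, Q) -> float:
    """Peak signal-to-noise ratio in dB; +inf when P == Q."""
    P, Q = _pair(P, Q)
    peak = float(np.max(np.abs(Q)))
    if peak == 0.0:
        raise ValueError("PSNR undefined for an identically-zero reference")
    err = float(np.sqrt(np.mean((P - Q) ** 2)))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / err**2)


def evaluate(P, Q) -> MetricsReport:
    """Both metrics plus the quantities they were computed from."""
    P_, Q_ = _pair(P, Q)
    return MetricsReport(
        rmse=rmse(P_, Q_),
        psnr=psnr(P_, Q_),
        n_pixels=int(Q_.size),
        peak_value=float(np.max(np.abs(Q_))),
    )
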