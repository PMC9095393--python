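"""Synthetic 2D test objects with known ground truth.

Phantoms are piecewise-constant attenuation maps on a square pixel grid,
the image class targeted by sparsity-promoting framelet regularization:
a small number of overlapping ellipses and rectangles, each adding a
constant intensity, on a constant background.

Coordinate convention (shared with :mod:`aihtct.geometry`): row 0 is the
top of the image; continuous coordinates place the image center at the
origin with y increasing upward; pixel centers sit at half-integer
offsets from the image edge.  Rasterization uses the center-point rule —
a pixel belongs to a shape iff its center lies inside — so phantoms are
exactly piecewise constant (no anti-aliasing).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Image2D",
    "Shape",
    "PhantomSpec",
    "make_shepp_logan",
    "make_piecewise_phantom",
    "default_phantom",
    "read_image",
    "write_image",
    "read_phantom_spec",
]


@dataclass
class Image2D:
    """A real-valued pixel grid: reconstruction target, phantom or result.

    Attenuation values are dimensionless on an arbitrary linear scale,
    typically in [0, 1]; no Hounsfield calibration is applied.
    """

    pixels: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2D pixel array")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError("Image2D requires at least 2x2 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D pixels must all be finite")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_image(obj, pixel_spacing: float = 1.0) -> Image2D:
    """Coerce an array (or pass through an Image2D) to :class:`Image2D`."""
    if isinstance(obj, Image2D):
        return obj
    return Image2D(np.asarray(obj, dtype=np.float64), pixel_spacing)


@dataclass
class Shape:
    """One additive primitive of a piecewise-constant phantom.

    kind
        ``"ellipse"`` or ``"rectangle"``.
    center
        (row, col) of the shape center, in pixel units from the top-left
        pixel edge (so ``size/2`` is the image center).
    size
        For an ellipse the two semi-axes (row_semi, col_semi); for a
        rectangle the full extents (height, width), all in pixels.
    rotation_deg
        Counter-clockwise rotation of the shape about its center.
    intensity
        Additive value; ``None`` means draw uniformly from [0.1, 0.9]
        using the phantom seed.
    """

    kind: str
    center: tuple[float, float]
    size: tuple[float, float]
    rotation_deg: float = 0.0
    intensity: float | None = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("ellipse", "rectangle"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if min(self.size) <= 0:
            raise ValueError("shape size components must be positive")


@dataclass
class PhantomSpec:
    """Recipe for a piecewise-constant phantom."""

    size: int
    shapes: list[Shape] = field(default_factory=list)
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("phantom size must be >= 2")
        for sh in self.shapes:
            r, c = sh.center
            if not (0 <= r <= self.size and 0 <= c <= self.size):
                raise ValueError(
                    f"shape centered at {sh.center} lies outside the image support"
                )


# Contrast-modified Shepp-Logan ellipse table: (additive value, semi-axis a,
# semi-axis b, x0, y0, rotation phi in degrees) on the [-1, 1]^2 square.
# The modified intensities keep the summed phantom inside [0, 1].
_SHEPP_LOGAN = [
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
]


def shepp_logan_value(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic (continuous) Shepp-Logan value at points of [-1, 1]^2."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    out = np.zeros(np.broadcast(x, y).shape, dtype=np.float64)
    for val, a, b, x0, y0, phi in _SHEPP_LOGAN:
        th = np.deg2rad(phi)
        ct, st = np.cos(th), np.sin(th)
        dx, dy = x - x0, y - y0
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        out += np.where((u / a) ** 2 + (v / b) ** 2 <= 1.0, val, 0.0)
    return out


def make_shepp_logan(size: int) -> Image2D:
    """Rasterize the standard 10-ellipse Shepp-Logan head phantom.

    Uses the contrast-modified intensity table so pixel values lie in
    [0, 1].  Pixels take the analytic value at their center point.
    """
    if size < 16:
        raise ValueError("Shepp-Logan phantom requires size >= 16")
    # pixel centers mapped onto [-1, 1]^2, y up
    coords = (np.arange(size) + 0.5) * (2.0 / size) - 1.0
    x = coords[None, :]
    y = -coords[:, None]
    vals = shepp_logan_value(x, y)
    # the additive ellipse table sums to 0 or small positives outside
    # features; cancel float round-off so the range is exactly [0, 1]
    vals[np.abs(vals) < 1e-12] = 0.0
    return Image2D(vals)


def _shape_mask(shape: Shape, size: int) -> np.ndarray:
    # pixel centers in (row, col) units measured from the top-left edge
    rc = np.arange(size) + 0.5
    rows = rc[:, None]
    cols = rc[None, :]
    dr = rows - shape.center[0]
    dc = cols - shape.center[1]
    # CCW rotation in (x, y) = (col, -row) coordinates
    th = np.deg2rad(shape.rotation_deg)
    ct, st = np.cos(th), np.sin(th)
    du = dc * ct - dr * st
    dv = dr * ct + dc * st
    if shape.kind == "ellipse":
        return (dv / shape.size[0]) ** 2 + (du / shape.size[1]) ** 2 <= 1.0
    half_h, half_w = shape.size[0] / 2.0, shape.size[1] / 2.0
    return (np.abs(dv) <= half_h) & (np.abs(du) <= half_w)


def make_piecewise_phantom(spec: PhantomSpec, seed: int | None = None) -> Image2D:
    """Render a piecewise-constant phantom from its spec.

    Shapes are additive; overlaps sum.  Values falling outside [0, 1]
    after summation are clipped with a warning.  Deterministic for a
    fixed (spec, seed); the seed only matters when some shape leaves its
    intensity unspecified.
    """
    rng = np.random.default_rng(seed)
    img = np.full((spec.size, spec.size), float(spec.background))
    for sh in spec.shapes:
        inten = sh.intensity
        if inten is None:
            inten = rng.uniform(0.1, 0.9)
        img[_shape_mask(sh, spec.size)] += inten
    if img.min() < 0.0 or img.max() > 1.0:
        warnings.warn(
            "phantom intensities outside [0, 1]; clipping", stacklevel=2
        )
        img = np.clip(img, 0.0, 1.0)
    return Image2D(img)


def default_phantom(size: int = 128) -> Image2D:
    """The packaged piecewise-constant test object.

    An abdomen-like arrangement: a large body ellipse containing two
    organ-like ellipses, a rotated rectangular insert and a small
    low-contrast lesion, on a dark background.  Values lie in [0, 1].
    """
    s = float(size)
    spec = PhantomSpec(
        size=size,
        background=0.0,
        shapes=[
            Shape("ellipse", (s / 2, s / 2), (0.42 * s, 0.36 * s), 0.0, 0.30),
            Shape("ellipse", (0.42 * s, 0.40 * s), (0.16 * s, 0.12 * s), 20.0, 0.25),
            Shape("ellipse", (0.60 * s, 0.62 * s), (0.10 * s, 0.14 * s), -15.0, 0.20),
            Shape("rectangle", (0.66 * s, 0.38 * s), (0.14 * s, 0.10 * s), 30.0, 0.15),
            Shape("ellipse", (0.40 * s, 0.60 * s), (0.05 * s, 0.05 * s), 0.0, 0.12),
        ],
    )
    return make_piecewise_phantom(spec)


def write_image(image: Image2D, path: str | Path) -> None:
    """Write an image as a 32-bit float single-page TIFF."""
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def read_image(path: str | Path) -> Image2D:
    """Read a single-page TIFF back into an :class:`Image2D`."""
    return Image2D(np.asarray(tifffile.imread(str(path)), dtype=np.float64))


def read_phantom_spec(path: str | Path) -> PhantomSpec:
    """Load a PhantomSpec from its JSON document.

    Schema: ``{"size": int, "background": float, "shapes": [{"kind": ...,
    "center": [r, c], "size": [a, b], "rotation_deg": float,
    "intensity": float|null}]}``.
    """
    doc = json.loads(Path(path).read_text())
    shapes = [
        Shape(
            kind=s["kind"],
            center=tuple(s["center"]),
            size=tuple(s["size"]),
            rotation_deg=float(s.get("rotation_deg", 0.0)),
            intensity=s.get("intensity", 0.5),
        )
        for s in doc.get("shapes", [])
    ]
    return PhantomSpec(
        size=int(doc["size"]),
        shapes=shapes,
        background=float(doc.get("background", 0.0)),
    )
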