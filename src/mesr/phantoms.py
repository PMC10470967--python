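"""Parametric phantoms for tomographic simulation.

The classic ten-ellipse Shepp-Logan head phantom (and a modified variant used
as an out-of-training test object) plus a simple numerical breast phantom built
from circular tissue regions with literature attenuation values.

Conventions
-----------
The continuous phantom frame is the square ``[-1, 1]^2`` with ``y`` increasing
upward.  A rasterized phantom of side ``size`` samples the continuous phantom
at pixel centers: column ``j`` has ``x = -1 + (j + 0.5) * h`` and row ``i`` has
``y = 1 - (i + 0.5) * h`` with ``h = 2 / size``.  Pixel values are point
samples (no area-weighted anti-aliasing), so point-in-ellipse membership is
exact and additive densities sum exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EllipseSpec",
    "TissueSpec",
    "PhantomImage",
    "default_shepp_logan",
    "modified_shepp_logan",
    "default_breast_tissues",
    "rasterize_ellipse_phantom",
    "breast_phantom",
    "phantom_grid",
    "to_display_range",
]


@dataclass(frozen=True)
class EllipseSpec:
    """One additive ellipse of an analytic phantom.

    Parameters are in the unit phantom frame: center ``(x0, y0)``, horizontal
    semi-axis ``a``, vertical semi-axis ``b``, counter-clockwise rotation
    ``phi_deg`` in degrees, and additive density ``rho`` (values of overlapping
    ellipses sum).
    """

    x0: float
    y0: float
    a: float
    b: float
    phi_deg: float
    rho: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if not (-1.0 <= self.x0 <= 1.0 and -1.0 <= self.y0 <= 1.0):
            raise ValueError("ellipse center must lie in the [-1, 1]^2 frame")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the (rotated) ellipse."""
        phi = np.deg2rad(self.phi_deg)
        c, s = np.cos(phi), np.sin(phi)
        xr = (x - self.x0) * c + (y - self.y0) * s
        yr = -(x - self.x0) * s + (y - self.y0) * c
        return (xr / self.a) ** 2 + (yr / self.b) ** 2 <= 1.0


@dataclass(frozen=True)
class TissueSpec:
    """A circular tissue region of the numerical breast phantom.

    ``rho`` is mass density (kg/m^3), ``c`` sound speed (m/s) and ``alpha0``
    acoustic attenuation (dB/MHz^y/cm); only ``alpha0`` is imaged here.  The
    region is a circle ``(cx, cy, radius)`` in the phantom frame; later-listed
    tissues overwrite earlier ones.
    """

    name: str
    rho: float
    c: float
    alpha0: float
    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if self.alpha0 < 0:
            raise ValueError("attenuation alpha0 must be non-negative")
        if np.hypot(self.cx, self.cy) + self.radius > 1.0 + 1e-12:
            raise ValueError("tissue region must lie inside the unit disk")


@dataclass
class PhantomImage:
    """A square rasterized phantom on the ``[-1, 1]^2`` frame."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("phantom grid must be square")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def pixel_width(self) -> float:
        return 2.0 / self.size

    def clipped(self) -> "PhantomImage":
        """Copy with negative summed densities clipped to zero (display use)."""
        return PhantomImage(np.clip(self.pixels, 0.0, None))


# Ten-ellipse head phantom: (x0, y0, a, b, phi_deg, rho).
_SHEPP_LOGAN_ROWS = (
    (0.0, 0.0, 0.6900, 0.9200, 0.0, 1.0),
    (0.0, -0.0184, 0.6624, 0.8740, 0.0, -0.8),
    (0.2200, 0.0, 0.1100, 0.3100, -18.0, -0.2),
    (-0.2200, 0.0, 0.1600, 0.4100, 18.0, -0.2),
    (0.0, 0.3500, 0.2100, 0.2500, 0.0, 0.1),
    (0.0, 0.1000, 0.0460, 0.0460, 0.0, 0.1),
    (0.0, -0.1000, 0.0460, 0.0460, 0.0, 0.1),
    (-0.0800, -0.6050, 0.0460, 0.0230, 0.0, 0.1),
    (0.0, -0.6050, 0.0230, 0.0230, 0.0, 0.1),
    (0.0600, -0.6050, 0.0230, 0.0460, 0.0, 0.1),
)

# Variant with altered rotations/axes, used as the unseen test object.
_MODIFIED_ROWS = (
    (0.0, 0.0, 0.6900, 0.9200, 0.0, 1.0),
    (0.0, -0.0184, 0.6624, 0.8740, 0.0, -0.8),
    (0.2200, 0.0, 0.1100, 0.3100, 18.0, -0.2),
    (-0.2200, 0.0, 0.1600, 0.4100, -18.0, -0.2),
    (0.0, 0.3500, 0.2100, 0.4500, 0.0, 0.1),
    (0.0, 0.1000, 0.0460, 0.0460, 20.0, 0.1),
    (0.0, -0.1000, 0.0460, 0.0460, -10.0, 0.1),
    (-0.0800, -0.6050, 0.0460, 0.0230, 90.0, 0.1),
    (0.0, -0.6050, 0.0230, 0.0130, -15.0, 0.1),
    (0.0600, -0.6050, 0.0230, 0.0460, 15.0, 0.1),
)


def default_shepp_logan() -> list[EllipseSpec]:
    """The ten ellipses of the standard Shepp-Logan head phantom."""
    return [EllipseSpec(*row) for row in _SHEPP_LOGAN_ROWS]


def modified_shepp_logan() -> list[EllipseSpec]:
    """The parameter-changed Shepp-Logan variant (test-phase phantom)."""
    return [EllipseSpec(*row) for row in _MODIFIED_ROWS]


def default_breast_tissues() -> list[TissueSpec]:
    """Water bath, fat disk and two inclusions with literature properties.

    Attenuation values follow the standard numerical breast phantom
    (fat 1.2, fibroadenoma 0.7, cancer 1.0, water 1.0 dB/MHz^y/cm).  The
    geometry (disk radii and inclusion positions) is a package default, chosen
    so that both inclusions sit well inside the fat disk and the water bath
    fills most of the transducer ring.
    """
    return [
        TissueSpec("water", 1000.0, 1500.0, 1.0, 0.0, 0.0, 0.95),
        TissueSpec("fat", 950.0, 1470.0, 1.2, 0.0, 0.0, 0.72),
        TissueSpec("fibroadenoma", 1040.0, 1515.0, 0.7, -0.25, 0.15, 0.18),
        TissueSpec("cancer", 1070.0, 1560.0, 1.0, 0.28, -0.22, 0.12),
    ]


def phantom_grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinate arrays ``(X, Y)`` for a ``size x size`` raster."""
    if size < 2:
        raise ValueError("phantom size must be >= 2")
    h = 2.0 / size
    x = -1.0 + (np.arange(size) + 0.5) * h
    y = 1.0 - (np.arange(size) + 0.5) * h
    return np.meshgrid(x, y)


def rasterize_ellipse_phantom(
    specs: Sequence[EllipseSpec], size: int, clip_negative: bool = False
) -> PhantomImage:
    """Rasterize an additive ellipse phantom by pixel-center sampling.

    Each pixel receives the sum of ``rho`` over all ellipses whose interior
    contains its center.  ``clip_negative`` optionally clips the summed image
    at zero; by default the raw additive values are returned (projection and
    reconstruction operate on the unclipped image).
    """
    if not specs:
        raise ValueError("at least one ellipse is required")
    if size < 2:
        raise ValueError("phantom size must be >= 2")
    X, Y = phantom_grid(size)
    img = np.zeros((size, size))
    for spec in specs:
        img[spec.contains(X, Y)] += spec.rho
    if clip_negative:
        img = np.clip(img, 0.0, None)
    return PhantomImage(img)


def breast_phantom(tissues: Sequence[TissueSpec], size: int) -> PhantomImage:
    """Attenuation map of the breast phantom (last-listed tissue wins).

    Pixels outside every region are 0; the first region is conventionally the
    water bath so the background inside the ring carries the water value.
    """
    if not tissues:
        raise ValueError("at least one tissue region is required")
    if size < 2:
        raise ValueError("phantom size must be >= 2")
    X, Y = phantom_grid(size)
    img = np.zeros((size, size))
    for t in tissues:
        mask = (X - t.cx) ** 2 + (Y - t.cy) ** 2 <= t.radius**2
        img[mask] = t.alpha0
    return PhantomImage(img)


def to_display_range(
    image: np.ndarray, lo: float | None = None, hi: float | None = None
) -> np.ndarray:
    """Affine map of a float image to the 8-bit-style [0, 255] scale.

    With ``lo``/``hi`` omitted the image's own min/max are used (min -> 0,
    max -> 255); passing a reference's min/max maps an image pair onto a
    common scale.  A constant image maps to all zeros.
    """
    image = np.asarray(image, dtype=float)
    lo = float(image.min()) if lo is None else float(lo)
    hi = float(image.max()) if hi is None else float(hi)
    if hi <= lo:
        return np.zeros_like(image)
    return (image - lo) * (255.0 / (hi - lo))
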