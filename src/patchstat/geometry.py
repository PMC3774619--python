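"""Planar geometry of quilt patches.

A quilt is modelled as an axis-aligned rectangular observation window
(continuous cm coordinates, origin top-left, y increasing downward, the
image convention) containing simple polygonal patches.  Areas and centroids
are computed analytically from the polygon vertices (shoelace / first
moments via shapely), which equals the pixel-averaging procedure used on
traced raster outlines in the limit of infinite resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "QuiltClass",
    "Patch",
    "Quilt",
    "InvalidGeometryError",
    "polygon_area",
    "polygon_centroid",
    "calibrate_scale",
    "patched_bounding_box",
]

#: tolerance for "vertex inside window" checks, cm
WINDOW_TOL = 1e-9


class InvalidGeometryError(ValueError):
    """Raised for degenerate or self-intersecting patch polygons."""


class QuiltClass(str, Enum):
    REGULAR = "regular"
    CRAZY = "crazy"


def _as_polygon(vertices: Sequence[Sequence[float]]) -> Polygon:
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise InvalidGeometryError(
            f"polygon needs >=3 two-dimensional vertices, got shape {verts.shape}"
        )
    poly = Polygon(verts)
    if not poly.is_valid or not poly.is_simple:
        raise InvalidGeometryError("polygon is self-intersecting or invalid")
    if poly.area <= 0.0:
        raise InvalidGeometryError("polygon has zero area")
    return poly


def polygon_area(vertices: Sequence[Sequence[float]]) -> float:
    """Area of a simple polygon, cm^2 (|shoelace sum| / 2).

    Orientation-independent and strictly positive; raises
    :class:`InvalidGeometryError` for <3 vertices, self-intersection or a
    degenerate (zero-area) polygon.
    """
    return float(_as_polygon(vertices).area)


def polygon_centroid(vertices: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Area centroid (first moments / area) of a simple polygon."""
    c = _as_polygon(vertices).centroid
    return (float(c.x), float(c.y))


def calibrate_scale(
    pixel_height: float, pixel_width: float, cm_height: float, cm_width: float
) -> float:
    """cm-per-pixel scale, estimated from height and width and averaged.

    The two independent estimates ``cm_height/pixel_height`` and
    ``cm_width/pixel_width`` are averaged, mirroring the double estimation
    used when calibrating scanned photographs against published dimensions.
    """
    vals = (pixel_height, pixel_width, cm_height, cm_width)
    if any(v <= 0 for v in vals):
        raise ValueError(f"calibration inputs must be positive, got {vals}")
    return 0.5 * (cm_height / pixel_height + cm_width / pixel_width)


@dataclass(frozen=True)
class Patch:
    """One cloth piece: a simple polygon with derived area and centroid."""

    vertices: tuple[tuple[float, float], ...]
    category: str | None = None
    #: derived, cm^2
    area: float = field(init=False)
    #: derived, cm
    centroid: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        poly = _as_polygon(self.vertices)
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )
        object.__setattr__(self, "area", float(poly.area))
        c = poly.centroid
        object.__setattr__(self, "centroid", (float(c.x), float(c.y)))

    def translated(self, dx: float, dy: float) -> "Patch":
        return Patch(
            vertices=tuple((x + dx, y + dy) for x, y in self.vertices),
            category=self.category,
        )

    def scaled(self, factor: float) -> "Patch":
        """Rescale coordinates by ``factor`` (areas scale by ``factor**2``)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return Patch(
            vertices=tuple((x * factor, y * factor) for x, y in self.vertices),
            category=self.category,
        )


@dataclass(frozen=True)
class Quilt:
    """A rectangular window plus its patches.

    ``window`` is ``(width, height)`` in cm with the origin at (0, 0).
    """

    window: tuple[float, float]
    patches: tuple[Patch, ...]
    quilt_class: QuiltClass = QuiltClass.CRAZY
    name: str = ""
    scale: float = 1.0
    #: allowed relative excess of summed patch area over the window area.
    #: Exact tessellations satisfy the strict default; quilts whose patches
    #: physically overlap (e.g. Gaussian seam jitter) need a looser bound.
    area_tol: float = 1e-6

    def __post_init__(self) -> None:
        w, h = self.window
        if w <= 0 or h <= 0:
            raise ValueError(f"window must have positive dimensions, got {w}x{h}")
        object.__setattr__(self, "patches", tuple(self.patches))
        object.__setattr__(self, "quilt_class", QuiltClass(self.quilt_class))
        for i, p in enumerate(self.patches):
            for x, y in p.vertices:
                if not (
                    -WINDOW_TOL <= x <= w + WINDOW_TOL
                    and -WINDOW_TOL <= y <= h + WINDOW_TOL
                ):
                    raise ValueError(
                        f"patch {i} vertex ({x}, {y}) outside window {w}x{h}"
                    )
        if self.patched_area > self.window_area * (1 + self.area_tol):
            raise ValueError("patched area exceeds window area")

    @property
    def window_area(self) -> float:
        return self.window[0] * self.window[1]

    @property
    def patched_area(self) -> float:
        return float(sum(p.area for p in self.patches))

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.patches], dtype=float)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([p.centroid for p in self.patches], dtype=float)

    @property
    def categories(self) -> list[str | None]:
        return [p.category for p in self.patches]

    def with_name(self, name: str) -> "Quilt":
        return replace(self, name=name)


def patched_bounding_box(quilt: Quilt) -> Quilt:
    """Crop a quilt to the smallest axis-aligned box covering its patches.

    Returns a new quilt translated so the cropped window's origin is (0, 0);
    idempotent. Non-patched borders are thereby excluded from all downstream
    spatial analysis.
    """
    if not quilt.patches:
        raise ValueError("cannot crop a quilt with no patches")
    verts = np.concatenate([np.asarray(p.vertices) for p in quilt.patches])
    x0, y0 = verts.min(axis=0)
    x1, y1 = verts.max(axis=0)
    patches = tuple(p.translated(-x0, -y0) for p in quilt.patches)
    return Quilt(
        window=(float(x1 - x0), float(y1 - y0)),
        patches=patches,
        quilt_class=quilt.quilt_class,
        name=quilt.name,
        scale=quilt.scale,
        area_tol=quilt.area_tol,
    )
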