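"""Planar closed-polygon contours: model, area, rasterization and JSON I/O.

Contours are stored in physical millimeters (not pixel indices) so the same
delineation survives reformatting and resampling.  The on-disk format is a
small versioned JSON schema, ``esovol-contours v1``::

    {"format": "esovol-contours", "version": 1,
     "slices": [{"index": 0, "label": "tumor", "vertices": [[x, y], ...]}, ...]}
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import GeometryError, ValidationError
from .imaging_core import CTVolume

log = logging.getLogger(__name__)

__all__ = ["SliceContour", "KeySliceSet", "polygon_area", "rasterize", "read_contours", "write_contours"]

FORMAT_NAME = "esovol-contours"
FORMAT_VERSION = 1


def _shoelace_signed(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class SliceContour:
    """A simple closed polygon on one axial slice, vertices in mm.

    The polygon is implicitly closed (last vertex connects to the first) and
    validated on construction: at least 3 vertices, simple (no
    self-intersection) and nonzero signed area.
    """

    slice_index: int
    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.slice_index = int(self.slice_index)
        if self.slice_index < 0:
            raise ValidationError(f"slice_index must be >= 0, got {self.slice_index}")
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError(f"need >= 3 (x, y) vertices, got array of shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("contour vertices must be finite")
        self.vertices = v
        if abs(_shoelace_signed(v)) == 0.0:
            raise ValidationError("degenerate contour: zero signed area (collinear vertices?)")
        poly = ShapelyPolygon(v)
        if not poly.is_valid:
            raise ValidationError("contour polygon is not simple (self-intersecting)")


@dataclass
class KeySliceSet:
    """Sparse key-slice delineation: the first and last tumor-bearing slices
    plus any slices where the shape changes appreciably, one contour each,
    strictly increasing slice indices."""

    contours: list[SliceContour]

    def __post_init__(self) -> None:
        if len(self.contours) < 2:
            raise ValidationError(f"a KeySliceSet needs >= 2 contours, got {len(self.contours)}")
        idx = [c.slice_index for c in self.contours]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(f"key slice indices must be strictly increasing, got {idx}")

    @property
    def slice_indices(self) -> list[int]:
        return [c.slice_index for c in self.contours]

    @property
    def first(self) -> int:
        return self.contours[0].slice_index

    @property
    def last(self) -> int:
        return self.contours[-1].slice_index


def polygon_area(c: SliceContour) -> float:
    """Cross-sectional area of the contour in mm² (shoelace absolute value):
    ``|Σ_i x_i·y_{i+1} − x_{i+1}·y_i| / 2`` — orientation-invariant."""
    return abs(_shoelace_signed(c.vertices))


def rasterize(c: SliceContour, grid: CTVolume) -> np.ndarray:
    """Rasterize a contour onto the in-plane grid of ``grid``.

    A pixel is included iff its *center* lies inside the polygon — an
    unbiased area estimator.  Returns a 2-D boolean mask of shape
    ``(ny, nx)`` for slice ``c.slice_index``.

    Raises
    ------
    GeometryError
        If the polygon extends beyond the grid's in-plane physical extent.
    """
    nz, ny, nx = grid.voxels.shape
    xs, ys = grid.pixel_centers()
    # physical extent spanned by the pixel grid (outer pixel edges)
    x_lo, x_hi = xs[0] - grid.dx / 2, xs[-1] + grid.dx / 2
    y_lo, y_hi = ys[0] - grid.dy / 2, ys[-1] + grid.dy / 2
    vx, vy = c.vertices[:, 0], c.vertices[:, 1]
    if vx.min() < x_lo or vx.max() > x_hi or vy.min() < y_lo or vy.max() > y_hi:
        raise GeometryError(
            f"contour bbox x[{vx.min():.2f},{vx.max():.2f}] y[{vy.min():.2f},{vy.max():.2f}] mm "
            f"exceeds grid extent x[{x_lo:.2f},{x_hi:.2f}] y[{y_lo:.2f},{y_hi:.2f}] mm"
        )
    # restrict the point-in-polygon test to the bounding box for speed
    i0 = max(0, int(np.searchsorted(xs, vx.min())) - 1)
    i1 = min(nx, int(np.searchsorted(xs, vx.max())) + 1)
    j0 = max(0, int(np.searchsorted(ys, vy.min())) - 1)
    j1 = min(ny, int(np.searchsorted(ys, vy.max())) + 1)
    mask = np.zeros((ny, nx), dtype=bool)
    if i1 > i0 and j1 > j0:
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1])
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        # with closed=True matplotlib uses the last vertex as the CLOSEPOLY
        # placeholder, so the closing vertex must be appended explicitly
        ring = np.vstack([c.vertices, c.vertices[:1]])
        inside = MplPath(ring, closed=True).contains_points(pts)
        mask[j0:j1, i0:i1] = inside.reshape(j1 - j0, i1 - i0)
    if not mask.any():
        log.warning(
            "contour on slice %d rasterized to zero pixels (area %.3f mm², pixel %.3f mm²)",
            c.slice_index, polygon_area(c), grid.pixel_area_mm2,
        )
    return mask


# -- JSON I/O ---------------------------------------------------------------

def write_contours(keys: KeySliceSet, path: str | os.PathLike) -> None:
    """Write a key-slice set as ``esovol-contours v1`` JSON, full float precision."""
    doc = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "slices": [
            {"index": c.slice_index, "label": c.label, "vertices": c.vertices.tolist()}
            for c in keys.contours
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_contours(path: str | os.PathLike) -> KeySliceSet:
    """Read an ``esovol-contours v1`` JSON document.

    Raises
    ------
    ValidationError
        Malformed document (with line context) or invariant violations
        (unordered slices, fewer than two contours).
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"malformed contour JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_NAME:
        raise ValidationError(f"not an {FORMAT_NAME} document: {path}")
    if doc.get("version") != FORMAT_VERSION:
        raise ValidationError(f"unsupported contour format version {doc.get('version')!r}")
    slices = doc.get("slices")
    if not isinstance(slices, list):
        raise ValidationError("contour document lacks a 'slices' list")
    contours = [
        SliceContour(slice_index=s["index"], vertices=np.asarray(s["vertices"], dtype=float), label=s.get("label", ""))
        for s in slices
    ]
    return KeySliceSet(contours)
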