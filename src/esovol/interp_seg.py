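"""Semiautomatic segmentation core.

The workflow mirrors how a radiologist works at a volumetry workstation:
draw the tumor outline on a sparse set of key slices, let the software fill
in every intermediate slice, constrain the result to a Hounsfield window
(default [0, 1000] HU — excludes intraluminal air, keeps all soft tissue),
then review and touch up individual slices.

Inter-slice interpolation is shape-based: each key contour is rasterized and
converted to a signed Euclidean distance map (negative inside, positive
outside, in mm); for a slice a fraction ``t`` of the way between two keys the
mask is the negative region of the linearly blended map
``(1−t)·D_a + t·D_b``.  This is deterministic and exact on the key slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .contours import KeySliceSet, SliceContour, rasterize
from .errors import DegenerateInputError, GeometryError, ValidationError
from .imaging_core import CTVolume

__all__ = [
    "SegmentationMask",
    "HUWindow",
    "interpolate_contours",
    "apply_hu_window",
    "edit_mask",
    "segment_manual",
]


@dataclass
class HUWindow:
    """Inclusive Hounsfield inclusion window; defaults exclude air (< 0 HU)
    and retain all soft tissue up to 1000 HU."""

    low: float = 0.0
    high: float = 1000.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(f"HU window requires low < high, got [{self.low}, {self.high}]")


@dataclass
class SegmentationMask:
    """A boolean volume-of-interest congruent with a :class:`CTVolume`.

    ``provenance`` records whether the mask came from the manual or the
    semiautomatic path; ``edits`` is the replayable list of manual
    adjustments applied after the fact.
    """

    mask: np.ndarray
    provenance: Literal["manual", "semiauto"]
    edits: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got ndim={self.mask.ndim}")
        if self.provenance not in ("manual", "semiauto"):
            raise ValidationError(f"provenance must be 'manual' or 'semiauto', got {self.provenance!r}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _signed_distance(mask2d: np.ndarray, spacing_yx: tuple[float, float]) -> np.ndarray:
    """Signed Euclidean distance map in mm: negative inside, positive outside."""
    outside = ndimage.distance_transform_edt(~mask2d, sampling=spacing_yx)
    inside = ndimage.distance_transform_edt(mask2d, sampling=spacing_yx)
    return outside - inside


def interpolate_contours(keys: KeySliceSet, grid: CTVolume) -> SegmentationMask:
    """Fill every slice between consecutive key contours by linear
    interpolation of their signed distance maps.

    Key slices reproduce their rasterized contours exactly; slices outside
    ``[first, last]`` stay empty.

    Raises
    ------
    GeometryError
        A key slice index falls outside the grid.
    DegenerateInputError
        A key contour rasterizes to zero pixels, leaving no shape to
        interpolate from.
    """
    nz = grid.n_slices
    if keys.last >= nz:
        raise GeometryError(f"key slice {keys.last} outside grid with {nz} slices")
    out = np.zeros(grid.voxels.shape, dtype=bool)
    rasters: dict[int, np.ndarray] = {}
    for c in keys.contours:
        r = rasterize(c, grid)
        if not r.any():
            raise DegenerateInputError(
                f"key contour on slice {c.slice_index} rasterized to zero pixels; "
                "cannot interpolate from an empty shape"
            )
        rasters[c.slice_index] = r
        out[c.slice_index] = r
    spacing_yx = (grid.dy, grid.dx)
    idx = keys.slice_indices
    for a, b in zip(idx, idx[1:]):
        if b - a < 2:
            continue  # adjacent keys: nothing to interpolate
        da = _signed_distance(rasters[a], spacing_yx)
        db = _signed_distance(rasters[b], spacing_yx)
        for k in range(a + 1, b):
            t = (k - a) / (b - a)
            out[k] = (1.0 - t) * da + t * db < 0.0
    return SegmentationMask(out, provenance="semiauto")


def apply_hu_window(m: SegmentationMask, vol: CTVolume, w: HUWindow | None = None) -> SegmentationMask:
    """Intersect the mask with the HU inclusion window (inclusive bounds).

    Idempotent and monotone: voxels are only ever removed.
    """
    if w is None:
        w = HUWindow()
    if m.mask.shape != vol.voxels.shape:
        raise GeometryError(f"mask shape {m.mask.shape} != volume shape {vol.voxels.shape}")
    keep = (vol.voxels >= w.low) & (vol.voxels <= w.high)
    return SegmentationMask(m.mask & keep, provenance=m.provenance, edits=list(m.edits))


def edit_mask(
    m: SegmentationMask,
    slice_index: int,
    region: SliceContour,
    mode: Literal["add", "remove"],
    grid: CTVolume,
) -> SegmentationMask:
    """Apply one manual touch-up on a single slice.

    ``mode='add'`` unions the rasterized region with the slice mask,
    ``mode='remove'`` subtracts it.  The edit is appended to the mask's
    provenance so the sequence can be replayed.
    """
    if mode not in ("add", "remove"):
        raise ValidationError(f"mode must be 'add' or 'remove', got {mode!r}")
    if not 0 <= slice_index < m.mask.shape[0]:
        raise GeometryError(f"slice {slice_index} out of range for mask with {m.mask.shape[0]} slices")
    region_mask = rasterize(region, grid)
    new = m.mask.copy()
    if mode == "add":
        new[slice_index] |= region_mask
    else:
        new[slice_index] &= ~region_mask
    record = {"slice_index": int(slice_index), "mode": mode, "vertices": region.vertices.tolist()}
    return SegmentationMask(new, provenance=m.provenance, edits=list(m.edits) + [record])


def segment_manual(contours: list[SliceContour], grid: CTVolume) -> SegmentationMask:
    """Manual segmentation: one contour per tumor-bearing slice over a
    contiguous slice range, rasterized and unioned.  No HU window is applied
    in this path — thresholding belongs to the semiautomatic workflow only.
    """
    if not contours:
        raise ValidationError("segment_manual needs at least one contour")
    idx = [c.slice_index for c in contours]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValidationError(f"contour slice indices must be strictly increasing, got {idx}")
    missing = sorted(set(range(idx[0], idx[-1] + 1)) - set(idx))
    if missing:
        raise ValidationError(f"manual delineation must cover every slice in [{idx[0]}, {idx[-1]}]; missing {missing}")
    if idx[-1] >= grid.n_slices:
        raise GeometryError(f"contour slice {idx[-1]} outside grid with {grid.n_slices} slices")
    out = np.zeros(grid.voxels.shape, dtype=bool)
    for c in contours:
        out[c.slice_index] |= rasterize(c, grid)
    return SegmentationMask(out, provenance="manual")
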