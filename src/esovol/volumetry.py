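"""Summation-of-area tumor volume (Breiman method).

Volume is the sum over slices of cross-sectional area times slice
thickness, reported in milliliters (1 ml = 1000 mm³).  For a voxel mask this
is algebraically identical to voxel count × voxel volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import GeometryError, ValidationError
from .imaging_core import CTVolume
from .interp_seg import SegmentationMask

__all__ = ["VolumeMeasurement", "volume_from_mask", "volume_from_areas", "round_ml"]

METHODS = ("manual", "semiauto")
PHASES = ("arterial", "venous")


@dataclass
class VolumeMeasurement:
    """One tumor-volume measurement in the study design: patient × method ×
    observer × contrast phase, value in ml."""

    value: float
    method: Literal["manual", "semiauto"]
    phase: Literal["arterial", "venous"]
    observer: str
    patient: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError(f"volume must be >= 0 ml, got {self.value}")
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"phase must be one of {PHASES}, got {self.phase!r}")


def volume_from_mask(m: SegmentationMask, vol: CTVolume) -> float:
    """Summation-of-area volume of a mask in ml.

    Per slice: (set-pixel count × dx × dy) × dz, summed over slices and
    divided by 1000.
    """
    if m.mask.shape != vol.voxels.shape:
        raise GeometryError(f"mask shape {m.mask.shape} != volume shape {vol.voxels.shape}")
    counts = m.mask.sum(axis=(1, 2))
    return float(counts.sum()) * vol.voxel_volume_mm3 / 1000.0


def volume_from_areas(areas, thickness: float) -> float:
    """Volume in ml from per-slice cross-sectional areas (mm²) and a common
    slice thickness (mm): ``Σ areas · thickness / 1000``."""
    if thickness <= 0:
        raise ValidationError(f"thickness must be > 0 mm, got {thickness}")
    a = np.asarray(list(areas), dtype=float)
    if a.size and a.min() < 0:
        raise ValidationError(f"negative slice area: {a.min()}")
    return float(a.sum()) * thickness / 1000.0


def round_ml(value: float) -> int:
    """Round to integer ml, half away from zero — the convention used when
    comparing against published integer-ml tables."""
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)
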