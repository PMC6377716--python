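"""CT volume data model, NIfTI/NRRD I/O and axial average-intensity reformatting.

The in-memory convention is fixed: voxel arrays are indexed ``(z, y, x)``
with ``z`` the slice index, spacing is ``(dx, dy, dz)`` in mm and the origin
is the physical position (mm) of the *center* of voxel ``(0, 0, 0)``.  Slice
``k`` occupies the half-open physical slab ``[z0 + k*dz, z0 + (k+1)*dz)``.

Hounsfield units are clamped to the 12-bit CT range ``[-1024, 3071]`` when a
volume is loaded from disk, which protects downstream threshold logic from
padding/sentinel values some scanners write outside the reconstruction circle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import MetadataError, ParameterError

HU_MIN = -1024
HU_MAX = 3071

__all__ = ["CTVolume", "load_volume", "save_volume", "reformat_axial", "HU_MIN", "HU_MAX"]


@dataclass
class CTVolume:
    """A 3-D grid of Hounsfield values with anisotropic spacing.

    Parameters
    ----------
    voxels
        Array of shape ``(nz, ny, nx)`` holding HU values.
    spacing
        ``(dx, dy, dz)`` voxel spacing in mm, all strictly positive.
    origin
        ``(x0, y0, z0)`` physical position in mm of the center of voxel
        ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise MetadataError(f"expected a 3-D voxel array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be three strictly positive values, got {self.spacing}")

    # -- convenience geometry ------------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def dx(self) -> float:
        return self.spacing[0]

    @property
    def dy(self) -> float:
        return self.spacing[1]

    @property
    def dz(self) -> float:
        return self.spacing[2]

    @property
    def pixel_area_mm2(self) -> float:
        return self.dx * self.dy

    @property
    def voxel_volume_mm3(self) -> float:
        return self.dx * self.dy * self.dz

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of in-plane pixel centers.

        Returns 1-D arrays ``xs`` (length nx) and ``ys`` (length ny).
        """
        nz, ny, nx = self.voxels.shape
        xs = self.origin[0] + np.arange(nx) * self.dx
        ys = self.origin[1] + np.arange(ny) * self.dy
        return xs, ys

    def slice_center_z(self, k: int) -> float:
        """Physical z coordinate (mm) of the center of slice ``k``.

        ``origin[2]`` marks the start of the first slab, so the center sits
        half a slice thickness in; this keeps slab membership stable under
        :func:`reformat_axial`, which merges whole slabs.
        """
        return self.origin[2] + (k + 0.5) * self.dz


def _clamp_hu(a: np.ndarray) -> np.ndarray:
    return np.clip(a, HU_MIN, HU_MAX)


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("nifti", "nrrd"):
            raise ParameterError(f"unknown format {fmt!r}; expected 'nifti' or 'nrrd'")
        return fmt
    name = str(path)
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    raise ParameterError(f"cannot infer format from {name!r}; pass format='nifti' or 'nrrd'")


def load_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Read a NIfTI-1 or NRRD volume, normalizing axes to ``(z, y, x)``.

    Spacing is taken from the file header (NIfTI ``pixdim`` / NRRD space
    directions); HU values are clamped to ``[-1024, 3071]``.

    Raises
    ------
    MetadataError
        If the header carries a non-positive spacing component.
    OSError
        If the file does not exist or cannot be parsed.
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if any(not np.isfinite(z) or z <= 0 for z in zooms):
            raise MetadataError(f"non-positive pixdim spacing in {path}: {zooms}")
        data = np.asanyarray(img.dataobj)  # (x, y, z)
        voxels = _clamp_hu(np.transpose(data, (2, 1, 0)))
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return CTVolume(voxels, spacing=tuple(float(z) for z in zooms), origin=origin)
    else:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()  # (dx, dy, dz)
        if any(s <= 0 for s in spacing):
            raise MetadataError(f"non-positive spacing in NRRD header of {path}: {spacing}")
        voxels = _clamp_hu(sitk.GetArrayFromImage(img))  # already (z, y, x)
        return CTVolume(voxels, spacing=tuple(spacing), origin=tuple(img.GetOrigin()))


def save_volume(vol: CTVolume, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a :class:`CTVolume` so that :func:`load_volume` round-trips it
    (voxels bit-exact for in-range HU, spacing within 1e-6 mm)."""
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag([vol.dx, vol.dy, vol.dz, 1.0])
        affine[:3, 3] = vol.origin
        data = np.transpose(vol.voxels, (2, 1, 0))
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
    else:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.voxels)
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        sitk.WriteImage(img, str(path))


def reformat_axial(vol: CTVolume, target_thickness: float) -> CTVolume:
    """Average-intensity axial reformat to a thicker slice.

    Groups of ``m = round(target_thickness / dz)`` consecutive thin slices are
    replaced by their voxelwise arithmetic mean (an average intensity
    projection); trailing slices that do not fill a complete group are
    dropped.  ``target_thickness`` must be an integer multiple of the input
    slice thickness to within 1e-6 mm.
    """
    dz = vol.dz
    m = int(round(target_thickness / dz))
    residual = abs(m * dz - target_thickness)
    if m < 1 or residual > 1e-6:
        raise ParameterError(
            f"target thickness {target_thickness} mm is not an integer multiple of "
            f"dz={dz} mm (nearest multiple m={m}, residual {residual:.3g} mm)"
        )
    if m == 1:
        return CTVolume(vol.voxels.copy(), vol.spacing, vol.origin)
    nz = vol.n_slices // m
    if nz == 0:
        raise ParameterError(f"volume has {vol.n_slices} slices, fewer than the group size {m}")
    blocks = vol.voxels[: nz * m].reshape(nz, m, *vol.voxels.shape[1:])
    out = blocks.mean(axis=1)
    return CTVolume(out, spacing=(vol.dx, vol.dy, m * dz), origin=vol.origin)
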