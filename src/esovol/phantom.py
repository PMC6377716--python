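"""Synthetic CT phantoms and observer simulation.

The phantom is a tapered soft-tissue tube — an idealized esophageal tumor —
embedded in a homogeneous mediastinal background, optionally with an air
lumen, on an anisotropic grid (0.625 mm native slices by default, matching
thin-slice staging CT).  Ground truth is known analytically, so the entire
manual-vs-semiautomatic measurement experiment can run end to end with no
patient data.

Observer behaviour is modeled as (a) a smooth radial perturbation of each
drawn contour — a periodic Gaussian field over vertex angle, built from a
few Fourier harmonics so contours stay simple, mimicking human tracing —
and (b) Gaussian error in locating the cranial and caudal tumor borders.
The manual protocol draws every slice independently; the semiautomatic
protocol draws only sparse key slices and lets interpolation fill the rest,
so fewer independent noisy decisions enter the measured volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contours import KeySliceSet, SliceContour
from .errors import DegenerateInputError, GeometryError, ValidationError
from .imaging_core import CTVolume, HU_MAX, HU_MIN, reformat_axial
from .interp_seg import HUWindow, SegmentationMask, apply_hu_window, interpolate_contours, segment_manual
from .measurements import MeasurementTable
from .volumetry import volume_from_mask

__all__ = [
    "PhantomSpec",
    "ObserverModel",
    "generate_phantom",
    "truth_contours",
    "simulate_observer_manual",
    "simulate_observer_semiauto",
    "simulate_study",
    "default_observer_models",
    "default_spec_sampler",
]


@dataclass
class PhantomSpec:
    """Geometry and intensity model of a tubular tumor phantom.

    ``r_outer``/``r_lumen`` give per-slice radii (mm) for the native tumor
    slices ``z_first .. z_last``; ``center`` is the in-plane tube center in
    mm (the in-plane origin sits at the grid center).  HU levels default to
    soft-tissue tumor (60 ± 15) against mediastinum (20) with air lumen
    (−1000); ``noise_sd`` is additive acquisition noise.
    """

    shape: tuple[int, int, int] = (144, 48, 48)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (1.25, 1.25, 0.625)  # (dx, dy, dz)
    z_first: int = 16
    z_last: int = 127
    r_outer: np.ndarray | float = 15.0
    r_lumen: np.ndarray | float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    background_hu: float = 20.0
    tumor_hu: float = 60.0
    tumor_sd: float = 15.0
    lumen_hu: float = -1000.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        nz, ny, nx = self.shape
        if not 0 <= self.z_first < self.z_last <= nz - 1:
            raise ValidationError(f"need 0 <= z_first < z_last < nz, got {self.z_first}, {self.z_last}, nz={nz}")
        n = self.n_tumor_slices
        self.r_outer = np.broadcast_to(np.asarray(self.r_outer, dtype=float), (n,)).copy()
        self.r_lumen = np.broadcast_to(np.asarray(self.r_lumen, dtype=float), (n,)).copy()
        if np.any(self.r_lumen < 0) or np.any(self.r_outer <= self.r_lumen):
            raise ValidationError("radii must satisfy r_outer > r_lumen >= 0 on every tumor slice")
        if not 0 <= self.tumor_hu <= 1000:
            raise ValidationError(f"tumor HU mean must lie in [0, 1000], got {self.tumor_hu}")
        dx, dy, _ = self.spacing
        half_x, half_y = (nx - 1) / 2 * dx, (ny - 1) / 2 * dy
        cx, cy = self.center
        rmax = float(self.r_outer.max())
        if abs(cx) + rmax > half_x + dx / 2 or abs(cy) + rmax > half_y + dy / 2:
            raise GeometryError(
                f"tumor (center {self.center}, max radius {rmax:.1f} mm) exceeds the "
                f"in-plane grid extent ±({half_x + dx / 2:.1f}, {half_y + dy / 2:.1f}) mm"
            )

    @property
    def n_tumor_slices(self) -> int:
        return self.z_last - self.z_first + 1

    def grid(self) -> CTVolume:
        """Empty CTVolume with this spec's geometry (in-plane origin centered)."""
        nz, ny, nx = self.shape
        dx, dy, dz = self.spacing
        origin = (-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, 0.0)
        return CTVolume(np.zeros(self.shape, dtype=np.float32), self.spacing, origin)

    def radius_at_z(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Outer and lumen radii at physical z (mm), linearly interpolated
        between native tumor slice centers; NaN outside the tumor slab."""
        dz = self.spacing[2]
        z = np.asarray(z, dtype=float)
        z_lo, z_hi = self.z_first * dz, (self.z_last + 1) * dz
        centers = (np.arange(self.z_first, self.z_last + 1) + 0.5) * dz
        ro = np.interp(z, centers, self.r_outer)
        rl = np.interp(z, centers, self.r_lumen)
        outside = (z < z_lo) | (z >= z_hi)
        ro = np.where(outside, np.nan, ro)
        rl = np.where(outside, np.nan, rl)
        return ro, rl

    @property
    def true_volume_ml(self) -> float:
        """Analytic volume: per-slice annulus area × dz, summed, in ml."""
        dz = self.spacing[2]
        areas = np.pi * (self.r_outer**2 - self.r_lumen**2)
        return float(areas.sum() * dz / 1000.0)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, SegmentationMask, float]:
    """Render the phantom: returns the HU volume, the analytic ground-truth
    mask (pixel centers inside the outer radius, outside the lumen) and the
    exact tumor volume in ml.  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    nz, ny, nx = spec.shape
    vox = spec.background_hu + spec.noise_sd * rng.standard_normal(spec.shape).astype(np.float32)
    truth = np.zeros(spec.shape, dtype=bool)
    xs, ys = grid.pixel_centers()
    gx, gy = np.meshgrid(xs - spec.center[0], ys - spec.center[1])
    d = np.hypot(gx, gy)
    for i, k in enumerate(range(spec.z_first, spec.z_last + 1)):
        ro, rl = spec.r_outer[i], spec.r_lumen[i]
        tumor = (d < ro) & (d >= rl)
        truth[k] = tumor
        if tumor.any():
            vox[k][tumor] = spec.tumor_hu + spec.tumor_sd * rng.standard_normal(int(tumor.sum()))
        if rl > 0:
            vox[k][d < rl] = spec.lumen_hu
    np.clip(vox, HU_MIN, HU_MAX, out=vox)
    vol = CTVolume(vox, spec.spacing, grid.origin)
    return vol, SegmentationMask(truth, provenance="manual"), spec.true_volume_ml


def _circle(cx: float, cy: float, r: float, n_vertices: int = 64) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def truth_contours(spec: PhantomSpec, grid: CTVolume | None = None, n_vertices: int = 64) -> list[SliceContour]:
    """Outer-boundary contours of the phantom on a target grid (defaults to
    the native grid).  The lumen is not delineated — as at the workstation,
    the observer outlines the outer tumor margin and the HU window is what
    removes intraluminal air in the semiautomatic path."""
    if grid is None:
        grid = spec.grid()
    out = []
    for k in range(grid.n_slices):
        ro, _ = spec.radius_at_z(np.array([grid.slice_center_z(k)]))
        if np.isnan(ro[0]):
            continue
        out.append(SliceContour(k, _circle(spec.center[0], spec.center[1], float(ro[0]), n_vertices), label="tumor"))
    return out


# -- observer simulation ----------------------------------------------------

@dataclass
class ObserverModel:
    """Stochastic model of one reader under one protocol.

    ``boundary_sd`` is the pointwise SD (mm) of the smooth radial tracing
    error; ``smoothness`` its angular scale in radians (larger = smoother);
    ``extent_sd`` the SD (slices) of the error in locating the first/last
    tumor slice; ``key_slice_step`` the key-slice density of the
    semiautomatic protocol (1 = every slice).
    """

    boundary_sd: float = 1.0
    extent_sd: float = 1.0
    key_slice_step: int = 4
    smoothness: float = 0.8
    seed: int = 0
    n_harmonics: int = 8

    def __post_init__(self) -> None:
        if self.boundary_sd < 0 or self.extent_sd < 0:
            raise ValidationError("boundary_sd and extent_sd must be >= 0")
        if self.key_slice_step < 1:
            raise ValidationError(f"key_slice_step must be >= 1, got {self.key_slice_step}")

    def _radial_field(self, rng: np.random.Generator):
        """Sample a smooth periodic radial-error function f(theta) with
        pointwise SD ``boundary_sd``: a truncated Fourier series with
        Gaussian coefficients whose spectrum decays on the angular scale
        ``smoothness`` (squared-exponential-like)."""
        h = np.arange(self.n_harmonics + 1)
        w = np.exp(-0.5 * (h * self.smoothness) ** 2)
        s = self.boundary_sd * w / np.sqrt((w**2).sum())
        a = s * rng.standard_normal(self.n_harmonics + 1)
        b = s * rng.standard_normal(self.n_harmonics + 1)

        def f(theta: np.ndarray) -> np.ndarray:
            ht = np.outer(h, theta)
            return a @ np.cos(ht) + b @ np.sin(ht)

        return f


def _perturb_contour(c: SliceContour, om: ObserverModel, rng: np.random.Generator, new_index: int | None = None) -> SliceContour:
    if om.boundary_sd == 0:
        return SliceContour(c.slice_index if new_index is None else new_index, c.vertices.copy(), c.label)
    ctr = c.vertices.mean(axis=0)
    rel = c.vertices - ctr
    r = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    # tracing error is bounded in practice: truncate the field at 3.5 sigma,
    # and at half the local radius — small structures are traced with
    # proportionally small error, and a drawn region cannot invert
    cap = np.minimum(3.5 * om.boundary_sd, 0.5 * r)
    r_new = r + np.clip(om._radial_field(rng)(theta), -cap, cap)
    keep = r_new > 0
    if keep.sum() < 3:
        raise DegenerateInputError(
            f"radial perturbation collapsed the contour on slice {c.slice_index} "
            f"below 3 effective vertices ({int(keep.sum())} left)"
        )
    r_new = r_new[keep]
    theta = theta[keep]
    verts = ctr + np.column_stack([r_new * np.cos(theta), r_new * np.sin(theta)])
    return SliceContour(c.slice_index if new_index is None else new_index, verts, c.label)


def _shifted_range(truth: list[SliceContour], om: ObserverModel, rng: np.random.Generator, max_slice: int | None):
    first, last = truth[0].slice_index, truth[-1].slice_index
    d_first = int(np.rint(rng.normal(0.0, om.extent_sd))) if om.extent_sd > 0 else 0
    d_last = int(np.rint(rng.normal(0.0, om.extent_sd))) if om.extent_sd > 0 else 0
    new_first = max(0, first + d_first)
    new_last = last + d_last
    if max_slice is not None:
        new_last = min(new_last, max_slice)
        new_first = min(new_first, max_slice - 1)
    if new_last <= new_first:  # keep at least a two-slice tumor
        new_last = new_first + 1
    by_index = {c.slice_index: c for c in truth}

    def base(k: int) -> SliceContour:
        kk = min(max(k, first), last)  # beyond the true extent, reuse the end shape
        return by_index[kk]

    return new_first, new_last, base


def simulate_observer_manual(
    truth: list[SliceContour],
    om: ObserverModel,
    rng: np.random.Generator | None = None,
    max_slice: int | None = None,
) -> list[SliceContour]:
    """Simulate a manual delineation: every slice of the (extent-perturbed)
    tumor range receives an independently noisy contour."""
    if not truth:
        raise ValidationError("need at least one truth contour")
    if rng is None:
        rng = np.random.default_rng(om.seed)
    new_first, new_last, base = _shifted_range(truth, om, rng, max_slice)
    return [_perturb_contour(base(k), om, rng, new_index=k) for k in range(new_first, new_last + 1)]


def simulate_observer_semiauto(
    truth: list[SliceContour],
    om: ObserverModel,
    rng: np.random.Generator | None = None,
    max_slice: int | None = None,
) -> KeySliceSet:
    """Simulate the key-slice protocol: the (extent-perturbed) first and
    last tumor slices plus every ``key_slice_step``-th slice between, each
    with its own radial tracing noise."""
    if not truth:
        raise ValidationError("need at least one truth contour")
    if rng is None:
        rng = np.random.default_rng(om.seed)
    new_first, new_last, base = _shifted_range(truth, om, rng, max_slice)
    keys = list(range(new_first, new_last, om.key_slice_step))
    if keys[-1] != new_last:
        keys.append(new_last)
    return KeySliceSet([_perturb_contour(base(k), om, rng, new_index=k) for k in keys])


# -- full study simulation ---------------------------------------------------

def default_observer_models() -> dict[str, tuple[ObserverModel, ObserverModel]]:
    """Default observer pairs per method.

    Key-slice contours are drawn deliberately on morphologically clear
    slices, so their tracing noise is small; tracing every one of ~25 thin
    slices is faster and noisier.  Extent uncertainty (the cranial/caudal
    border) is protocol-independent.
    """
    manual = ObserverModel(boundary_sd=2.5, extent_sd=1.0, key_slice_step=1)
    semi = ObserverModel(boundary_sd=0.6, extent_sd=1.0, key_slice_step=4)
    return {
        "manual": (dataclasses.replace(manual), dataclasses.replace(manual)),
        "semiauto": (dataclasses.replace(semi), dataclasses.replace(semi)),
    }


def default_spec_sampler(rng: np.random.Generator) -> PhantomSpec:
    """Sample a patient: a spindle-shaped tumor, length 30–80 mm, peak
    radius 8–24 mm tapering to 2.5 mm at the ends, on a 0.625 mm grid."""
    dz = 0.625
    length = rng.uniform(30.0, 80.0)
    r_max = rng.uniform(8.0, 20.0)
    n = int(round(length / dz))
    nz = 160
    z_first = (nz - n) // 2
    u = (np.arange(n) + 0.5) / n
    r = 2.5 + (r_max - 2.5) * np.sin(np.pi * u) ** 0.7
    return PhantomSpec(
        shape=(nz, 52, 52),
        spacing=(1.25, 1.25, dz),
        z_first=z_first,
        z_last=z_first + n - 1,
        r_outer=r,
        seed=int(rng.integers(2**31)),
    )


def simulate_study(
    n_patients: int,
    spec_sampler=None,
    observers: dict[str, tuple[ObserverModel, ObserverModel]] | None = None,
    seed: int = 0,
    reading_thickness: float = 2.5,
    hu_window: HUWindow | None = None,
) -> MeasurementTable:
    """Run the full two-observer, two-method, two-phase experiment on
    ``n_patients`` sampled phantoms.

    Per patient the two contrast phases are independent noise realizations
    (CT noise and observer noise) of the same anatomy.  Volumes are read on
    the ``reading_thickness`` average-intensity reformat, as at the
    workstation.  Returns a :class:`MeasurementTable` with an extra
    ``true_volume_ml`` column.
    """
    if n_patients < 2:
        raise ValidationError(f"a study needs >= 2 patients, got {n_patients}")
    if spec_sampler is None:
        spec_sampler = default_spec_sampler
    if observers is None:
        observers = default_observer_models()
    if hu_window is None:
        hu_window = HUWindow()
    rng = np.random.default_rng(seed)
    observer_names = ("resident", "consultant")
    rows = []
    for p in range(1, n_patients + 1):
        spec = spec_sampler(rng)
        for phase in ("arterial", "venous"):
            phase_spec = dataclasses.replace(spec, seed=int(rng.integers(2**31)))
            vol, _, true_ml = generate_phantom(phase_spec)
            grid = reformat_axial(vol, reading_thickness) if reading_thickness > spec.spacing[2] else vol
            truth = truth_contours(spec, grid)
            for method, oms in observers.items():
                for obs_name, om in zip(observer_names, oms):
                    child = np.random.default_rng(rng.integers(2**31))
                    if method == "manual":
                        contours = simulate_observer_manual(truth, om, child, max_slice=grid.n_slices - 1)
                        mask = segment_manual(contours, grid)
                    else:
                        keys = simulate_observer_semiauto(truth, om, child, max_slice=grid.n_slices - 1)
                        mask = apply_hu_window(interpolate_contours(keys, grid), grid, hu_window)
                    rows.append(
                        {
                            "patient": p,
                            "method": method,
                            "observer": obs_name,
                            "phase": phase,
                            "volume_ml": volume_from_mask(mask, grid),
                            "true_volume_ml": true_ml,
                        }
                    )
    return MeasurementTable(pd.DataFrame(rows))
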