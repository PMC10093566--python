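"""VOI-based SUV quantification of 3-D uptake volumes.

Conventions
-----------
* A volume is a 3-D grid of nonnegative values with anisotropic spacing;
  array axes 0, 1, 2 correspond to physical axes x, y, z.
* Physical coordinates place the origin at the *center* of voxel (0, 0, 0),
  so voxel (i, j, k) is centered at (i*sx, j*sy, k*sz) mm.  NIfTI affines
  vary; volumes loaded from file use the header zooms with this convention.
* A voxel belongs to a spherical VOI iff its geometric center lies within
  the sphere (no partial-volume weighting).
* SUV normalization divides the tissue concentration by decay-corrected
  injected activity per gram, assuming tissue density 1 g/mL, so a uniform
  distribution of the tracer over the body gives SUV 1 everywhere.
* SUVpeak follows the EANM-style convention: the best average over a 1.0 mL
  sphere (diameter ~12.4 mm) centered on any voxel center inside the VOI;
  the averaging sphere may extend beyond the VOI but is clipped at the
  volume boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "F18_HALF_LIFE_MIN",
    "PEAK_SPHERE_VOLUME_ML",
    "UptakeVolume",
    "SphereVOI",
    "ScanContext",
    "suv_normalize",
    "voi_voxels",
    "suv_max",
    "suv_mean",
    "suv_peak",
    "make_phantom",
    "load_nifti",
    "save_nifti",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

#: Averaging-sphere volume defining SUVpeak.
PEAK_SPHERE_VOLUME_ML = 1.0

#: Default voxel size (mm) of the synthetic phantoms, matching a clinical
#: whole-body PET reconstruction grid.
DEFAULT_SPACING_MM = (1.5, 1.5, 5.0)


@dataclass(frozen=True)
class UptakeVolume:
    """A 3-D tracer-uptake grid in either kBq/mL or SUV units."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    units: str  # "kBq_per_ml" | "suv"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"volume must be a 3-D grid, got shape {arr.shape}")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("voxel values must be finite and nonnegative")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing_mm}")
        if self.units not in ("kBq_per_ml", "suv"):
            raise ValueError(f"units must be 'kBq_per_ml' or 'suv', got {self.units!r}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers_along(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return np.arange(self.shape[axis]) * self.spacing_mm[axis]


@dataclass(frozen=True)
class SphereVOI:
    """Spherical volume of interest in physical (mm) coordinates."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.center_mm) != 3 or not all(np.isfinite(c) for c in self.center_mm):
            raise ValueError(f"center_mm must be a finite coordinate triple, got {self.center_mm}")
        if not (np.isfinite(self.diameter_mm) and self.diameter_mm > 0):
            raise ValueError(f"diameter_mm must be > 0, got {self.diameter_mm}")
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class ScanContext:
    """Injection and timing data needed to scale concentrations to SUV."""

    injected_activity_mbq: float
    body_weight_kg: float
    minutes_injection_to_scan: float
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be > 0 MBq")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be > 0 kg")
        if self.minutes_injection_to_scan < 0:
            raise ValueError("uptake time must be >= 0 min")
        if self.half_life_min <= 0:
            raise ValueError("half-life must be > 0 min")

    @property
    def decay_corrected_activity_mbq(self) -> float:
        """Activity remaining at scan time: A0 * 2^(-t / T1/2)."""
        return self.injected_activity_mbq * 2.0 ** (
            -self.minutes_injection_to_scan / self.half_life_min
        )


def suv_normalize(volume: UptakeVolume, ctx: ScanContext) -> UptakeVolume:
    """Convert a kBq/mL volume to body-weight SUV.

    SUV = C[kBq/mL] * weight[g] / (decay-corrected activity[kBq]), with
    weight in grams (kg * 1000) and activity in kBq (MBq * 1000); tissue
    density is taken as 1 g/mL.
    """
    if volume.units != "kBq_per_ml":
        raise ValueError(f"expected a kBq_per_ml volume, got units {volume.units!r}")
    factor = (ctx.body_weight_kg * 1000.0) / (ctx.decay_corrected_activity_mbq * 1000.0)
    return replace(volume, values=volume.values * factor, units="suv")


def voi_voxels(volume: UptakeVolume, voi: SphereVOI) -> np.ndarray:
    """Indices (N, 3 int array) of voxels whose centers fall inside the VOI.

    Raises if the sphere contains no voxel center.
    """
    sx, sy, sz = volume.spacing_mm
    cx, cy, cz = voi.center_mm
    r = voi.radius_mm
    # Bounding box in index space, clipped to the grid.
    lo = [max(0, int(np.ceil((c - r) / s))) for c, s in zip(voi.center_mm, volume.spacing_mm)]
    hi = [
        min(n - 1, int(np.floor((c + r) / s)))
        for c, s, n in zip(voi.center_mm, volume.spacing_mm, volume.shape)
    ]
    if any(l > h for l, h in zip(lo, hi)):
        raise ValueError(f"VOI {voi.name or voi.center_mm} contains no voxel center")
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1), np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1), indexing="ij",
    )
    d2 = (ii * sx - cx) ** 2 + (jj * sy - cy) ** 2 + (kk * sz - cz) ** 2
    inside = d2 <= r * r
    if not inside.any():
        raise ValueError(f"VOI {voi.name or voi.center_mm} contains no voxel center")
    return np.stack([ii[inside], jj[inside], kk[inside]], axis=1)


def _voi_values(volume: UptakeVolume, voi: SphereVOI) -> np.ndarray:
    idx = voi_voxels(volume, voi)
    return volume.values[idx[:, 0], idx[:, 1], idx[:, 2]]


def suv_max(volume: UptakeVolume, voi: SphereVOI) -> float:
    """Maximum voxel value inside the VOI."""
    return float(_voi_values(volume, voi).max())


def suv_mean(volume: UptakeVolume, voi: SphereVOI) -> float:
    """Arithmetic mean of voxel values inside the VOI."""
    return float(_voi_values(volume, voi).mean())


def peak_sphere_diameter_mm(volume_ml: float = PEAK_SPHERE_VOLUME_ML) -> float:
    """Diameter of the SUVpeak averaging sphere (1.0 mL ~ 12.4 mm)."""
    return 2.0 * (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def suv_peak(volume: UptakeVolume, voi: SphereVOI) -> float:
    """Best local 1.0 mL spherical average within the VOI.

    Candidate centers are the voxel centers inside the VOI; for each, the
    mean over voxels whose centers lie within the averaging sphere is taken
    (clipped at the volume boundary), and the maximum over candidates is
    returned.  Always <= :func:`suv_max` of the same VOI.
    """
    candidates = voi_voxels(volume, voi)
    sx, sy, sz = volume.spacing_mm
    r = peak_sphere_diameter_mm() / 2.0
    # Precompute the neighborhood stencil once: the grid is regular, so the
    # set of index offsets within the averaging sphere is shared.
    nx = int(np.floor(r / sx))
    ny = int(np.floor(r / sy))
    nz = int(np.floor(r / sz))
    oi, oj, ok = np.meshgrid(
        np.arange(-nx, nx + 1), np.arange(-ny, ny + 1), np.arange(-nz, nz + 1),
        indexing="ij",
    )
    within = (oi * sx) ** 2 + (oj * sy) ** 2 + (ok * sz) ** 2 <= r * r
    offsets = np.stack([oi[within], oj[within], ok[within]], axis=1)

    shape = np.array(volume.shape)
    best = -np.inf
    for c in candidates:
        pts = c + offsets
        ok_mask = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok_mask]
        mean = float(volume.values[pts[:, 0], pts[:, 1], pts[:, 2]].mean())
        if mean > best:
            best = mean
    return best


def make_phantom(
    dims: tuple[int, int, int],
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
    background: float = 0.5,
    lesions: Sequence[tuple[SphereVOI, float]] = (),
    noise_cv: float = 0.0,
    seed: int | None = None,
    units: str = "suv",
) -> UptakeVolume:
    """Paint a uniform-background phantom with spherical lesions.

    Lesion values replace the background inside each sphere (center-in-sphere
    membership).  ``noise_cv`` > 0 applies multiplicative Gaussian noise with
    that coefficient of variation, clipped at zero, under the given seed.
    Lesions must lie fully inside the grid.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    vol = UptakeVolume(np.full(dims, float(background)), tuple(spacing_mm), units)
    extent = [(n - 1) * s for n, s in zip(dims, spacing_mm)]
    arr = vol.values.copy()
    for voi, value in lesions:
        for ax in range(3):
            if voi.center_mm[ax] - voi.radius_mm < -spacing_mm[ax] / 2 or \
               voi.center_mm[ax] + voi.radius_mm > extent[ax] + spacing_mm[ax] / 2:
                raise ValueError(
                    f"lesion {voi.name or voi.center_mm} extends outside the grid on axis {ax}"
                )
        idx = voi_voxels(vol, voi)
        arr[idx[:, 0], idx[:, 1], idx[:, 2]] = float(value)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        arr = np.clip(arr * (1.0 + noise_cv * rng.standard_normal(arr.shape)), 0.0, None)
    return UptakeVolume(arr, tuple(spacing_mm), units)


def load_nifti(path, units: str) -> UptakeVolume:
    """Load a single-file NIfTI-1 volume; spacing from the header zooms."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    return UptakeVolume(data, tuple(float(z) for z in zooms), units)


def save_nifti(volume: UptakeVolume, path) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine from the spacing."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.values, affine), str(path))
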