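"""CT volume ingestion and tissue-mask construction.

Volumes are plain 3D numpy arrays of Hounsfield units together with voxel
spacing (mm, array-index order) and a physical origin.  The stage turns a
calibrated CT volume plus anatomical compartment masks (muscle envelope,
subcutaneous shell — these are inputs, not computed here) into mutually
exclusive binary masks for skeletal muscle (SM), subcutaneous adipose
tissue (SAT) and intra/inter-muscular adipose tissue (IMAT), and splits a
bilateral lower-extremity mask set into per-leg sets for downstream
fractal analysis.

Conventions: voxel indices are 0-based; physical position = origin +
index * spacing; axis 0 of the array is the subject's left-right axis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume",
    "TissueMaskSet",
    "HuRanges",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "gaussian_smooth",
    "normalize_hu",
    "threshold_tissues",
    "split_legs",
]


@dataclass
class CTVolume:
    """A 3D scalar grid in HU with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"every axis must have length >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class TissueMaskSet:
    """Mutually exclusive binary SM / SAT / IMAT masks on one shared grid."""

    sm: np.ndarray
    sat: np.ndarray
    imat: np.ndarray
    spacing: Tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sm = _as_binary(self.sm, "sm")
        self.sat = _as_binary(self.sat, "sat")
        self.imat = _as_binary(self.imat, "imat")
        if not (self.sm.shape == self.sat.shape == self.imat.shape):
            raise ValueError("all tissue masks must share one shape")
        self.spacing = tuple(float(s) for s in self.spacing)
        overlap = self.sm.astype(np.int16) + self.sat + self.imat
        if overlap.max(initial=0) > 1:
            raise ValueError("tissue masks overlap: a voxel belongs to more than one tissue")

    def tissues(self) -> dict:
        return {"sm": self.sm, "sat": self.sat, "imat": self.imat}

    def union(self) -> np.ndarray:
        return (self.sm | self.sat | self.imat).astype(np.uint8)


@dataclass(frozen=True)
class HuRanges:
    """HU windows used to classify voxels inside anatomical compartments.

    Defaults are the CT body-composition ranges in wide clinical use:
    muscle [-29, 150] HU, adipose [-190, -30] HU.  The two windows must be
    disjoint with fat below muscle so that SM/IMAT assignment inside the
    muscle compartment is unambiguous.
    """

    muscle_lo: float = -29.0
    muscle_hi: float = 150.0
    fat_lo: float = -190.0
    fat_hi: float = -30.0

    def __post_init__(self) -> None:
        if not (self.muscle_lo < self.muscle_hi and self.fat_lo < self.fat_hi):
            raise ValueError("each HU range needs lo < hi")
        if not self.fat_hi < self.muscle_lo:
            raise ValueError("fat range must lie strictly below the muscle range")


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask '{name}' contains values other than 0/1: {vals[:10]}")
    return arr.astype(np.uint8)


# ---------------------------------------------------------------------------
# I/O  (NIfTI via nibabel, NRRD via SimpleITK)
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike, kind: str = "image") -> CTVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD volume.

    ``kind="mask"`` additionally validates the voxel values as binary.
    """
    path = os.fspath(path)
    if kind not in ("image", "mask"):
        raise ValueError(f"kind must be 'image' or 'mask', got {kind!r}")
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    elif path.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        # GetArrayFromImage yields (z, y, x); reverse metadata to match.
        data = sitk.GetArrayFromImage(img)
        spacing = tuple(reversed(img.GetSpacing()))
        origin = tuple(reversed(img.GetOrigin()))
    else:
        raise ValueError(f"unsupported volume format: {path}")
    if kind == "mask":
        data = _as_binary(data, os.path.basename(path))
    else:
        data = np.asarray(data, dtype=np.float64)
    return CTVolume(data=data, spacing=spacing, origin=origin)


def write_volume(vol: CTVolume, path: str | os.PathLike, kind: str = "image") -> None:
    """Write a volume as NIfTI or NRRD; masks are stored as unsigned 8-bit."""
    path = os.fspath(path)
    data = vol.data
    if kind == "mask":
        data = _as_binary(data, path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(np.asarray(data), affine), path)
    elif path.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.asarray(data))
        img.SetSpacing(tuple(reversed(vol.spacing)))
        img.SetOrigin(tuple(reversed(vol.origin)))
        sitk.WriteImage(img, path)
    else:
        raise ValueError(f"unsupported volume format: {path}")


# ---------------------------------------------------------------------------
# Harmonisation
# ---------------------------------------------------------------------------

def resample_isotropic(vol: CTVolume, target_mm: float, *, is_mask: bool = False) -> CTVolume:
    """Resample to cubic voxels of edge ``target_mm``.

    Images use trilinear interpolation; masks nearest-neighbour so they stay
    binary.  A volume already isotropic at the target spacing is returned
    unchanged.  Cubic voxels are required upstream of box counting, where
    the box grid is defined in voxel units.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if np.allclose(vol.spacing, target_mm):
        return CTVolume(vol.data.copy(), vol.spacing, vol.origin)
    zoom = np.asarray(vol.spacing) / target_mm
    order = 0 if is_mask else 1
    out = ndimage.zoom(np.asarray(vol.data, dtype=float), zoom, order=order,
                       mode="nearest", grid_mode=True)
    if is_mask:
        out = (out > 0.5).astype(np.uint8)
    return CTVolume(out, (target_mm,) * 3, vol.origin)


def gaussian_smooth(vol: CTVolume, sigma_mm: float) -> CTVolume:
    """Gaussian noise filtering with a physically specified width.

    The per-axis kernel sigma is ``sigma_mm / spacing`` so anisotropic grids
    are smoothed isotropically in physical space.  Reflective boundaries;
    ``sigma_mm = 0`` is the exact identity.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be non-negative")
    if sigma_mm == 0:
        return CTVolume(vol.data.copy(), vol.spacing, vol.origin)
    sigma_vox = [sigma_mm / s for s in vol.spacing]
    out = ndimage.gaussian_filter(np.asarray(vol.data, dtype=float), sigma_vox, mode="reflect")
    return CTVolume(out, vol.spacing, vol.origin)


def normalize_hu(vol: CTVolume, muscle_mask: np.ndarray, target_muscle_hu: float = 50.0) -> CTVolume:
    """Scanner-harmonising HU normalisation against a muscle reference.

    Applies one global additive shift so that the median HU inside the
    muscle mask equals ``target_muscle_hu`` exactly.  An additive model is
    used because inter-scanner HU offsets are approximately additive; the
    operation is idempotent.
    """
    muscle_mask = np.asarray(muscle_mask)
    if muscle_mask.shape != vol.data.shape:
        raise ValueError("muscle mask shape must match the volume")
    inside = vol.data[muscle_mask > 0]
    if inside.size == 0:
        raise ValueError("muscle reference mask is empty")
    med = float(np.median(inside))
    if med == float(target_muscle_hu):
        return CTVolume(vol.data.copy(), vol.spacing, vol.origin)
    # subtract-then-add keeps the reference voxels exactly at the target
    return CTVolume((vol.data - med) + float(target_muscle_hu), vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# Tissue classification and leg splitting
# ---------------------------------------------------------------------------

def threshold_tissues(
    vol: CTVolume,
    muscle_compartment: np.ndarray,
    subcut_compartment: np.ndarray,
    ranges: HuRanges | None = None,
) -> TissueMaskSet:
    """Classify compartment voxels into SM / IMAT / SAT by HU window.

    SM  = muscle-compartment voxels within the muscle HU window.
    IMAT = muscle-compartment voxels within the adipose HU window
           (fat marbled through the muscle envelope).
    SAT = subcutaneous-compartment voxels within the adipose HU window.

    Compartments must be disjoint; with disjoint HU windows this guarantees
    the output masks are mutually exclusive.
    """
    ranges = ranges or HuRanges()
    mc = _as_binary(muscle_compartment, "muscle_compartment").astype(bool)
    sc = _as_binary(subcut_compartment, "subcut_compartment").astype(bool)
    if mc.shape != vol.data.shape or sc.shape != vol.data.shape:
        raise ValueError("compartment shapes must match the volume")
    if (mc & sc).any():
        raise ValueError("muscle and subcutaneous compartments overlap")
    hu = vol.data
    in_muscle_win = (hu >= ranges.muscle_lo) & (hu <= ranges.muscle_hi)
    in_fat_win = (hu >= ranges.fat_lo) & (hu <= ranges.fat_hi)
    return TissueMaskSet(
        sm=(mc & in_muscle_win),
        imat=(mc & in_fat_win),
        sat=(sc & in_fat_win),
        spacing=vol.spacing,
        provenance={
            "hu_ranges": {
                "muscle": [ranges.muscle_lo, ranges.muscle_hi],
                "fat": [ranges.fat_lo, ranges.fat_hi],
            }
        },
    )


def split_legs(masks: TissueMaskSet, dominant_frac: float = 0.10) -> Tuple[TissueMaskSet, TissueMaskSet]:
    """Split a bilateral mask set into (left, right) per-leg sets.

    The union mask is labelled with 26-connectivity; components holding at
    least ``dominant_frac`` of the foreground are the candidate legs, and
    exactly two must be present.  Components are ordered by centroid along
    axis 0 (the left-right axis) and each output is cropped to its
    component's bounding box.
    """
    union = masks.union()
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(union, structure=structure)
    if n == 0:
        raise ValueError("cannot split legs: union mask is empty (0 components)")
    sizes = ndimage.sum_labels(union, labels, index=np.arange(1, n + 1))
    dominant = np.flatnonzero(sizes >= dominant_frac * sizes.max()) + 1
    if len(dominant) != 2:
        raise ValueError(
            f"expected exactly 2 dominant components along the left-right axis, found {len(dominant)}"
        )
    centroids = ndimage.center_of_mass(union, labels, dominant)
    order = np.argsort([c[0] for c in centroids])  # smaller axis-0 centroid = left
    out = []
    for lab in (dominant[order[0]], dominant[order[1]]):
        comp = labels == lab
        sl = ndimage.find_objects(comp.astype(np.uint8))[0]
        out.append(
            TissueMaskSet(
                sm=(masks.sm.astype(bool) & comp)[sl],
                sat=(masks.sat.astype(bool) & comp)[sl],
                imat=(masks.imat.astype(bool) & comp)[sl],
                spacing=masks.spacing,
                provenance={**masks.provenance, "leg_bbox": [(s.start, s.stop) for s in sl]},
            )
        )
    return out[0], out[1]
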