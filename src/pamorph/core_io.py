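"""Spatial data model and file I/O for CT volumes, masks and centerlines.

Conventions used throughout the package:

* voxel indices are 0-based triples ``(i, j, k)`` indexing ``voxels[i, j, k]``;
* the world frame is LPS (x grows to the patient's left, y posterior,
  z superior), all lengths in millimetres;
* the world position of a voxel is the position of its *center*:
  ``world = origin + index * spacing``;
* axis 2 (``k``) is the slice axis, so an "axial slice" is ``voxels[:, :, k]``.

NIfTI is the canonical on-disk format; NRRD and read-only DICOM series are
supported through SimpleITK.  Files stored in other orientations are
reorientated to axis-aligned LPS on read.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np


class FormatError(ValueError):
    """Unsupported or malformed image file."""


class GeometryError(ValueError):
    """Inconsistent or unsupported spatial geometry (spacing, orientation)."""


class BoundsError(IndexError):
    """Voxel index outside the image grid."""


@dataclass(frozen=True)
class Point3D:
    """A point in world coordinates (mm, LPS)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("Point3D coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a) -> "Point3D":
        a = np.asarray(a, dtype=float)
        return Point3D(float(a[0]), float(a[1]), float(a[2]))


def _check_geometry(shape, spacing, origin) -> tuple[np.ndarray, np.ndarray]:
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,):
        raise GeometryError("spacing and origin must be length-3 vectors")
    if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise GeometryError(f"spacing must be positive and finite, got {spacing}")
    if not np.all(np.isfinite(origin)):
        raise GeometryError("origin must be finite")
    if len(shape) != 3 or any(n < 1 for n in shape):
        raise GeometryError(f"grid must be 3D with at least one voxel per axis, got {shape}")
    return spacing, origin


@dataclass
class ImageVolume:
    """A 3D scalar grid in Hounsfield Units with anisotropic spacing.

    Attributes
    ----------
    voxels : (nx, ny, nz) float array, HU values
    spacing : (3,) per-axis voxel size in mm
    origin : (3,) world position (mm, LPS) of the center of voxel (0, 0, 0)
    """

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GeometryError("voxels must be a 3D array")
        self.spacing, self.origin = _check_geometry(self.voxels.shape, self.spacing, self.origin)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """A boolean grid sharing the geometry of a parent :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise GeometryError("voxels must be a 3D array")
        self.spacing, self.origin = _check_geometry(self.voxels.shape, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def volume_mm3(self) -> float:
        """Foreground voxel count times voxel volume."""
        return self.count() * float(np.prod(self.spacing))

    def same_grid_as(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


# ---------------------------------------------------------------------------
# index <-> world


def voxel_to_world(volume, index) -> Point3D:
    """World position (mm) of the center of voxel ``index`` (0-based)."""
    idx = np.asarray(index)
    shape = volume.shape
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        raise BoundsError(f"index {tuple(int(i) for i in idx)} outside grid {shape}")
    world = volume.origin + idx * volume.spacing
    return Point3D.from_array(world)


def world_to_voxel(volume, point: Point3D, *, clip: bool = False) -> tuple[int, int, int]:
    """Nearest voxel index for a world point (inverse of :func:`voxel_to_world`)."""
    cont = (point.as_array() - volume.origin) / volume.spacing
    idx = np.rint(cont).astype(int)
    if clip:
        idx = np.clip(idx, 0, np.asarray(volume.shape) - 1)
    elif np.any(idx < 0) or np.any(idx >= np.asarray(volume.shape)):
        raise BoundsError(
            f"point ({point.x:.2f}, {point.y:.2f}, {point.z:.2f}) mm maps to index "
            f"{tuple(int(i) for i in idx)} outside grid {volume.shape}"
        )
    return tuple(int(i) for i in idx)


def world_to_voxel_continuous(volume, points: np.ndarray) -> np.ndarray:
    """Fractional voxel coordinates for an (N, 3) array of world points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (pts - volume.origin[None, :]) / volume.spacing[None, :]


# ---------------------------------------------------------------------------
# volume / mask file I/O


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def _is_nrrd(path: str) -> bool:
    return path.endswith(".nrrd") or path.endswith(".nhdr")


def read_volume(path: str) -> ImageVolume:
    """Read a volume from NIfTI, NRRD, or a DICOM series directory.

    HU values are passed through unchanged (the DICOM rescale slope and
    intercept are applied by the reader).  The grid is reorientated to
    axis-aligned LPS; obliquely acquired data are rejected.
    """
    if os.path.isdir(path):
        return _read_dicom_series(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nifti(path):
        arr, spacing, origin = _read_nifti(path)
    elif _is_nrrd(path):
        arr, spacing, origin = _read_sitk(path)
    else:
        raise FormatError(f"unsupported volume format: {path!r} (expected .nii/.nii.gz/.nrrd or a DICOM directory)")
    return ImageVolume(arr.astype(np.float32), spacing, origin)


def read_mask(path: str) -> BinaryMask:
    """Read a 0/1 integer volume as a binary mask."""
    vol = read_volume(path)
    return BinaryMask(vol.voxels > 0.5, vol.spacing, vol.origin)


def write_volume(volume: ImageVolume, path: str) -> None:
    if _is_nifti(path):
        _write_nifti(volume.voxels, volume.spacing, volume.origin, path)
    elif _is_nrrd(path):
        _write_sitk(volume.voxels, volume.spacing, volume.origin, path)
    else:
        raise FormatError(f"unsupported volume format: {path!r}")


def write_mask(mask: BinaryMask, path: str) -> None:
    arr = mask.voxels.astype(np.uint8)
    if _is_nifti(path):
        _write_nifti(arr, mask.spacing, mask.origin, path)
    elif _is_nrrd(path):
        _write_sitk(arr, mask.spacing, mask.origin, path)
    else:
        raise FormatError(f"unsupported mask format: {path!r}")


def _read_nifti(path: str):
    import nibabel as nib

    img = nib.load(path)
    img = nib.as_closest_canonical(img)  # index -> RAS, positive diagonal
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-3 * max(1.0, np.abs(rot).max())):
        raise GeometryError("oblique NIfTI orientations are not supported")
    arr = np.asanyarray(img.dataobj).astype(np.float64)
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI image, got shape {arr.shape}")
    spacing = np.abs(np.diag(rot))
    origin_ras = aff[:3, 3]
    # RAS -> LPS: negate x and y; flip those array axes so spacing stays positive.
    n = arr.shape
    arr = arr[::-1, ::-1, :].copy()
    origin = np.array(
        [
            -(origin_ras[0] + spacing[0] * (n[0] - 1)),
            -(origin_ras[1] + spacing[1] * (n[1] - 1)),
            origin_ras[2],
        ]
    )
    return arr, spacing, origin


def _write_nifti(arr, spacing, origin, path) -> None:
    import nibabel as nib

    # store as RAS: flip x and y axes back
    n = arr.shape
    data = np.asarray(arr)[::-1, ::-1, :]
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[0, 3] = -origin[0] - spacing[0] * (n[0] - 1)
    aff[1, 3] = -origin[1] - spacing[1] * (n[1] - 1)
    aff[2, 3] = origin[2]
    img = nib.Nifti1Image(np.ascontiguousarray(data), aff)
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, path)


def _sitk_to_arrays(img):
    import SimpleITK as sitk

    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    if not np.allclose(direction - np.diag(np.diag(direction)), 0, atol=1e-3):
        raise GeometryError("oblique image orientations are not supported")
    arr = sitk.GetArrayFromImage(img).astype(np.float64)  # [z, y, x]
    arr = np.transpose(arr, (2, 1, 0))
    # handle axis flips encoded in the direction diagonal (SimpleITK is LPS)
    for ax in range(3):
        if direction[ax, ax] < 0:
            arr = np.flip(arr, axis=ax)
            origin[ax] = origin[ax] + direction[ax, ax] * spacing[ax] * (arr.shape[ax] - 1)
    return np.ascontiguousarray(arr), spacing, origin


def _read_sitk(path: str):
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # pragma: no cover - backend specific message
        raise FormatError(f"could not read {path!r}: {exc}") from exc
    return _sitk_to_arrays(img)


def _write_sitk(arr, spacing, origin, path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(np.asarray(arr), (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, path)


def _read_dicom_series(path: str) -> ImageVolume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(path)
    if not names:
        raise FormatError(f"no DICOM series found under {path!r}")
    reader.SetFileNames(names)
    img = reader.Execute()
    # check uniform slice spacing
    zs = []
    for f in names:
        fr = sitk.ImageFileReader()
        fr.SetFileName(f)
        fr.ReadImageInformation()
        zs.append(fr.GetOrigin()[2])
    if len(zs) > 2:
        steps = np.diff(sorted(zs))
        if steps.size and (steps.max() - steps.min()) > 0.01 * max(steps.mean(), 1e-6):
            raise GeometryError("inconsistent DICOM slice spacing")
    arr, spacing, origin = _sitk_to_arrays(img)
    return ImageVolume(arr.astype(np.float32), spacing, origin)


# ---------------------------------------------------------------------------
# centerline / measurement table export


def write_centerline_csv(tree, path: str, profiles: dict | None = None) -> None:
    """Write a centerline tree to CSV.

    Columns: ``branch_id, point_index, x_mm, y_mm, z_mm, arclength_mm, area_mm2``.
    ``profiles`` optionally maps branch id to a cross-section profile providing
    per-control-point areas (NaN where absent).
    """
    import pandas as pd

    rows = []
    for name, branch in tree.branches.items():
        areas = np.full(len(branch.points), np.nan)
        if profiles and name in profiles:
            prof = profiles[name]
            areas_interp = np.interp(
                branch.arclengths, prof.arclengths, prof.areas, left=np.nan, right=np.nan
            )
            areas = areas_interp
        for i, (p, s) in enumerate(zip(branch.points, branch.arclengths)):
            rows.append(
                {
                    "branch_id": name,
                    "point_index": i,
                    "x_mm": p[0],
                    "y_mm": p[1],
                    "z_mm": p[2],
                    "arclength_mm": s,
                    "area_mm2": areas[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_centerline_json(tree, path: str) -> None:
    out = {"branches": {}, "bifurcation": None}
    if tree.bifurcation is not None:
        b = tree.bifurcation
        out["bifurcation"] = [b.x, b.y, b.z]
    for name, branch in tree.branches.items():
        out["branches"][name] = {
            "points": np.asarray(branch.points).tolist(),
            "tangents": np.asarray(branch.tangents).tolist(),
            "arclengths": np.asarray(branch.arclengths).tolist(),
        }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
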