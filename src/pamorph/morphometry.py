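"""The nine central pulmonary artery quantities: D, A, V for MPA, RPA, LPA.

Given a lumen mask and a centerline tree this module measures, per artery:

* ``D`` - the 1D diameter on an axial maximum-intensity projection (MIP)
  through a 10 mm slab, measured through the centerline point 15 mm from the
  bifurcation, perpendicular to the vessel's in-plane long axis, using the
  full-width-at-half-maximum convention for sub-voxel edge localization;
* ``A`` - the 2D cross-sectional area of the lumen on the plane orthogonal
  to the centerline tangent at that same point;
* ``V`` - the 3D volume, the area profile integrated over arclength
  (trapezoidal; at the standard 1 mm control spacing this coincides with the
  plain sum of per-control-point areas).

Control points close to the bifurcation (and to the trunk's valve end) are
excluded, since planes there cut through merged lumina of several vessels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .centerline import Centerline, CenterlineTree, LengthError
from .core_io import BinaryMask, BoundsError, ImageVolume, Point3D

log = logging.getLogger(__name__)

ARTERIES = ("MPA", "RPA", "LPA")
_BRANCH_OF = {"MPA": "trunk", "RPA": "child_1", "LPA": "child_2"}


class MarginError(ValueError):
    """Exclusion margins leave no usable control points."""


@dataclass
class MeasurementConfig:
    """Tunable measurement geometry (all mm).

    ``exclusion_margin`` is trimmed from the bifurcation end of every branch
    and from the trunk's proximal (valve) end before areas are profiled; it
    should be at least the trunk radius when branches are fat, because the
    junction's merged lumen extends roughly that far into each branch.
    ``diameter_offset`` is where the 1D/2D measurements are taken: 15 mm from
    the bifurcation along each branch (proximally for the trunk, which ends
    at the bifurcation).
    """

    exclusion_margin: float = 5.0
    mip_slab: float = 10.0
    diameter_offset: float = 15.0
    section_halfsize: float = 30.0
    section_step: float = 0.25

    def __post_init__(self) -> None:
        for name in ("exclusion_margin", "mip_slab", "diameter_offset", "section_halfsize", "section_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CrossSectionProfile:
    """Per-control-point cross-sectional areas along one artery."""

    arclengths: np.ndarray  # mm, on the branch's own arclength axis
    areas: np.ndarray  # mm^2
    artery: str = "MPA"

    def __post_init__(self) -> None:
        self.arclengths = np.asarray(self.arclengths, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.arclengths.shape != self.areas.shape:
            raise ValueError("arclengths and areas must have the same length")
        if self.arclengths.size and np.any(np.diff(self.arclengths) <= 0):
            raise ValueError("arclengths must be strictly increasing")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")

    def slab_widths(self) -> np.ndarray:
        """Thickness of the slice each control point represents: the local
        control spacing (half-gap to each neighbour, a full half-gap beyond
        the end points)."""
        s = self.arclengths
        if s.size < 2:
            raise ValueError("volume needs at least two control points")
        gaps = np.diff(s)
        w = np.empty_like(s)
        w[1:-1] = (s[2:] - s[:-2]) / 2.0
        w[0] = gaps[0]
        w[-1] = gaps[-1]
        return w

    def slab_extent(self) -> tuple[float, float]:
        """Arclength window actually covered by the summed slices."""
        s = self.arclengths
        gaps = np.diff(s)
        return float(s[0] - gaps[0] / 2.0), float(s[-1] + gaps[-1] / 2.0)


@dataclass
class VesselMeasurements:
    """The nine quantities; fields are None for arteries absent from the tree."""

    d_mpa: float | None = None
    d_rpa: float | None = None
    d_lpa: float | None = None
    a_mpa: float | None = None
    a_rpa: float | None = None
    a_lpa: float | None = None
    v_mpa: float | None = None
    v_rpa: float | None = None
    v_lpa: float | None = None
    extents: dict = field(default_factory=dict)  # artery -> (s0, s1) mm used for V

    def as_dict(self) -> dict:
        return {
            "D_MPA": self.d_mpa,
            "A_MPA": self.a_mpa,
            "V_MPA": self.v_mpa,
            "D_RPA": self.d_rpa,
            "A_RPA": self.a_rpa,
            "V_RPA": self.v_rpa,
            "D_LPA": self.d_lpa,
            "A_LPA": self.a_lpa,
            "V_LPA": self.v_lpa,
        }


# ---------------------------------------------------------------------------
# sampling helpers


def _to_cont_index(grid, pts: np.ndarray) -> np.ndarray:
    return (np.atleast_2d(pts) - np.asarray(grid.origin)[None, :]) / np.asarray(grid.spacing)[None, :]


def _sample(arr: np.ndarray, grid, pts: np.ndarray) -> np.ndarray:
    cont = _to_cont_index(grid, pts)
    return ndimage.map_coordinates(arr.astype(np.float32), cont.T, order=1, mode="constant", cval=0.0)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def cross_section_area(
    mask: BinaryMask,
    point: Point3D,
    normal,
    config: MeasurementConfig | None = None,
) -> float:
    """Lumen area (mm^2) on the plane through ``point`` orthogonal to ``normal``.

    The mask is sampled with trilinear interpolation on a square plane grid,
    thresholded at 0.5, and only the in-plane connected region containing the
    center point is counted - an adjacent vessel crossing the plane must not
    inflate the area.  Returns 0 when the center sample is background.
    """
    config = config or MeasurementConfig()
    n = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n)
    if not math.isclose(nn, 1.0, rel_tol=1e-3):
        raise ValueError(f"normal must be a unit vector, |n| = {nn:.4f}")
    p = point.as_array()
    cont = _to_cont_index(mask, p[None, :])[0]
    if np.any(cont < -0.5) or np.any(cont > np.asarray(mask.shape) - 0.5):
        raise BoundsError(f"section point {p} outside the grid")
    u, v = _plane_basis(n)
    step = config.section_step
    t = np.arange(-config.section_halfsize, config.section_halfsize + step / 2, step)
    m = len(t)
    uu, vv = np.meshgrid(t, t, indexing="ij")
    pts = p[None, :] + uu.reshape(-1, 1) * u[None, :] + vv.reshape(-1, 1) * v[None, :]
    vals = _sample(mask.voxels, mask, pts).reshape(m, m)
    center = (m // 2, m // 2)
    if vals[center] < 0.5:
        return 0.0
    bw = vals >= 0.5
    labels, _ = ndimage.label(bw, structure=np.ones((3, 3), dtype=bool))
    region = labels == labels[center]
    return float(region.sum()) * step * step


def area_profile(
    mask: BinaryMask,
    branch: Centerline,
    config: MeasurementConfig | None = None,
    artery: str = "MPA",
    trim_start: float | None = None,
    trim_end: float | None = None,
) -> CrossSectionProfile:
    """One area per surviving control point, normals from the branch tangents.

    ``trim_start``/``trim_end`` default to ``exclusion_margin`` at both ends;
    callers set the margin per end (children keep their free distal end).
    """
    config = config or MeasurementConfig()
    ts = config.exclusion_margin if trim_start is None else trim_start
    te = config.exclusion_margin if trim_end is None else trim_end
    s = branch.arclengths
    keep = (s >= ts - 1e-9) & (s <= branch.length - te + 1e-9)
    if keep.sum() < 3:
        raise MarginError(
            f"exclusion margins ({ts:.1f}, {te:.1f}) mm leave {int(keep.sum())} of "
            f"{len(s)} control points on a {branch.length:.1f} mm branch"
        )
    areas = np.empty(int(keep.sum()))
    for i, j in enumerate(np.nonzero(keep)[0]):
        areas[i] = cross_section_area(
            mask, Point3D.from_array(branch.points[j]), branch.tangents[j], config
        )
    return CrossSectionProfile(s[keep], areas, artery)


def volume_from_profile(profile: CrossSectionProfile) -> float:
    """V = sum of A(s_i) * local slice thickness over the profile.

    Each control point represents one slice whose thickness is the local
    control spacing, so at uniform 1 mm spacing this is the plain sum of the
    per-slice areas; for non-uniform spacing it is trapezoidal integration
    extended half a slice beyond each end point (see ``slab_extent``).
    """
    if profile.arclengths.size == 0:
        raise ValueError("empty cross-section profile")
    return float(np.sum(profile.areas * profile.slab_widths()))


# ---------------------------------------------------------------------------
# MIP diameter


def _measurement_arclength(tree: CenterlineTree, artery: str, offset: float) -> float:
    branch = tree.branches[_BRANCH_OF[artery]]
    if artery == "MPA":
        # the trunk ends at (or just short of) the bifurcation: measure
        # proximally from the bifurcation's arclength on the trunk axis
        s_bif = tree.trunk_bif_s if tree.trunk_bif_s is not None else branch.length
        s = s_bif - offset
        # s may exceed the branch length when the junction swallowed the
        # distal trunk skeleton; the point is then reached by extrapolating
        # the trunk axis, which point_at supports
        if s < 0:
            raise LengthError(
                f"MPA branch ({branch.length:.1f} mm, bifurcation at {s_bif:.1f} mm) cannot host "
                f"a measurement {offset:.1f} mm proximal to the bifurcation"
            )
        return s
    if branch.length < offset:
        raise LengthError(
            f"{artery} branch ({branch.length:.1f} mm) shorter than the {offset:.1f} mm measurement offset"
        )
    return offset


def diameter_mip(
    volume: ImageVolume,
    mask: BinaryMask,
    tree: CenterlineTree,
    artery: str,
    config: MeasurementConfig | None = None,
) -> float:
    """Vessel width (mm) on an axial MIP through a 10 mm slab.

    The slab is centered on the centerline point ``diameter_offset`` from the
    bifurcation; the width is the in-lumen chord through that point
    perpendicular to the branch's in-plane long-axis direction.  Edges are
    located at half maximum between the lumen and background intensity of the
    mask-restricted HU projection, giving sub-voxel precision.
    """
    config = config or MeasurementConfig()
    branch = tree.branches.get(_BRANCH_OF[artery])
    if branch is None:
        raise KeyError(f"tree has no branch for artery {artery}")
    s_meas = _measurement_arclength(tree, artery, config.diameter_offset)
    p = branch.point_at(s_meas)
    tan = branch.tangent_at(s_meas)

    k_center = (p[2] - mask.origin[2]) / mask.spacing[2]
    half = config.mip_slab / 2.0 / mask.spacing[2]
    k0 = max(0, int(math.ceil(k_center - half)))
    k1 = min(mask.shape[2] - 1, int(math.floor(k_center + half)))
    if k1 < k0:
        raise BoundsError("MIP slab lies outside the grid")
    # keep the raw HU (with its partial-volume ramp, needed for sub-voxel
    # FWHM edges) inside a slightly dilated mask; fill the background level
    # elsewhere so unrelated bright structures cannot contaminate the MIP
    slab_mask = mask.voxels[:, :, k0 : k1 + 1]
    slab_hu = volume.voxels[:, :, k0 : k1 + 1]
    dil = ndimage.binary_dilation(slab_mask, iterations=2)
    bg = float(np.median(slab_hu[~dil])) if np.any(~dil) else -1000.0
    mip = np.where(dil, slab_hu, bg).max(axis=2)

    d_inplane = tan[:2].copy()
    nrm = np.linalg.norm(d_inplane)
    d_inplane = np.array([1.0, 0.0]) if nrm < 1e-3 else d_inplane / nrm
    chord_dir = np.array([-d_inplane[1], d_inplane[0]])

    step = 0.1
    tgrid = np.arange(-config.section_halfsize, config.section_halfsize + step / 2, step)
    xy = p[None, :2] + tgrid[:, None] * chord_dir[None, :]
    cont = (xy - np.asarray(mask.origin)[None, :2]) / np.asarray(mask.spacing)[None, :2]
    prof = ndimage.map_coordinates(mip.astype(np.float32), cont.T, order=1, mode="constant", cval=bg)
    c = len(tgrid) // 2
    level = 0.5 * (prof[c] + bg)
    if prof[c] <= level:
        raise ValueError(f"{artery}: measurement point is not inside the lumen on the MIP")

    def edge(side: int) -> float:
        i = c
        while 0 < i < len(prof) - 1:
            j = i + side
            if prof[j] < level:
                # linear interpolation of the crossing
                frac = (prof[i] - level) / (prof[i] - prof[j])
                return tgrid[i] + side * frac * step
            i = j
        return tgrid[i]

    width = edge(+1) - edge(-1)
    return float(width)


# ---------------------------------------------------------------------------
# all nine quantities


def measure_all(
    volume: ImageVolume,
    mask: BinaryMask,
    tree: CenterlineTree,
    config: MeasurementConfig | None = None,
) -> VesselMeasurements:
    """Fill D/A/V for every artery present in the tree.

    A single-branch tree yields MPA values only (measured at the offset from
    the distal end); the trimmed arclength extents used for each volume are
    recorded in ``extents`` and logged.
    """
    config = config or MeasurementConfig()
    out = VesselMeasurements()
    have_children = "child_1" in tree.branches or "child_2" in tree.branches
    for artery in ARTERIES:
        bname = _BRANCH_OF[artery]
        branch = tree.branches.get(bname)
        if branch is None:
            continue
        s_meas = _measurement_arclength(tree, artery, config.diameter_offset)
        a = cross_section_area(
            mask, Point3D.from_array(branch.point_at(s_meas)), branch.tangent_at(s_meas), config
        )
        d = diameter_mip(volume, mask, tree, artery, config)
        if artery == "MPA":
            # trim the valve end by the margin, and the bifurcation end by
            # the margin measured back from the bifurcation arclength
            s_bif = tree.trunk_bif_s if tree.trunk_bif_s is not None else branch.length
            te = branch.length - (s_bif - config.exclusion_margin) if have_children else 0.0
            trim = (config.exclusion_margin, max(0.0, te))
        else:
            trim = (config.exclusion_margin, 0.0)  # bifurcation end, free distal end
        prof = area_profile(mask, branch, config, artery, trim_start=trim[0], trim_end=trim[1])
        v = volume_from_profile(prof)
        extent = prof.slab_extent()
        out.extents[artery] = extent
        log.info("%s: D=%.2f mm A=%.1f mm^2 V=%.0f mm^3 over s=[%.1f, %.1f] mm", artery, d, a, v, *extent)
        circle = math.pi * (d / 2.0) ** 2
        if a > 0 and not (0.75 <= a / circle <= 1.25):
            log.warning("%s: area %.1f deviates >25%% from the circular estimate %.1f", artery, a, circle)
        setattr(out, f"d_{artery.lower()}", float(d))
        setattr(out, f"a_{artery.lower()}", float(a))
        setattr(out, f"v_{artery.lower()}", float(v))
    return out
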