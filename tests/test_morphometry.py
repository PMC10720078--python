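"""Cross-sectional areas, volumes, MIP diameters."""

import math

import numpy as np
import pytest

from pamorph.centerline import CenterlineTree, LengthError
from pamorph.core_io import Point3D
from pamorph.morphometry import (
    CrossSectionProfile,
    MarginError,
    MeasurementConfig,
    area_profile,
    cross_section_area,
    diameter_mip,
    measure_all,
    volume_from_profile,
)
from pamorph.phantom import make_cylinder_spec, rasterize_phantom
from pamorph.segmentation import segment_vessel
from tests.conftest import _chain

CIRCLE = math.pi * 15.0**2


def test_cylinder_cross_section_area(cylinder):
    a = cross_section_area(cylinder.mask, Point3D(0, 0, 25.0), (0, 0, 1.0))
    assert abs(a / CIRCLE - 1.0) < 0.02


def test_tilted_plane_gives_ellipse_area(cylinder):
    """A 45-degree tilted section cuts an ellipse of area pi r^2 / cos(45)."""
    n = np.array([0.0, 1.0, 1.0]) / math.sqrt(2)
    a = cross_section_area(cylinder.mask, Point3D(0, 0, 25.0), n)
    assert abs(a / (CIRCLE * math.sqrt(2)) - 1.0) < 0.04


def test_section_outside_vessel_is_zero(cylinder):
    assert cross_section_area(cylinder.mask, Point3D(16.2, 16.2, 25.0), (0, 0, 1.0)) == 0.0


def test_non_unit_normal_rejected(cylinder):
    with pytest.raises(ValueError):
        cross_section_area(cylinder.mask, Point3D(0, 0, 25.0), (0, 0, 2.0))


def test_flat_profile_on_cylinder(cylinder):
    prof = area_profile(cylinder.mask, cylinder.tree.branches["trunk"], trim_start=5.0, trim_end=5.0)
    assert prof.areas.max() / prof.areas.min() < 1.05


def test_tapered_profile_monotone():
    """Areas decrease along a linearly tapering tube (2% ripple allowed)."""
    spec = make_cylinder_spec(radius=15.0, length=50.0, spacing=(1.0, 1.0, 1.0), r_end=10.0)
    bundle = _chain(spec, Point3D(0, 0, 25.0))
    prof = area_profile(bundle.mask, bundle.tree.branches["trunk"], trim_start=5.0, trim_end=5.0)
    areas = prof.areas if prof.areas[0] > prof.areas[-1] else prof.areas[::-1]
    ratios = np.diff(areas) / areas[:-1]
    assert np.all(ratios < 0.02)  # monotone decrease, small ripple allowed
    # every area matches the analytic taper pi*(15 - z/10)^2 at its z position
    branch = bundle.tree.branches["trunk"]
    for s, a in zip(prof.arclengths, prof.areas):
        z = branch.point_at(s)[2]
        r_true = 15.0 - 5.0 * z / 50.0
        assert a == pytest.approx(math.pi * r_true**2, rel=0.05)


def test_margin_error_when_branch_consumed(cylinder):
    with pytest.raises(MarginError):
        area_profile(cylinder.mask, cylinder.tree.branches["trunk"], trim_start=40.0, trim_end=40.0)


def test_volume_constant_profile_is_plain_sum():
    """Three 100 mm^2 slices at 1 mm spacing hold 300 mm^3."""
    prof = CrossSectionProfile(np.array([0.0, 1.0, 2.0]), np.array([100.0, 100.0, 100.0]))
    assert volume_from_profile(prof) == pytest.approx(300.0)
    assert prof.slab_extent() == (-0.5, 2.5)


def test_volume_empty_profile_rejected():
    with pytest.raises(ValueError):
        volume_from_profile(CrossSectionProfile(np.array([]), np.array([])))
    with pytest.raises(ValueError):
        volume_from_profile(CrossSectionProfile(np.array([1.0]), np.array([5.0])))


def test_volume_additive_over_slice_partition(cylinder):
    """Splitting the control points into two runs preserves total volume."""
    prof = area_profile(cylinder.mask, cylinder.tree.branches["trunk"], trim_start=5.0, trim_end=5.0)
    mid = len(prof.areas) // 2
    v_full = volume_from_profile(prof)
    v_a = volume_from_profile(CrossSectionProfile(prof.arclengths[:mid], prof.areas[:mid]))
    v_b = volume_from_profile(CrossSectionProfile(prof.arclengths[mid:], prof.areas[mid:]))
    assert abs((v_a + v_b) / v_full - 1.0) < 0.005


def test_cylinder_volume_against_closed_form(cylinder):
    prof = area_profile(cylinder.mask, cylinder.tree.branches["trunk"], trim_start=5.0, trim_end=5.0)
    v = volume_from_profile(prof)
    lo, hi = prof.slab_extent()
    assert abs(v / (CIRCLE * (hi - lo)) - 1.0) < 0.03


def test_profile_volume_matches_voxel_count(cylinder):
    """Profile-integrated volume agrees with voxel counting over the same
    axial extent within 3% (the cylinder's axis is the z axis)."""
    prof = area_profile(cylinder.mask, cylinder.tree.branches["trunk"], trim_start=5.0, trim_end=5.0)
    v_prof = volume_from_profile(prof)
    trunk = cylinder.tree.branches["trunk"]
    lo, hi = prof.slab_extent()
    z0 = trunk.point_at(lo)[2]
    z1 = trunk.point_at(hi)[2]
    mask = cylinder.mask
    zs = mask.origin[2] + np.arange(mask.shape[2]) * mask.spacing[2]
    sel = (zs >= min(z0, z1)) & (zs <= max(z0, z1))
    v_vox = mask.voxels[:, :, sel].sum() * mask.spacing.prod()
    assert abs(v_prof / v_vox - 1.0) < 0.03


def test_diameter_mip_axis_along_z(cylinder):
    d = diameter_mip(cylinder.volume, cylinder.mask, cylinder.tree, "MPA")
    assert abs(d - 30.0) < 0.5  # within one in-plane voxel


def test_diameter_mip_axis_in_axial_plane():
    """With the axis lying in the axial plane the perpendicular chord still
    equals the diameter."""
    spec = make_cylinder_spec(radius=15.0, length=50.0, spacing=(1.0, 1.0, 1.0), axis="x")
    bundle = _chain(spec, Point3D(25.0, 0.0, 0.0))
    d = diameter_mip(bundle.volume, bundle.mask, bundle.tree, "MPA")
    assert abs(d - 30.0) < 1.0


def test_diameter_offset_beyond_branch_errors(cylinder):
    with pytest.raises(LengthError):
        diameter_mip(cylinder.volume, cylinder.mask, cylinder.tree, "MPA", MeasurementConfig(diameter_offset=200.0))


def test_single_branch_tree_reports_mpa_only(cylinder):
    m = measure_all(cylinder.volume, cylinder.mask, cylinder.tree, MeasurementConfig())
    assert m.d_mpa is not None and m.a_mpa is not None and m.v_mpa is not None
    assert m.d_rpa is None and m.v_lpa is None


def test_measurements_translation_invariant(pa_tree):
    """All nine quantities are unchanged by a whole-voxel shift of the data."""
    from pamorph.centerline import CenterlineConfig, extract_tree, skeletonize
    from pamorph.core_io import BinaryMask, ImageVolume

    shift = (2, 1, 2)
    vol2 = ImageVolume(np.roll(pa_tree.volume.voxels, shift, (0, 1, 2)), pa_tree.volume.spacing, pa_tree.volume.origin)
    mask2 = BinaryMask(np.roll(pa_tree.mask.voxels, shift, (0, 1, 2)), pa_tree.mask.spacing, pa_tree.mask.origin)
    seed = Point3D.from_array(
        pa_tree.spec.tubes["trunk"].curve.point(30.0) + np.asarray(shift) * np.asarray(pa_tree.mask.spacing)
    )
    tree2 = extract_tree(skeletonize(mask2), CenterlineConfig(), mask=mask2, seed=seed)
    m2 = measure_all(vol2, mask2, tree2, MeasurementConfig(exclusion_margin=18.0))
    ref = pa_tree.measurements.as_dict()
    # equal up to tip-search tie-breaking, which is sub-voxel
    for key, val in m2.as_dict().items():
        assert val == pytest.approx(ref[key], rel=0.01), key


def test_area_consistent_with_diameter(pa_tree):
    """Near-circular sections: A within 25% of pi (D/2)^2 for every artery."""
    m = pa_tree.measurements.as_dict()
    for art in ("MPA", "RPA", "LPA"):
        circle = math.pi * (m[f"D_{art}"] / 2.0) ** 2
        assert 0.75 < m[f"A_{art}"] / circle < 1.25
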