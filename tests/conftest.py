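"""Shared fixtures: phantoms are rasterized once per session and reused."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from pamorph.centerline import CenterlineConfig, CenterlineTree, extract_tree, skeletonize
from pamorph.core_io import BinaryMask, ImageVolume, Point3D
from pamorph.morphometry import MeasurementConfig, VesselMeasurements, measure_all
from pamorph.phantom import (
    PhantomSpec,
    make_arc_tube_spec,
    make_cylinder_spec,
    make_pa_tree_spec,
    rasterize_phantom,
)
from pamorph.segmentation import segment_vessel

# geometry of the standard test phantoms (mm)
CYL_RADIUS, CYL_LENGTH = 15.0, 50.0
ARC_RADIUS, ARC_CURVE_RADIUS, ARC_ANGLE = 8.0, 40.0, 90.0
TREE = dict(trunk_radius=18.0, branch_radii=(12.0, 12.0), trunk_length=60.0, branch_lengths=(50.0, 50.0))
TREE_MARGIN = 18.0  # one trunk radius: the junction's merged lumen reaches about that far


@dataclass
class Bundle:
    """One phantom taken through the full measurement chain."""

    spec: PhantomSpec
    volume: ImageVolume
    mask: BinaryMask
    tree: CenterlineTree
    measurements: VesselMeasurements | None = None


def _chain(spec: PhantomSpec, seed_point: Point3D, margin: float | None = None) -> Bundle:
    volume, _ = rasterize_phantom(spec)
    mask = segment_vessel(volume, seed_point)
    tree = extract_tree(skeletonize(mask), CenterlineConfig(), mask=mask, seed=seed_point)
    meas = None
    if margin is not None:
        meas = measure_all(volume, mask, tree, MeasurementConfig(exclusion_margin=margin))
    return Bundle(spec, volume, mask, tree, meas)


@pytest.fixture(scope="session")
def cylinder() -> Bundle:
    spec = make_cylinder_spec(radius=CYL_RADIUS, length=CYL_LENGTH, spacing=(0.5, 0.5, 0.5))
    return _chain(spec, Point3D(0.0, 0.0, CYL_LENGTH / 2))


@pytest.fixture(scope="session")
def arc_tube() -> Bundle:
    spec = make_arc_tube_spec(
        radius=ARC_RADIUS, arc_radius=ARC_CURVE_RADIUS, arc_angle_deg=ARC_ANGLE, spacing=(0.5, 0.5, 0.5)
    )
    tube = spec.tubes["trunk"]
    return _chain(spec, Point3D.from_array(tube.curve.point(tube.curve.length / 2)))


def build_tree_bundle(scale: float = 1.0, noise_sd: float = 0.0, seed: int = 0) -> Bundle:
    spec = make_pa_tree_spec(
        trunk_radius=TREE["trunk_radius"] * scale,
        branch_radii=tuple(r * scale for r in TREE["branch_radii"]),
        trunk_length=TREE["trunk_length"] * scale,
        branch_lengths=tuple(L * scale for L in TREE["branch_lengths"]),
        spacing=(1.0, 1.0, 1.0),
        noise_sd=noise_sd,
        seed=seed,
    )
    seed_pt = Point3D.from_array(spec.tubes["trunk"].curve.point(TREE["trunk_length"] * scale / 2))
    return _chain(spec, seed_pt, margin=TREE_MARGIN * scale)


@pytest.fixture(scope="session")
def pa_tree() -> Bundle:
    return build_tree_bundle(1.0)


@pytest.fixture(scope="session")
def pa_tree_scaled() -> Bundle:
    return build_tree_bundle(1.2)


def truth_volume_over_extent(bundle: Bundle, artery: str) -> float:
    """Analytic tube volume over the arclength window actually profiled,
    found by projecting the measured extent endpoints onto the true curve."""
    from pamorph.morphometry import _BRANCH_OF

    name = _BRANCH_OF[artery]
    tube = {"MPA": "trunk", "RPA": "child_1", "LPA": "child_2"}[artery]
    s0, s1 = bundle.measurements.extents[artery]
    branch = bundle.tree.branches[name]
    curve = bundle.spec.tubes[tube].curve
    _, ta = curve.distance(branch.point_at(s0)[None, :])
    _, tb = curve.distance(branch.point_at(s1)[None, :])
    lo, hi = sorted([float(ta[0]), float(tb[0])])
    return bundle.spec.tubes[tube].volume(lo, hi)
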