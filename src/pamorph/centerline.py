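"""Centerline extraction from a vessel mask.

The mask is reduced to a one-voxel-wide skeleton by medialness-weighted
minimal-path tracing: the Euclidean distance transform provides a
centeredness field, geodesically farthest voxels mark the vessel tips, and
each tip is connected to the growing skeleton by the cheapest path where
cost falls off as one over the squared distance-to-boundary - so paths hug
the lumen center.  (Classic parallel 3D thinning is unreliable here: on fat,
bluntly-cut tubes it retracts ends by about one radius and can consume a
short fat trunk completely.)  The skeleton becomes a graph whose short leaf
twigs are pruned, the graph is split into branches at junctions, and every
branch is smoothed with a cubic smoothing spline and resampled at a uniform
control-point spacing along its arclength (1 mm by default, matching how
clinical centerline tools place control points).

Smoothing-factor semantics: the dimensionless factor f in [0, 1] scales the
spline's residual budget so that f = 0 interpolates the raw voxel path and
f -> 1 degenerates to the least-squares straight line.  Internally the
residual tolerance per point is ``smoothing_scale * tan(f * pi / 2)`` mm,
with ``smoothing_scale`` half a millimetre by default - the typical staircase
amplitude of voxel skeletons at millimetric grids.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import interpolate, ndimage

from .core_io import BinaryMask, Point3D

log = logging.getLogger(__name__)


class TopologyError(ValueError):
    """Mask or skeleton does not have the expected topology."""


class LengthError(ValueError):
    """Branch too short for the requested operation."""


@dataclass
class CenterlineConfig:
    smoothing_factor: float = 0.5
    control_spacing: float = 1.0  # mm between successive control points
    resample_resolution: float = 1.0  # mm spline evaluation step before resampling
    spur_length_min: float = 5.0  # mm; shorter leaf twigs are pruned
    smoothing_scale: float = 0.5  # mm residual scale behind the [0,1] factor
    extend_tips: bool = True  # extend free ends to the lumen surface

    def __post_init__(self) -> None:
        if not (0.0 <= self.smoothing_factor <= 1.0):
            raise ValueError("smoothing_factor must lie in [0, 1]")
        if self.control_spacing <= 0 or self.resample_resolution <= 0:
            raise ValueError("control_spacing and resample_resolution must be positive")


@dataclass
class Centerline:
    """Ordered control points with unit tangents and cumulative arclength."""

    points: np.ndarray  # (N, 3) world mm
    tangents: np.ndarray  # (N, 3) unit vectors
    arclengths: np.ndarray  # (N,) cumulative mm, starting at 0

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Point at arclength ``s``; extrapolates linearly along the end
        tangents beyond either end (used when a measurement site sits on the
        axis continuation inside a junction)."""
        if s < 0:
            return self.points[0] + s * self.tangents[0]
        if s > self.length:
            return self.points[-1] + (s - self.length) * self.tangents[-1]
        return np.array([np.interp(s, self.arclengths, self.points[:, d]) for d in range(3)])

    def tangent_at(self, s: float) -> np.ndarray:
        t = np.array([np.interp(s, self.arclengths, self.tangents[:, d]) for d in range(3)])
        n = np.linalg.norm(t)
        return t / n if n > 0 else t

    def reversed(self) -> "Centerline":
        return Centerline(
            self.points[::-1].copy(),
            -self.tangents[::-1].copy(),
            (self.arclengths[-1] - self.arclengths[::-1]).copy(),
        )

    def slice_from(self, s0: float) -> "Centerline":
        """Re-origin the centerline at arclength ``s0`` (dropping what lies
        before it); the new first point is interpolated exactly at ``s0``."""
        if s0 <= 0:
            return self
        if s0 >= self.length:
            raise LengthError(f"cannot slice at {s0:.1f} mm on a {self.length:.1f} mm branch")
        keep = self.arclengths > s0 + 1e-9
        p0 = self.point_at(s0)
        t0 = self.tangent_at(s0)
        pts = np.vstack([p0, self.points[keep]])
        tans = np.vstack([t0, self.tangents[keep]])
        s = np.concatenate([[s0], self.arclengths[keep]]) - s0
        return Centerline(pts, tans, s)


@dataclass
class CenterlineTree:
    """Named branches plus the trunk/children bifurcation point.

    The trunk is oriented to end at the bifurcation and children start at
    it: child arclength 0 sits at the bifurcation.  ``trunk_bif_s`` is the
    bifurcation's arclength on the trunk's axis - it can exceed the trunk
    branch length because thinning merges the child paths slightly proximal
    to the geometric bifurcation, which is recovered by extrapolation.
    """

    branches: dict = field(default_factory=dict)
    bifurcation: Point3D | None = None
    trunk_bif_s: float | None = None

    @property
    def trunk(self) -> Centerline | None:
        return self.branches.get("trunk")


# ---------------------------------------------------------------------------
# skeletonization


_NEIGHBOR_OFFSETS = np.array(
    [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
)


def _path_euclid_mm(path: list, spacing: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.diff(np.asarray(path, dtype=float), axis=0) * spacing[None, :]
    return float(np.linalg.norm(steps, axis=1).sum())


def _trim_end_cone(path: list, dvals: np.ndarray, spacing: np.ndarray) -> list:
    """Drop the leading voxels of a tip-first path that climb a blunt end
    cap.

    Near a flat tube end the medial surface is the 45-degree cone where the
    cap and the side wall are equidistant, so a traced path approaches the
    tip along that cone and the distance-to-boundary climbs at close to
    1 mm per mm of arclength.  Along the true axis (even of a tapering
    tube) it changes far more slowly, so voxels are trimmed while the local
    climb rate exceeds 0.5.  The trimmed millimetres are recovered later by
    tangent extension to the lumen surface."""
    if len(path) < 3:
        return path
    steps = np.linalg.norm(np.diff(np.asarray(path, dtype=float), axis=0) * spacing[None, :], axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    win = max(2.0 * float(np.max(spacing)), 1.5)
    i = 0
    while i < len(path) - 2:
        j = int(np.searchsorted(s, s[i] + win))
        if j >= len(path):
            break
        slope = (dvals[j] - dvals[i]) / max(s[j] - s[i], 1e-9)
        if slope < 0.5:
            break
        i += 1
    return path[i:]


def skeletonize(mask: BinaryMask, min_branch_mm: float = 5.0, max_branches: int = 8) -> nx.Graph:
    """Trace a one-voxel-wide skeleton graph through a single-component mask.

    Minimal-path tracing on the Euclidean distance transform: the first path
    connects the two geodesically farthest tips through the medial ridge
    (edge cost falls off as 1/(distance-to-boundary)^2, so paths run along
    the lumen center), then further tips are attached while they lie more
    than ``min_branch_mm`` from the skeleton.  Blunt-end cones are trimmed
    so that every retained voxel sits on the medial ridge; the lost end
    millimetres are recovered later by tangent extension to the surface.

    Nodes are voxel index triples with a world-coordinate attribute ``xyz``;
    edges connect 26-neighbors and carry their length in mm.
    """
    from skimage.graph import MCP_Geometric

    if mask.count() == 0:
        raise TopologyError("cannot skeletonize an empty mask")
    _, ncomp = ndimage.label(mask.voxels, structure=ndimage.generate_binary_structure(3, 3))
    if ncomp != 1:
        raise TopologyError(f"mask has {ncomp} connected components; expected exactly 1")

    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    dist = ndimage.distance_transform_edt(mask.voxels, sampling=spacing)
    eps = 0.5 * float(np.min(spacing))
    med_cost = np.where(mask.voxels, 1.0 / (dist + eps) ** 2, np.inf)
    euc_cost = np.where(mask.voxels, 1.0, np.inf)

    def farthest(sources):
        mcp = MCP_Geometric(euc_cost, sampling=tuple(spacing))
        costs, _ = mcp.find_costs(sources)
        finite = np.where(np.isfinite(costs) & mask.voxels, costs, -1.0)
        tip = np.unravel_index(int(np.argmax(finite)), finite.shape)
        return tuple(int(i) for i in tip), float(finite[tip])

    root = tuple(int(i) for i in np.unravel_index(int(np.argmax(dist)), dist.shape))
    t1, _ = farthest([root])

    skel: set = {t1}
    for it in range(max_branches):
        tip, reach = farthest(list(skel))
        if reach < min_branch_mm:
            break
        mcp = MCP_Geometric(med_cost, sampling=tuple(spacing))
        mcp.find_costs(list(skel))
        path = [tuple(int(i) for i in p) for p in mcp.traceback(tip)]
        if path[0] != tip:
            path = path[::-1]  # tip first, attach point last
        dvals = dist[tuple(np.asarray(path).T)]
        path = _trim_end_cone(path, dvals, spacing)
        if it == 0:
            # the initial attach point is itself a raw tip: trim that end too
            dvals = dist[tuple(np.asarray(path).T)]
            path = _trim_end_cone(path[::-1], dvals[::-1], spacing)[::-1]
            skel = set()
        if _path_euclid_mm(path, spacing) < min_branch_mm and skel:
            break
        skel.update(path)
        if not skel:  # degenerate blob: keep at least the seed tip
            skel = {t1}
            break
    if not skel:
        skel = {t1}

    g = nx.Graph(spacing=spacing, origin=origin)
    for node in skel:
        g.add_node(node, xyz=origin + np.asarray(node) * spacing)
    for node in skel:
        c = np.asarray(node)
        for off in _NEIGHBOR_OFFSETS:
            nb = tuple(int(v) for v in c + off)
            if nb in skel and nb > node:
                g.add_edge(node, nb, weight=float(np.linalg.norm(off * spacing)))
    return g


# ---------------------------------------------------------------------------
# tree extraction


def _leaf_paths(g: nx.Graph):
    """Yield (path, terminates_at_junction) for every leaf twig."""
    for leaf in [n for n in g.nodes if g.degree[n] == 1]:
        path = [leaf]
        prev = None
        cur = leaf
        while True:
            nxt = [n for n in g.neighbors(cur) if n != prev]
            if g.degree[cur] >= 3 or not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
            if g.degree[cur] >= 3:
                break
        yield path, g.degree[path[-1]] >= 3


def _path_length(g: nx.Graph, path) -> float:
    return sum(g.edges[a, b]["weight"] for a, b in zip(path, path[1:]))


def prune_spurs(g: nx.Graph, spur_length_min: float) -> nx.Graph:
    """Iteratively remove leaf twigs shorter than ``spur_length_min`` mm that
    terminate at a junction (a pure path is never pruned away)."""
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for path, at_junction in list(_leaf_paths(g)):
            if not at_junction:
                continue
            if _path_length(g, path) < spur_length_min:
                g.remove_nodes_from(path[:-1])
                changed = True
    return g


def _junction_clusters(g: nx.Graph):
    junc = [n for n in g.nodes if g.degree[n] >= 3]
    sub = g.subgraph(junc)
    return [set(c) for c in nx.connected_components(sub)]


def _raw_branches(g: nx.Graph):
    """Split the pruned skeleton into raw voxel paths between endpoints and
    junction clusters.  Each path includes its terminal junction node(s)."""
    clusters = _junction_clusters(g)
    cluster_of = {}
    for ci, c in enumerate(clusters):
        for n in c:
            cluster_of[n] = ci
    interior = g.subgraph([n for n in g.nodes if n not in cluster_of])
    branches = []
    seen_pairs = set()
    for comp in nx.connected_components(interior):
        sub = g.subgraph(comp)
        ends = [n for n in comp if sub.degree[n] <= 1]
        if len(comp) == 1:
            path = list(comp)
        else:
            if len(ends) < 2:  # small loop artifact: take the weighted diameter path
                a = next(iter(comp))
                dist = nx.single_source_dijkstra_path_length(sub, a)
                a = max(dist, key=dist.get)
                dist, paths = nx.single_source_dijkstra(sub, a)
                b = max(dist, key=dist.get)
                path = paths[b]
            else:
                dist, paths = nx.single_source_dijkstra(sub, ends[0])
                far = max(((n, dist.get(n, -1)) for n in ends[1:]), key=lambda t: t[1])[0]
                path = paths[far]
        # attach adjoining junction nodes
        first_j = [n for n in g.neighbors(path[0]) if n in cluster_of]
        last_j = [n for n in g.neighbors(path[-1]) if n in cluster_of]
        if first_j:
            path = [first_j[0]] + path
        if last_j and (len(path) < 2 or last_j[0] != path[0]):
            path = path + [last_j[0]]
        key = (path[0], path[-1])
        if key in seen_pairs or (key[1], key[0]) in seen_pairs:
            # keep only the longest of parallel paths between the same pair
            continue
        seen_pairs.add(key)
        branches.append(path)
    return branches, clusters, cluster_of


def _sample_mask(mask: BinaryMask, pts: np.ndarray) -> np.ndarray:
    cont = (np.atleast_2d(pts) - mask.origin[None, :]) / mask.spacing[None, :]
    return ndimage.map_coordinates(
        mask.voxels.astype(np.float32), cont.T, order=1, mode="constant", cval=0.0
    )


def _recenter_path(path_xyz: np.ndarray, mask: BinaryMask, edt: np.ndarray) -> np.ndarray:
    """Move each path point to the centroid of its local cross-section.

    The traced path sits on the medial structure but can ride off-axis near
    blunt ends.  For each point the mask is sampled on the plane orthogonal
    to the local path direction within a window of ~1.3 local radii; the
    point moves to the centroid of the in-plane connected lumen region
    containing it, which for a tubular lumen is the center by definition.
    Junction regions are unaffected: there the window is filled and its
    centroid coincides with the point.
    """
    pts = np.asarray(path_xyz, dtype=float)
    if len(pts) < 3:
        return pts
    spacing = np.asarray(mask.spacing)
    h = float(np.min(spacing))
    cont = (pts - mask.origin[None, :]) / spacing[None, :]
    dvals = ndimage.map_coordinates(edt, cont.T, order=1, mode="nearest")
    out = pts.copy()
    maskf = mask.voxels.astype(np.float32)
    for i in range(len(pts)):
        j0, j1 = max(0, i - 2), min(len(pts) - 1, i + 2)
        tan = pts[j1] - pts[j0]
        n = np.linalg.norm(tan)
        if n == 0:
            continue
        tan /= n
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(tan)))] = 1.0
        u = np.cross(tan, helper)
        u /= np.linalg.norm(u)
        v = np.cross(tan, u)
        radius = 1.3 * float(dvals[i]) + 2.0 * h
        t = np.arange(-radius, radius + h / 4, h / 2)
        uu, vv = np.meshgrid(t, t, indexing="ij")
        plane = pts[i][None, :] + uu.reshape(-1, 1) * u[None, :] + vv.reshape(-1, 1) * v[None, :]
        cplane = (plane - mask.origin[None, :]) / spacing[None, :]
        vals = ndimage.map_coordinates(maskf, cplane.T, order=1, mode="constant", cval=0.0).reshape(
            len(t), len(t)
        )
        c = len(t) // 2
        if vals[c, c] < 0.5:
            continue
        labels, _ = ndimage.label(vals >= 0.5, structure=np.ones((3, 3), bool))
        region = labels == labels[c, c]
        out[i] = pts[i] + float(uu[region].mean()) * u + float(vv[region].mean()) * v
    return out


def _extend_tip(path_xyz: np.ndarray, mask: BinaryMask, max_extend: float = 40.0) -> np.ndarray:
    """Extend the end of a world-coordinate path along its end direction until
    the interpolated mask drops below 0.5 (the lumen surface)."""
    n_back = min(len(path_xyz) - 1, 6)
    if n_back < 1:
        return path_xyz
    d = path_xyz[-1] - path_xyz[-1 - n_back]
    nd = np.linalg.norm(d)
    if nd == 0:
        return path_xyz
    d = d / nd
    step = float(min(mask.spacing)) / 2.0
    ts = np.arange(step, max_extend, step)
    probes = path_xyz[-1][None, :] + ts[:, None] * d[None, :]
    vals = _sample_mask(mask, probes)
    outside = np.nonzero(vals < 0.5)[0]
    n_keep = outside[0] if outside.size else len(ts)
    if n_keep == 0:
        return path_xyz
    return np.vstack([path_xyz, probes[:n_keep]])


def extract_tree(
    skeleton: nx.Graph,
    config: CenterlineConfig | None = None,
    mask: BinaryMask | None = None,
    seed: Point3D | None = None,
) -> CenterlineTree:
    """Prune spurs, decompose the skeleton into branches, name the trunk and
    the two principal children, and smooth/resample every branch.

    The trunk is the branch containing the seed point when one is given,
    otherwise the longest branch.  When the skeleton has no junction the
    result is a single-branch tree with no bifurcation.  Children are named
    ``child_1``/``child_2`` by ascending mean x (in LPS the right pulmonary
    artery has the smaller x).
    """
    config = config or CenterlineConfig()
    if skeleton.number_of_nodes() == 0:
        raise TopologyError("empty skeleton")
    g = prune_spurs(skeleton, config.spur_length_min)
    spacing = np.asarray(g.graph.get("spacing", np.ones(3)))
    branches, clusters, cluster_of = _raw_branches(g)
    if not branches:  # degenerate blob: a single (possibly tiny) cluster
        xyz = np.array([g.nodes[n]["xyz"] for n in g.nodes])
        c = xyz.mean(axis=0)
        line = Centerline(np.array([c, c + [0, 0, 1e-6]]), np.tile([0.0, 0, 1.0], (2, 1)), np.array([0.0, 1e-6]))
        return CenterlineTree({"trunk": line}, None)

    paths_xyz = [np.array([g.nodes[n]["xyz"] for n in p]) for p in branches]
    edt = None
    if mask is not None:
        edt = ndimage.distance_transform_edt(mask.voxels, sampling=np.asarray(mask.spacing))
        paths_xyz = [_recenter_path(p, mask, edt) for p in paths_xyz]
    lengths = [_path_length(g, p) for p in branches]

    if seed is not None:
        seed_arr = seed.as_array()
        dists = [np.linalg.norm(p - seed_arr, axis=1).min() for p in paths_xyz]
        trunk_i = int(np.argmin(dists))
    else:
        trunk_i = int(np.argmax(lengths))

    # junction cluster adjoining the trunk -> bifurcation
    trunk_path = branches[trunk_i]
    trunk_clusters = [cluster_of[n] for n in (trunk_path[0], trunk_path[-1]) if n in cluster_of]
    tree = CenterlineTree()
    if not trunk_clusters:
        raw = paths_xyz[trunk_i]
        if mask is not None and config.extend_tips:
            raw = _extend_tip(raw, mask)
            raw = _extend_tip(raw[::-1], mask)[::-1]
        tree.branches["trunk"] = smooth_resample(raw, config)
        tree.trunk_bif_s = tree.branches["trunk"].length
        return tree

    ci = trunk_clusters[0]
    cluster_nodes = clusters[ci]
    bif_xyz = np.mean([g.nodes[n]["xyz"] for n in cluster_nodes], axis=0)
    # orient trunk to end at the bifurcation
    raw_trunk = paths_xyz[trunk_i]
    if branches[trunk_i][0] in cluster_nodes:
        raw_trunk = raw_trunk[::-1]
    children = [
        i
        for i in range(len(branches))
        if i != trunk_i and (branches[i][0] in cluster_nodes or branches[i][-1] in cluster_nodes)
    ]
    children.sort(key=lambda i: -lengths[i])
    principal = children[:2]
    # deterministic naming: ascending mean x
    principal.sort(key=lambda i: float(paths_xyz[i][:, 0].mean()))

    if mask is not None and config.extend_tips:
        raw_trunk = _extend_tip(raw_trunk[::-1], mask)[::-1]
    tree.branches["trunk"] = smooth_resample(raw_trunk, config)
    tree.bifurcation = Point3D.from_array(bif_xyz)
    for rank, i in enumerate(principal, start=1):
        raw = paths_xyz[i]
        if branches[i][-1] in cluster_nodes:
            raw = raw[::-1]  # children start at the bifurcation
        if mask is not None and config.extend_tips:
            raw = _extend_tip(raw, mask)
        tree.branches[f"child_{rank}"] = smooth_resample(raw, config)
    extra = [i for i in children if i not in principal]
    for rank, i in enumerate(extra, start=1):
        tree.branches[f"extra_{rank}"] = smooth_resample(paths_xyz[i], config)
    _refine_bifurcation(tree, bif_xyz, mask, edt)
    log.info(
        "centerline tree: %s",
        {k: f"{v.length:.1f} mm" for k, v in tree.branches.items()},
    )
    return tree


# ---------------------------------------------------------------------------
# bifurcation refinement


def _points_at(cl: Centerline, s_grid: np.ndarray) -> np.ndarray:
    return np.stack([np.interp(s_grid, cl.arclengths, cl.points[:, d]) for d in range(3)], axis=1)


def _fit_line_window(cl: Centerline, s_lo: float, s_hi: float):
    sel = (cl.arclengths >= s_lo) & (cl.arclengths <= s_hi)
    pts = cl.points[sel]
    if len(pts) < 3:
        return None
    c = pts.mean(axis=0)
    _, sv, vt = np.linalg.svd(pts - c)
    return c, vt[0]


def _least_squares_intersection(lines):
    """Point minimizing the summed squared distance to a set of 3D lines."""
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for c, d in lines:
        P = np.eye(3) - np.outer(d, d)
        A += P
        b += P @ c
    if np.linalg.cond(A) > 1e8:
        return None
    return np.linalg.solve(A, b)


def _refine_bifurcation(
    tree: CenterlineTree, b0: np.ndarray, mask: BinaryMask | None, edt: np.ndarray | None = None
) -> None:
    """Replace the raw skeleton-junction bifurcation estimate by the
    least-squares intersection of the branch axes fitted outside the
    junction-contaminated zone.

    Thinning a union of fat tubes merges the child skeleton paths roughly one
    inscribed radius proximal to the geometric branch point, so the raw
    junction node is biased.  The inscribed radius at the junction (from the
    Euclidean distance transform) sizes the exclusion window; each branch
    axis is fitted just beyond it and the axes are intersected.  Children are
    then re-originated so arclength 0 sits at the refined bifurcation, and
    the trunk records the (possibly extrapolated) bifurcation arclength.
    """
    trunk = tree.branches.get("trunk")
    children = [k for k in ("child_1", "child_2") if k in tree.branches]
    if trunk is not None and tree.trunk_bif_s is None:
        tree.trunk_bif_s = trunk.length
    if mask is None or trunk is None or len(children) < 2:
        return
    idx = np.clip(
        np.rint((b0 - mask.origin) / mask.spacing).astype(int), 0, np.asarray(mask.shape) - 1
    )
    if edt is None:
        edt = ndimage.distance_transform_edt(mask.voxels, sampling=np.asarray(mask.spacing))
    rj = max(float(edt[tuple(idx)]), float(np.max(mask.spacing)))

    lines = []
    t_line = _fit_line_window(trunk, trunk.length - rj - 20.0, trunk.length - rj)
    if t_line is not None:
        lines.append(t_line)
    for name in children:
        ch = tree.branches[name]
        w0 = 1.2 * rj
        ln = _fit_line_window(ch, w0, w0 + max(12.0, rj))
        if ln is not None:
            lines.append(ln)
    if len(lines) < 2:
        return
    refined = _least_squares_intersection(lines)
    if refined is None or np.linalg.norm(refined - b0) > 2.5 * rj:
        log.warning("bifurcation refinement rejected (moved too far); keeping the junction centroid")
        return
    tree.bifurcation = Point3D.from_array(refined)

    for name in children:
        ch = tree.branches[name]
        s_grid = np.arange(0.0, min(ch.length, 3.0 * rj + 5.0), 0.25)
        if len(s_grid) < 2:
            continue
        d = np.linalg.norm(_points_at(ch, s_grid) - refined[None, :], axis=1)
        s_j = float(s_grid[int(np.argmin(d))])
        # re-origin at the projection of the bifurcation: arclength 0 is the
        # point of the child's path closest to the bifurcation, so offsets
        # "x mm distal to the bifurcation" are measured along the vessel and
        # not through the lateral projection gap
        if 0.0 < s_j < ch.length - 1.0:
            ch = ch.slice_from(s_j)
        tree.branches[name] = ch

    s_grid = np.arange(max(0.0, trunk.length - 3.0 * rj - 5.0), trunk.length + 1e-9, 0.25)
    d = np.linalg.norm(_points_at(trunk, s_grid) - refined[None, :], axis=1)
    s_p = float(s_grid[int(np.argmin(d))])
    if s_p >= trunk.length - 0.5:
        overshoot = float(np.dot(refined - trunk.points[-1], trunk.tangents[-1]))
        tree.trunk_bif_s = trunk.length + max(0.0, overshoot)
    else:
        tree.trunk_bif_s = s_p


# ---------------------------------------------------------------------------
# smoothing and resampling


def _dedupe(pts: np.ndarray) -> np.ndarray:
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    return pts[keep]


def smooth_resample(path: np.ndarray, config: CenterlineConfig | None = None) -> Centerline:
    """Fit a smoothing cubic spline to a raw voxel path and resample it at a
    uniform arclength spacing.

    Factor 0 interpolates; factor 1 projects onto the least-squares straight
    line; in between the allowed RMS residual grows as
    ``smoothing_scale * tan(f * pi/2)``.
    """
    config = config or CenterlineConfig()
    pts = _dedupe(np.atleast_2d(np.asarray(path, dtype=float)))
    if len(pts) < 2:
        raise LengthError("path needs at least two distinct points")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if chord[-1] < 2.0 * config.control_spacing:
        raise LengthError(
            f"path length {chord[-1]:.2f} mm is shorter than twice the control spacing"
        )
    f = config.smoothing_factor
    if f >= 1.0:
        dense = _project_line(pts, chord)
    else:
        if f <= 0.0 or len(pts) <= 3:
            k = min(3, len(pts) - 1)
            s_val = 0.0
        else:
            k = 3
            tol = config.smoothing_scale * math.tan(f * math.pi / 2.0)
            s_val = len(pts) * tol * tol
        tck, _ = interpolate.splprep(pts.T, u=chord, s=s_val, k=k)
        n_eval = max(int(math.ceil(chord[-1] / config.resample_resolution)) + 1, len(pts), 2)
        ue = np.linspace(0.0, chord[-1], n_eval)
        dense = np.stack(interpolate.splev(ue, tck), axis=1)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_dense[-1]
    n_ctrl = max(2, int(round(total / config.control_spacing)) + 1)
    s_ctrl = np.linspace(0.0, total, n_ctrl)
    ctrl = np.stack([np.interp(s_ctrl, s_dense, dense[:, d]) for d in range(3)], axis=1)
    # tangents from central differences on the dense curve
    grad = np.gradient(dense, s_dense, axis=0)
    tans = np.stack([np.interp(s_ctrl, s_dense, grad[:, d]) for d in range(3)], axis=1)
    norms = np.linalg.norm(tans, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tans = tans / norms
    return Centerline(ctrl, tans, s_ctrl)


def _project_line(pts: np.ndarray, chord: np.ndarray) -> np.ndarray:
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center)
    direction = vt[0]
    t = (pts - center) @ direction
    if t[-1] < t[0]:
        direction = -direction
        t = -t
    return center + np.linspace(t.min(), t.max(), max(len(pts), 2))[:, None] * direction[None, :]


def total_turning_angle(points: np.ndarray) -> float:
    """Sum of discrete turning angles (radians) along a polyline - a simple
    curvature budget used to verify that smoothing straightens, never bends."""
    d = np.diff(np.asarray(points, dtype=float), axis=0)
    d = d[np.linalg.norm(d, axis=1) > 1e-12]
    if len(d) < 2:
        return 0.0
    u = d / np.linalg.norm(d, axis=1, keepdims=True)
    cosang = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    return float(np.arccos(cosang).sum())
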