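"""Parametric 3D curves with closed-form arclength, tangents and distances.

These back the vessel phantoms: a tube is a curve plus a radius profile, and
because segments and circular arcs have exact arclength parameterizations the
phantom's centerline, area profile and volume are all analytic.
"""

from __future__ import annotations

import numpy as np


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


class Segment:
    """Straight segment from ``start`` to ``end``, parameterized by arclength."""

    def __init__(self, start, end):
        self.start = np.asarray(start, dtype=float)
        self.end = np.asarray(end, dtype=float)
        d = self.end - self.start
        self.length = float(np.linalg.norm(d))
        if self.length <= 0:
            raise ValueError("segment must have positive length")
        self._dir = d / self.length

    def point(self, s):
        s = np.asarray(s, dtype=float)
        return self.start + np.multiply.outer(s, self._dir)

    def tangent(self, s):
        s = np.asarray(s, dtype=float)
        return np.broadcast_to(self._dir, s.shape + (3,)).copy()

    def distance(self, pts):
        """Distance from (N, 3) points to the segment and the closest arclength."""
        pts = np.atleast_2d(pts)
        t = (pts - self.start) @ self._dir
        t = np.clip(t, 0.0, self.length)
        closest = self.start + t[:, None] * self._dir
        return np.linalg.norm(pts - closest, axis=1), t

    def _frame(self, pts):
        pts = np.atleast_2d(pts)
        t = (pts - self.start) @ self._dir  # unclamped axial coordinate
        radial = np.linalg.norm(pts - self.start - t[:, None] * self._dir, axis=1)
        return radial, t

    def tube_inside(self, pts, radius_fn):
        """Flat-capped tube membership: perpendicular foot on the segment and
        radial distance below the local radius."""
        radial, t = self._frame(pts)
        ok = (t >= 0.0) & (t <= self.length)
        return ok & (radial < radius_fn(np.clip(t, 0.0, self.length)))

    def tube_core(self, pts, radius_fn, band):
        """Points at least ``band`` inside the tube in every direction."""
        radial, t = self._frame(pts)
        ok = (t >= band) & (t <= self.length - band)
        return ok & (radial <= radius_fn(np.clip(t, 0.0, self.length)) - band)


class Arc:
    """Circular arc given by start point, unit start tangent, in-plane normal
    toward the center of curvature, radius of curvature, and turned angle
    (radians).  Arclength runs from 0 to ``radius * angle``."""

    def __init__(self, start, tangent0, normal0, radius, angle):
        if radius <= 0 or angle <= 0:
            raise ValueError("arc radius and angle must be positive")
        self.start = np.asarray(start, dtype=float)
        self.t0 = _unit(tangent0)
        n0 = np.asarray(normal0, dtype=float)
        n0 = n0 - (n0 @ self.t0) * self.t0  # enforce orthogonality
        self.n0 = _unit(n0)
        self.radius = float(radius)
        self.angle = float(angle)
        self.length = self.radius * self.angle
        self.center = self.start + self.radius * self.n0
        self._binormal = np.cross(self.t0, self.n0)

    def point(self, s):
        phi = np.asarray(s, dtype=float) / self.radius
        return (
            self.start
            + np.multiply.outer(self.radius * np.sin(phi), self.t0)
            + np.multiply.outer(self.radius * (1.0 - np.cos(phi)), self.n0)
        )

    def tangent(self, s):
        phi = np.asarray(s, dtype=float) / self.radius
        return np.multiply.outer(np.cos(phi), self.t0) + np.multiply.outer(np.sin(phi), self.n0)

    def distance(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        rel = pts - self.center
        h = rel @ self._binormal  # out-of-plane offset
        in_plane = rel - h[:, None] * self._binormal
        # angle of the in-plane component measured from the start direction
        u = -self.n0  # center -> start
        v = self.t0
        a = in_plane @ u
        b = in_plane @ v
        phi = np.arctan2(b, a)  # in (-pi, pi], 0 at the start point
        on_arc = (phi >= 0) & (phi <= self.angle)
        rho = np.hypot(a, b)
        d_arc = np.sqrt((rho - self.radius) ** 2 + h**2)
        d_start = np.linalg.norm(pts - self.start, axis=1)
        endp = self.point(self.length)
        d_end = np.linalg.norm(pts - endp, axis=1)
        d_ends = np.minimum(d_start, d_end)
        s_ends = np.where(d_start <= d_end, 0.0, self.length)
        dist = np.where(on_arc, d_arc, d_ends)
        s = np.where(on_arc, np.clip(phi, 0, self.angle) * self.radius, s_ends)
        return dist, s

    def _frame(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        rel = pts - self.center
        h = rel @ self._binormal
        in_plane = rel - h[:, None] * self._binormal
        a = in_plane @ (-self.n0)
        b = in_plane @ self.t0
        phi = np.arctan2(b, a)
        rho = np.hypot(a, b)
        radial = np.sqrt((rho - self.radius) ** 2 + h**2)
        return radial, phi

    def tube_inside(self, pts, radius_fn):
        """Flat-capped membership: angular coordinate within the arc and
        distance to the arc below the local radius."""
        radial, phi = self._frame(pts)
        ok = (phi >= 0.0) & (phi <= self.angle)
        s = np.clip(phi, 0.0, self.angle) * self.radius
        return ok & (radial < radius_fn(s))

    def tube_core(self, pts, radius_fn, band):
        radial, phi = self._frame(pts)
        dphi = band / self.radius
        ok = (phi >= dphi) & (phi <= self.angle - dphi)
        s = np.clip(phi, 0.0, self.angle) * self.radius
        return ok & (radial <= radius_fn(s) - band)


class Polyline:
    """Piecewise-linear curve through the given points."""

    def __init__(self, points):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError("polyline needs an (N>=2, 3) point array")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps <= 0):
            raise ValueError("polyline points must be distinct consecutive")
        self.points = pts
        self._cum = np.concatenate([[0.0], np.cumsum(steps)])
        self.length = float(self._cum[-1])
        self._segments = [Segment(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]

    def point(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty((len(s), 3))
        for d in range(3):
            out[:, d] = np.interp(s, self._cum, self.points[:, d])
        return out if out.shape[0] > 1 else out[0]

    def tangent(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        idx = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0, len(self._segments) - 1)
        out = np.stack([self._segments[i]._dir for i in idx])
        return out if out.shape[0] > 1 else out[0]

    def distance(self, pts):
        pts = np.atleast_2d(pts)
        best_d = np.full(len(pts), np.inf)
        best_s = np.zeros(len(pts))
        for seg, s0 in zip(self._segments, self._cum[:-1]):
            d, t = seg.distance(pts)
            better = d < best_d
            best_d = np.where(better, d, best_d)
            best_s = np.where(better, s0 + t, best_s)
        return best_d, best_s

    def tube_inside(self, pts, radius_fn):
        """Union of flat-capped segments plus balls at the interior joints
        (so the tube is watertight at bends but flat at its two ends)."""
        pts = np.atleast_2d(pts)
        inside = np.zeros(len(pts), dtype=bool)
        for seg, s0 in zip(self._segments, self._cum[:-1]):
            inside |= seg.tube_inside(pts, lambda s: radius_fn(s0 + s))
        for joint, sj in zip(self.points[1:-1], self._cum[1:-1]):
            inside |= np.linalg.norm(pts - joint, axis=1) < radius_fn(sj)
        return inside

    def tube_core(self, pts, radius_fn, band):
        d, s = self.distance(pts)
        radial, t0 = self._segments[0]._frame(pts)
        _, tN = self._segments[-1]._frame(pts)
        ok = (t0 >= band) & (tN <= self._segments[-1].length - band)
        return ok & (d <= radius_fn(s) - band)
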