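"""Exact leaf solids: spheres, tetrahedra and spindles.

Every solid — leaf primitive or CSG node — answers the same three
questions:

* ``contains(points)``: exact inside/outside classification, with points
  exactly on the surface counted as inside;
* ``intersect_segment(segment)``: the closed parameter intervals on which
  the segment lies inside the solid;
* ``starting_cubes(lattice)``: a few lattice cubes straddling the surface
  (at least one corner inside, one outside), used to seed the surface
  floodfill.

All coordinates are in Angstroms.  ``contains`` is vectorized over an
(n, 3) array of points; this is what keeps lattice classification fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import EPS_TANGENT, IntervalSet

#: Absolute boundary tolerance for containment comparisons, in Angstroms.
ABS_TOL = 1e-12

#: Realness threshold for companion-matrix eigenvalues: eigensolvers
#: perturb real roots into conjugate pairs near tangency.
EIG_IMAG_TOL = 1e-8


class Segment:
    """Directed segment ``point(t) = origin + t * direction`` for t in [0, t_max]."""

    __slots__ = ("origin", "direction", "t_max")

    def __init__(self, origin, direction, t_max: float = 1.0):
        self.origin = np.asarray(origin, dtype=float)
        self.direction = np.asarray(direction, dtype=float)
        if not np.all(np.isfinite(self.origin)) or not np.all(np.isfinite(self.direction)):
            raise ValueError("segment with non-finite components")
        if float(np.dot(self.direction, self.direction)) == 0.0:
            raise ValueError("segment direction has zero norm")
        self.t_max = float(t_max)

    @classmethod
    def between(cls, p0, p1) -> "Segment":
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        return cls(p0, p1 - p0, 1.0)

    def point(self, t):
        t = np.asarray(t, dtype=float)
        return self.origin + np.multiply.outer(t, self.direction)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.direction) * self.t_max)

    def __repr__(self):
        return f"Segment({self.origin}, {self.direction}, t_max={self.t_max})"


class Solid:
    """Base contract shared by all leaf primitives and CSG nodes."""

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean inside/outside classification for an (n, 3) point array."""
        raise NotImplementedError

    def contains_point(self, p) -> bool:
        return bool(self.contains(np.asarray(p, dtype=float)[None, :])[0])

    def intersect_segment(self, seg: Segment) -> IntervalSet:
        raise NotImplementedError

    def starting_cubes(self, lattice) -> set:
        raise NotImplementedError

    def bounds(self) -> tuple:
        """Axis-aligned bounding box as (lo, hi) arrays."""
        raise NotImplementedError

    def leaves(self):
        yield self


def is_surface_cube(solid: Solid, lattice, idx) -> bool:
    """Mixed-corner test: cube has >= 1 corner inside and >= 1 outside."""
    inside = solid.contains(lattice.cube_corners(idx))
    return bool(inside.any() and not inside.all())


def _widen_degenerate(pairs):
    """Give tangency intervals the canonical 2 * EPS_TANGENT width."""
    out = []
    for lo, hi in pairs:
        if hi - lo < 2 * EPS_TANGENT:
            mid = 0.5 * (lo + hi)
            out.append((mid - EPS_TANGENT, mid + EPS_TANGENT))
        else:
            out.append((lo, hi))
    return out


def intervals_from_boundaries(solid: Solid, seg: Segment, ts) -> IntervalSet:
    """Assemble inside-intervals from candidate boundary parameters.

    ``ts`` are candidate crossings on the segment; the interval states are
    fixed by classifying the midpoint of every gap with ``solid.contains``,
    so the result is consistent with point containment by construction.
    """
    ts = np.asarray(ts, dtype=float)
    ts = ts[(ts > -ABS_TOL) & (ts < seg.t_max + ABS_TOL)]
    cuts = np.unique(np.concatenate([[0.0, seg.t_max], np.clip(ts, 0.0, seg.t_max)]))
    mids = 0.5 * (cuts[:-1] + cuts[1:])
    if mids.size == 0:
        mids = np.array([0.5 * seg.t_max])
        cuts = np.array([0.0, seg.t_max])
    inside = solid.contains(seg.point(mids))
    pairs = []
    for k, isin in enumerate(inside):
        if not isin:
            continue
        if pairs and abs(pairs[-1][1] - cuts[k]) < EPS_TANGENT:
            pairs[-1] = (pairs[-1][0], cuts[k + 1])
        else:
            pairs.append((cuts[k], cuts[k + 1]))
    return IntervalSet(_widen_degenerate(pairs))


# ---------------------------------------------------------------------------
# Sphere


@dataclass(frozen=True, eq=False)
class Sphere(Solid):
    """Ball defined by center and radius.

    ``is_negative`` marks negspheres: probe-sized spheres that carve
    solvent space out of a molecular solid.  As a standalone geometric
    solid a negsphere behaves like any other ball; the sign is applied by
    the molecular-solid assembly.
    """

    center: np.ndarray
    radius: float
    is_negative: bool = False

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - self.center
        return np.einsum("ij,ij->i", d, d) <= (self.radius + ABS_TOL) ** 2

    def intersect_segment(self, seg: Segment) -> IntervalSet:
        # line-sphere reduces to a quadratic in t
        oc = seg.origin - self.center
        a = float(np.dot(seg.direction, seg.direction))
        b = 2.0 * float(np.dot(seg.direction, oc))
        c = float(np.dot(oc, oc)) - self.radius**2
        disc = b * b - 4.0 * a * c
        scale = max(b * b, abs(4.0 * a * c), 1.0)
        if disc < -1e-14 * scale:
            return IntervalSet.empty()
        if disc <= 1e-14 * scale:
            # tangency: two artificial intersection points at a trivial
            # separation keep the interval topology consistent
            t0 = -b / (2.0 * a)
            if t0 < -EPS_TANGENT or t0 > seg.t_max + EPS_TANGENT:
                return IntervalSet.empty()
            return IntervalSet([(t0 - EPS_TANGENT, t0 + EPS_TANGENT)]).clip(
                -EPS_TANGENT, seg.t_max + EPS_TANGENT
            )
        sq = np.sqrt(disc)
        t1 = (-b - sq) / (2.0 * a)
        t2 = (-b + sq) / (2.0 * a)
        if t2 < 0.0 or t1 > seg.t_max:
            return IntervalSet.empty()
        return IntervalSet([(max(t1, 0.0), min(t2, seg.t_max))])

    def starting_cubes(self, lattice) -> set:
        found = set()
        start = lattice.cube_of_point(self.center)
        if start is None:
            return found
        for axis in range(3):
            for step in (-1, 1):
                idx = np.array(start)
                while lattice.in_bounds(idx):
                    if is_surface_cube(self, lattice, tuple(idx)):
                        found.add(tuple(int(v) for v in idx))
                        break
                    # stop once the cube lies entirely beyond the sphere
                    lo = lattice.origin + idx * lattice.resolution
                    if lo[axis] - self.center[axis] > self.radius + lattice.resolution:
                        break
                    if self.center[axis] - (lo[axis] + lattice.resolution) > self.radius + lattice.resolution:
                        break
                    idx[axis] += step
        return found

    def bounds(self):
        r = self.radius
        return self.center - r, self.center + r


# ---------------------------------------------------------------------------
# Tetrahedron


class Tetrahedron(Solid):
    """Solid tetrahedron given by its four corners.

    Containment is the intersection of the four closed half-spaces whose
    boundary planes carry the faces, so a point on a face, edge or corner
    is inside.
    """

    def __init__(self, corners, allow_degenerate: bool = False):
        self.corners = np.asarray(corners, dtype=float).reshape(4, 3)
        a, b, c, d = self.corners
        vol6 = float(np.dot(np.cross(b - a, c - a), d - a))
        if abs(vol6) < 1e-14 and not allow_degenerate:
            raise ValueError("degenerate tetrahedron (zero signed volume)")
        self.signed_volume = vol6 / 6.0
        # inward-pointing unit normals, one per face (face i is opposite corner i)
        opposite = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
        normals, offsets = [], []
        for i, (p, q, r) in enumerate(opposite):
            n = np.cross(self.corners[q] - self.corners[p], self.corners[r] - self.corners[p])
            norm = np.linalg.norm(n)
            if norm > 0:
                n = n / norm
            if np.dot(n, self.corners[i] - self.corners[p]) < 0:
                n = -n
            normals.append(n)
            offsets.append(np.dot(n, self.corners[p]))
        self._normals = np.array(normals)
        self._offsets = np.array(offsets)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        s = pts @ self._normals.T - self._offsets
        return np.all(s >= -ABS_TOL, axis=1)

    def intersect_segment(self, seg: Segment) -> IntervalSet:
        # clip [0, t_max] against the four inward half-spaces
        lo, hi = 0.0, seg.t_max
        for n, off in zip(self._normals, self._offsets):
            denom = float(np.dot(n, seg.direction))
            num = off - float(np.dot(n, seg.origin))
            if abs(denom) < 1e-15:
                if num > ABS_TOL:  # segment parallel and strictly outside
                    return IntervalSet.empty()
                continue
            t = num / denom
            if denom > 0:
                lo = max(lo, t)
            else:
                hi = min(hi, t)
            if lo > hi + EPS_TANGENT:
                return IntervalSet.empty()
        if lo > hi:
            return IntervalSet.empty()
        return IntervalSet(_widen_degenerate([(lo, hi)]))

    def starting_cubes(self, lattice) -> set:
        found = set()
        face_centers = [
            self.corners[[1, 2, 3]].mean(axis=0),
            self.corners[[0, 2, 3]].mean(axis=0),
            self.corners[[0, 1, 3]].mean(axis=0),
            self.corners[[0, 1, 2]].mean(axis=0),
        ]
        for corner, target in zip(self.corners, face_centers):
            # walk cube-to-cube from the corner toward the opposite face center
            for idx in lattice.walk_cubes(corner, target):
                if is_surface_cube(self, lattice, idx):
                    found.add(idx)
                    break
        return found

    def bounds(self):
        return self.corners.min(axis=0), self.corners.max(axis=0)


# ---------------------------------------------------------------------------
# Spindle


def torus_implicit(R: float, r: float, points: np.ndarray) -> np.ndarray:
    """Implicit value of the x-axis-aligned torus at canonical-frame points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    s = np.einsum("ij,ij->i", pts, pts)
    yz = pts[:, 1] ** 2 + pts[:, 2] ** 2
    return (s + R * R - r * r) ** 2 - 4.0 * R * R * yz


def solve_torus_quartic(R: float, r: float, origin, direction) -> np.ndarray:
    """Real intersection parameters of a line with the canonical torus.

    The torus (axis = x) satisfies
    ``(x^2 + y^2 + z^2 + R^2 - r^2)^2 - 4 R^2 (y^2 + z^2) = 0``.
    Substituting the parametrized line gives a quartic in t; its roots are
    recovered as the eigenvalues of the 4x4 Frobenius companion matrix of
    the monic quartic.  Eigenvalues with significant imaginary part
    correspond to nonexistent intersections and are discarded.  Returned
    roots are sorted ascending.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    A = float(np.dot(d, d))
    B = 2.0 * float(np.dot(o, d))
    C = float(np.dot(o, o)) + R * R - r * r
    # (A t^2 + B t + C)^2 - 4 R^2 (a2 t^2 + b1 t + c0), descending powers
    a2 = d[1] * d[1] + d[2] * d[2]
    b1 = 2.0 * (o[1] * d[1] + o[2] * d[2])
    c0 = o[1] * o[1] + o[2] * o[2]
    poly = np.convolve([A, B, C], [A, B, C]).astype(float)
    poly -= 4.0 * R * R * np.array([0.0, 0.0, a2, b1, c0])
    lead = poly[0]
    if abs(lead) < 1e-300:
        # degenerate quartic; solve whatever degree is left
        nz = np.nonzero(np.abs(poly) > 1e-300)[0]
        if len(nz) == 0 or nz[0] == len(poly) - 1:
            return np.empty(0)
        roots = np.roots(poly[nz[0]:])
    else:
        monic = poly / lead
        comp = np.zeros((4, 4))
        comp[0, :] = -monic[1:]
        comp[1:, :3] = np.eye(3)
        roots = np.linalg.eigvals(comp)
    re, im = roots.real, np.abs(roots.imag)
    real = re[im <= EIG_IMAG_TOL * np.maximum(1.0, np.abs(re))]
    return np.sort(real)


class Spindle(Solid):
    """Solvent-excluded neck between two atoms: capped cylinder minus torus.

    The solid is rotationally symmetric about ``axis``.  In cross section
    a point with axial coordinate ``a`` (relative to the center) and
    radial distance ``rho`` is inside iff

    * ``cap_lo <= a <= cap_hi`` (between the tangency end caps),
    * ``rho <= R`` (inside the cylinder traced by the probe centers), and
    * ``a**2 + (rho - R)**2 >= r**2`` (outside the probe-tube circle).

    ``broken`` marks spindles whose probe circle radius R drops below the
    probe radius r, so the probe edge passes beyond the centerline and the
    solid becomes an annular collar with no material on the axis.
    """

    def __init__(self, center, axis, R: float, r: float, cap_lo: float, cap_hi: float):
        self.center = np.asarray(center, dtype=float)
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("spindle axis must be nonzero")
        self.axis = axis / n
        if r <= 0 or R <= 0:
            raise ValueError("spindle radii must be positive")
        if cap_lo >= cap_hi:
            raise ValueError("cap_lo must be below cap_hi")
        self.R = float(R)
        self.r = float(r)
        self.cap_lo = float(cap_lo)
        self.cap_hi = float(cap_hi)
        self.broken = self.R < self.r
        # deterministic orthonormal completion: pivot on the axis component
        # of largest magnitude so the frame is bit-reproducible
        i = int(np.argmax(np.abs(self.axis)))
        ref = np.zeros(3)
        ref[(i + 1) % 3] = 1.0
        e2 = np.cross(self.axis, ref)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(self.axis, e2)
        self._frame = np.vstack([self.axis, e2, e3])

    def to_canonical(self, points: np.ndarray) -> np.ndarray:
        """Map world points into the frame with center at origin, axis = x."""
        return (np.atleast_2d(points) - self.center) @ self._frame.T

    def contains(self, points: np.ndarray) -> np.ndarray:
        q = self.to_canonical(np.asarray(points, dtype=float))
        a = q[:, 0]
        rho = np.hypot(q[:, 1], q[:, 2])
        in_caps = (a >= self.cap_lo - ABS_TOL) & (a <= self.cap_hi + ABS_TOL)
        in_cyl = rho <= self.R + ABS_TOL
        tube = a**2 + (rho - self.R) ** 2
        out_tube = tube >= (self.r - ABS_TOL) ** 2
        return in_caps & in_cyl & out_tube

    def intersect_segment(self, seg: Segment) -> IntervalSet:
        o = self.to_canonical(seg.origin)[0]
        d = seg.direction @ self._frame.T
        cand = list(solve_torus_quartic(self.R, self.r, o, d))
        # cap-plane crossings, kept if the hit lies within the cap disc
        if abs(d[0]) > 1e-15:
            cand.append((self.cap_lo - o[0]) / d[0])
            cand.append((self.cap_hi - o[0]) / d[0])
        return intervals_from_boundaries(self, seg, np.asarray(cand))

    def _cap_centroids(self):
        return (
            self.center + self.cap_lo * self.axis,
            self.center + self.cap_hi * self.axis,
        )

    def starting_cubes(self, lattice) -> set:
        lo_c, hi_c = self._cap_centroids()
        walks = []
        if self.broken:
            # the centerline is outside a broken spindle: walk from each
            # endcap centroid toward the center separately
            walks = [(lo_c, self.center), (hi_c, self.center)]
        else:
            walks = [(lo_c, hi_c)]
        found = set()
        for a, b in walks:
            for idx in lattice.walk_cubes(a, b):
                if is_surface_cube(self, lattice, idx):
                    found.add(idx)
                    break
        return found

    def bounds(self):
        pad = self.R + self.r
        lo = self.center - pad
        hi = self.center + pad
        return lo, hi

    def __repr__(self):
        return (
            f"Spindle(center={self.center}, R={self.R:.4g}, r={self.r:.4g}, "
            f"caps=({self.cap_lo:.4g}, {self.cap_hi:.4g}), broken={self.broken})"
        )
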