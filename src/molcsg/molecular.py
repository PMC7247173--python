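"""Solvent-excluded molecular solids.

A molecular solid is the region a spherical solvent probe cannot reach:
its boundary is the classic solvent-excluded (Connolly) surface.  The
solid is assembled from exact primitives placed by the dual graph of the
power diagram of the solvent-expanded atoms:

* one sphere per atom (van der Waals radius);
* one spindle per dual edge short enough that the probe cannot pass
  between the two atoms;
* one tetrahedron per dual tetrahedron without an overlong edge;
* one *cup* (probe-sized negsphere + tetrahedron spanning the triangle
  atoms and the probe center) per exposed dual triangle where a probe can
  rest tangent to all three atoms without colliding with a fourth.

Point containment follows the sign convention of the assembly: inside a
negsphere means outside the solid, otherwise inside any positive
primitive means inside.  All primitive lookups go through a 2 Angstrom
spatial hash, so classification cost is independent of molecule size.

The regular (weighted Delaunay) triangulation behind the power diagram is
computed via the standard 4-d lifting of the weighted atom centers to a
convex hull, with weights ``(r_vdw + r_solvent)**2`` so that power
vertices coincide with solvent-tangent probe positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .intervals import IntervalSet
from .lattice import Lattice
from .primitives import (
    ABS_TOL,
    Segment,
    Solid,
    Sphere,
    Spindle,
    Tetrahedron,
    is_surface_cube,
)

log = logging.getLogger(__name__)

#: Element-keyed van der Waals radii in Angstroms (configurable).
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

DEFAULT_SOLVENT_RADIUS = 1.4

#: Side of the spatial-hash cubes, in Angstroms.
HASH_RESOLUTION = 2.0

#: Slack for the probe-atom collision check when placing cups.
_COLLISION_SLACK = 1e-9


@dataclass(frozen=True, eq=False)
class Atom:
    center: np.ndarray
    vdw_radius: float
    element: str = "C"
    serial: int = 0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.vdw_radius <= 0:
            raise ValueError("atom radius must be positive")


def atom(x, y, z, element="C", serial=0, radius=None) -> Atom:
    r = radius if radius is not None else VDW_RADII.get(element, DEFAULT_VDW_RADIUS)
    return Atom(np.array([x, y, z], dtype=float), r, element, serial)


@dataclass
class PowerDualGraph:
    """Dual of the power diagram: atoms are vertices, adjacent cells edges."""

    n_atoms: int
    edges: set = field(default_factory=set)
    triangles: set = field(default_factory=set)
    tetrahedra: set = field(default_factory=set)
    overlong: set = field(default_factory=set)

    def is_overlong(self, pair) -> bool:
        return tuple(sorted(pair)) in self.overlong


@dataclass
class Cup:
    """Concave patch: tetrahedron spanning a triangle and a probe center,
    minus the probe-sized negsphere centered there."""

    negsphere: Sphere
    tetra: Tetrahedron
    atom_ids: tuple
    tangency_points: np.ndarray  # (3, 3) probe-atom tangency points


def compute_power_dual(atoms, solvent_radius: float = DEFAULT_SOLVENT_RADIUS) -> PowerDualGraph:
    """Dual graph of the power diagram of solvent-expanded atoms.

    Uses the 4-d lifting ``(x, |x|^2 - w)`` with weights
    ``w = (r + r_solvent)^2``: lower convex-hull facets are exactly the
    tetrahedra of the regular triangulation.  Small or degenerate inputs
    (fewer than five atoms, coplanar sets) are handled combinatorially or
    by joggling.  Every edge is flagged overlong when it is longer than
    the two van der Waals radii plus the probe diameter.
    """
    centers = np.array([a.center for a in atoms], dtype=float)
    n = len(atoms)
    g = PowerDualGraph(n_atoms=n)

    def add_tetra(quad):
        quad = tuple(sorted(int(v) for v in quad))
        g.tetrahedra.add(quad)
        for tri in combinations(quad, 3):
            g.triangles.add(tri)
        for e in combinations(quad, 2):
            g.edges.add(e)

    if n == 2:
        g.edges.add((0, 1))
    elif n == 3:
        g.triangles.add((0, 1, 2))
        g.edges.update(combinations(range(3), 2))
    elif n == 4:
        a, b, c, d = centers
        vol6 = abs(np.dot(np.cross(b - a, c - a), d - a))
        if vol6 > 1e-10:
            add_tetra((0, 1, 2, 3))
        else:  # coplanar quadruple: keep the complete graph of triangles
            g.triangles.update(combinations(range(4), 3))
            g.edges.update(combinations(range(4), 2))
    elif n >= 5:
        w = np.array([(a.vdw_radius + solvent_radius) ** 2 for a in atoms])
        lifted = np.column_stack([centers, np.einsum("ij,ij->i", centers, centers) - w])
        try:
            hull = ConvexHull(lifted, qhull_options="Qt")
        except QhullError:
            log.warning("degenerate atom configuration; joggling the lifted hull")
            hull = ConvexHull(lifted, qhull_options="QJ")
        lower = hull.equations[:, 3] < -1e-12
        for simplex in hull.simplices[lower]:
            add_tetra(simplex)

    for i, j in list(g.edges):
        limit = atoms[i].vdw_radius + atoms[j].vdw_radius + 2.0 * solvent_radius
        if np.linalg.norm(centers[i] - centers[j]) > limit:
            g.overlong.add((i, j))
    return g


def spindle_between(a: Atom, b: Atom, solvent_radius: float) -> Spindle | None:
    """Spindle for a pair of atoms the probe cannot pass between.

    The probe-center circle is the intersection of the two expanded
    spheres; its radius is the spindle's major radius, the probe radius
    the minor radius, and the end caps sit at the probe-atom tangency
    circles.  Returns None when the probe passes (overlong pair) or the
    geometry degenerates.
    """
    delta = b.center - a.center
    d = float(np.linalg.norm(delta))
    Ra = a.vdw_radius + solvent_radius
    Rb = b.vdw_radius + solvent_radius
    if d < 1e-9 or d >= Ra + Rb or d <= abs(Ra - Rb):
        return None
    u = delta / d
    x = (d * d + Ra * Ra - Rb * Rb) / (2.0 * d)
    Rc2 = Ra * Ra - x * x
    if Rc2 <= 1e-18:
        return None
    R = float(np.sqrt(Rc2))
    cap_lo = -x * solvent_radius / Ra
    cap_hi = (d - x) * solvent_radius / Rb
    if cap_hi - cap_lo <= 1e-12:
        return None
    return Spindle(a.center + x * u, u, R, solvent_radius, cap_lo, cap_hi)


def place_solvent_tangent_sphere(a1: Atom, a2: Atom, a3: Atom,
                                 solvent_radius: float) -> list:
    """Centers of probes tangent to all three atoms (0, 1 or 2 solutions).

    Trilateration on the solvent-expanded spheres: solutions satisfy
    ``|c - center_i| = r_i + r_solvent`` for all three atoms, and in
    general position come as a mirror pair across the atom plane.
    """
    p1, p2, p3 = a1.center, a2.center, a3.center
    r1 = a1.vdw_radius + solvent_radius
    r2 = a2.vdw_radius + solvent_radius
    r3 = a3.vdw_radius + solvent_radius
    ex = p2 - p1
    d = float(np.linalg.norm(ex))
    if d < 1e-9:
        return []
    ex /= d
    v3 = p3 - p1
    i = float(np.dot(ex, v3))
    ey = v3 - i * ex
    j = float(np.linalg.norm(ey))
    if j < 1e-9:
        log.info("colinear atom triple; no tangent probe placement")
        return []
    ey /= j
    ez = np.cross(ex, ey)
    x = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    y = (i * i + j * j + r1 * r1 - r3 * r3 - 2.0 * i * x) / (2.0 * j)
    z2 = r1 * r1 - x * x - y * y
    base = p1 + x * ex + y * ey
    if z2 < -1e-12:
        return []
    if z2 <= 1e-12:
        return [base]
    z = float(np.sqrt(z2))
    return [base + z * ez, base - z * ez]


class MolecularSolid(Solid):
    """Exact solvent-excluded solid serving the three basic functions."""

    def __init__(self, atoms, spheres, spindles, tetrahedra, cups,
                 solvent_radius: float, isolated_atom_ids=None):
        self.atoms = list(atoms)
        self.spheres = list(spheres)
        self.spindles = list(spindles)
        self.tetrahedra = list(tetrahedra)
        self.cups = list(cups)
        self.solvent_radius = float(solvent_radius)
        if isolated_atom_ids is None:
            isolated_atom_ids = range(len(self.spheres))
        self.isolated_atom_ids = sorted(isolated_atom_ids)
        self.positives = self.spheres + self.spindles + self.tetrahedra + [
            c.tetra for c in self.cups
        ]
        self.negatives = [c.negsphere for c in self.cups]
        self._build_hash()

    # -- spatial hash --------------------------------------------------

    def _build_hash(self):
        prims = [(p, False) for p in self.positives] + [(p, True) for p in self.negatives]
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for p, _ in prims:
            plo, phi = p.bounds()
            lo = np.minimum(lo, plo)
            hi = np.maximum(hi, phi)
        lo_i = np.floor(lo / HASH_RESOLUTION).astype(np.int64) - 1
        hi_i = np.ceil(hi / HASH_RESOLUTION).astype(np.int64) + 1
        self.hash_lattice = Lattice(lo_i * HASH_RESOLUTION, HASH_RESOLUTION,
                                    np.maximum(hi_i - lo_i, 1))
        cells: dict = {}
        lat = self.hash_lattice
        for pid, (p, neg) in enumerate(prims):
            plo, phi = p.bounds()
            a = np.maximum(lat.cubes_of_points(plo[None])[0], 0)
            b = np.minimum(lat.cubes_of_points(phi[None])[0] + 1, lat.dims)
            for i in range(a[0], b[0]):
                for j in range(a[1], b[1]):
                    for k in range(a[2], b[2]):
                        key = int(lat.cube_lin(np.array([i, j, k])))
                        cells.setdefault(key, ([], []))[1 if neg else 0].append(p)
        self._cells = cells
        self._prims = prims

    def _cell_primitives(self, lin: int):
        return self._cells.get(int(lin), ((), ()))

    # -- basic functions ----------------------------------------------

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(len(pts), dtype=bool)
        lat = self.hash_lattice
        idx = lat.cubes_of_points(pts)
        inb = lat.in_bounds_mask(idx)
        if not inb.any():
            return out
        lin = lat.cube_lin(idx[inb])
        sel = np.flatnonzero(inb)
        order = np.argsort(lin, kind="stable")
        lin_s, sel_s = lin[order], sel[order]
        starts = np.flatnonzero(np.r_[True, lin_s[1:] != lin_s[:-1]])
        ends = np.r_[starts[1:], len(lin_s)]
        for s, e in zip(starts, ends):
            pos, neg = self._cell_primitives(lin_s[s])
            if not pos:
                continue
            rows = sel_s[s:e]
            sub = pts[rows]
            inside = np.zeros(len(sub), dtype=bool)
            for p in pos:
                todo = ~inside
                if not todo.any():
                    break
                inside[todo] = p.contains(sub[todo])
            if inside.any() and neg:
                for p in neg:
                    hit = inside & p.contains(sub)
                    inside &= ~hit  # inside a negsphere means outside
            out[rows] = inside
        return out

    def contains_exhaustive(self, points: np.ndarray) -> np.ndarray:
        """Hash-free evaluation over all primitives (test oracle)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        pos = np.zeros(len(pts), dtype=bool)
        for p in self.positives:
            pos |= p.contains(pts)
        neg = np.zeros(len(pts), dtype=bool)
        for p in self.negatives:
            neg |= p.contains(pts)
        return pos & ~neg

    def intersect_segment(self, seg: Segment) -> IntervalSet:
        lat = self.hash_lattice
        p0 = seg.point(0.0)
        p1 = seg.point(seg.t_max)
        pos_ids, neg_ids = {}, {}
        for idx in lat.walk_cubes(p0, p1):
            lin = int(lat.cube_lin(np.asarray(idx)))
            pos, neg = self._cell_primitives(lin)
            for p in pos:
                pos_ids[id(p)] = p
            for p in neg:
                neg_ids[id(p)] = p
        ivpos = IntervalSet.empty()
        for p in pos_ids.values():
            ivpos = ivpos | p.intersect_segment(seg)
        ivneg = IntervalSet.empty()
        for p in neg_ids.values():
            ivneg = ivneg | p.intersect_segment(seg)
        return ivpos - ivneg

    def starting_cubes(self, lattice) -> set:
        cand = set()
        for cup in self.cups:
            for p in cup.tangency_points:
                c = lattice.cube_of_point(p)
                if c is not None:
                    cand.add(c)
        for sp in self.spindles:
            cand |= sp.starting_cubes(lattice)
            # sample the cap tangency circles: they lie on the molecular
            # surface wherever they are not buried by neighboring atoms
            e2, e3 = sp._frame[1], sp._frame[2]
            for cap in (sp.cap_lo, sp.cap_hi):
                rho = sp.R - np.sqrt(max(sp.r**2 - cap**2, 0.0))
                if rho <= 0:
                    continue
                base = sp.center + cap * sp.axis
                for ang in np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False):
                    p = base + rho * (np.cos(ang) * e2 + np.sin(ang) * e3)
                    c = lattice.cube_of_point(p)
                    if c is not None:
                        cand.add(c)
        for i in self.isolated_atom_ids:
            cand |= self.spheres[i].starting_cubes(lattice)
        return {c for c in cand if is_surface_cube(self, lattice, c)}

    def bounds(self):
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for p in self.positives:
            plo, phi = p.bounds()
            lo = np.minimum(lo, plo)
            hi = np.maximum(hi, phi)
        return lo, hi


def build_molecular_solid(atoms, solvent_radius: float = DEFAULT_SOLVENT_RADIUS,
                          dual: PowerDualGraph | None = None) -> MolecularSolid:
    """Assemble the solvent-excluded solid for a set of atoms."""
    atoms = list(atoms)
    if not atoms:
        raise ValueError("no atoms")
    if dual is None:
        dual = compute_power_dual(atoms, solvent_radius)
    centers = np.array([a.center for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms])
    tree = cKDTree(centers)

    spheres = [Sphere(a.center, a.vdw_radius) for a in atoms]

    spindles = []
    spindle_pairs = set()
    for i, j in sorted(dual.edges):
        if dual.is_overlong((i, j)):
            continue
        sp = spindle_between(atoms[i], atoms[j], solvent_radius)
        if sp is not None:
            spindles.append(sp)
            spindle_pairs.add((i, j))

    tetra_prims = []
    solid_tetra = set()
    for quad in sorted(dual.tetrahedra):
        if any(dual.is_overlong(e) for e in combinations(quad, 2)):
            continue
        corners = centers[list(quad)]
        try:
            tetra_prims.append(Tetrahedron(corners))
        except ValueError:
            continue
        solid_tetra.add(quad)

    # triangles buried between two solid tetrahedra cannot host a probe
    tri_adjacency: dict = {tri: 0 for tri in dual.triangles}
    for quad in solid_tetra:
        for tri in combinations(quad, 3):
            if tri in tri_adjacency:
                tri_adjacency[tri] += 1

    max_reach = float(radii.max()) + 2.0 * solvent_radius
    cups = []
    for tri in sorted(dual.triangles):
        if tri_adjacency.get(tri, 0) >= 2:
            continue
        a1, a2, a3 = (atoms[t] for t in tri)
        for center in place_solvent_tangent_sphere(a1, a2, a3, solvent_radius):
            near = tree.query_ball_point(center, max_reach)
            collide = False
            for j in near:
                if j in tri:
                    continue
                if np.linalg.norm(center - centers[j]) < radii[j] + solvent_radius - _COLLISION_SLACK:
                    collide = True
                    break
            if collide:
                continue
            corners = np.vstack([centers[list(tri)], center])
            try:
                tet = Tetrahedron(corners)
            except ValueError:
                continue
            neg = Sphere(center, solvent_radius, is_negative=True)
            tang = np.array([
                atoms[t].center
                + (atoms[t].vdw_radius / (atoms[t].vdw_radius + solvent_radius))
                * (center - atoms[t].center)
                for t in tri
            ])
            cups.append(Cup(neg, tet, tri, tang))

    touched = {i for pair in spindle_pairs for i in pair}
    isolated = [i for i in range(len(atoms)) if i not in touched]
    return MolecularSolid(atoms, spheres, spindles, tetra_prims, cups,
                          solvent_radius, isolated_atom_ids=isolated)
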