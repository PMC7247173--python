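"""Closed triangle meshes interpreted as exact solids.

Any watertight mesh — an electrostatic isopotential, a surface from
another tool — can act as a CSG operand.  Preparation classifies an
internal cubic lattice: cubes crossed by triangles are *nonempty*, the
rest are grouped into face-connected components and labelled interior or
exterior by segment parity against the mesh (components touching the
lattice border are exterior by definition).  The parity rule also
resolves the thin-wall abnormality where an internal void's boundary and
the outer surface share a lattice cube.

Point containment in nonempty cubes is decided by majority vote over
five segments cast to nearby empty-cube centers; votes compare each
segment's triangle-crossing parity with the target cube's label.  The
five segments are chosen by a deterministic generator seeded from the
hashed query coordinates, so results are reproducible across runs and
worker counts.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .intervals import IntervalSet
from .lattice import Lattice
from .mesh import TriangleMesh
from .mesher import marching_cubes_grid
from .primitives import Segment, Solid, is_surface_cube

log = logging.getLogger(__name__)

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity

#: Jitter amplitude for re-cast segments when an intersection is degenerate.
_JITTER = 1e-7


class MeshValidationError(ValueError):
    pass


def segment_triangle_hits(p0, p1, tri):
    """Intersection parameters of segment p0->p1 with triangles (m, 3, 3).

    Returns ``(ts, clean)``: hit parameters in [0, 1], and False when any
    hit is suspiciously close to a triangle edge/vertex or segment end,
    in which case the caller should re-cast with a jittered segment to
    keep parity counts stable.
    """
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    a = tri[:, 0]
    e1 = tri[:, 1] - a
    e2 = tri[:, 2] - a
    pvec = np.cross(d[None, :], e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    eps = 1e-13
    ok = np.abs(det) > eps
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = p0 - a
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,j->i", qvec, d) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    margin = 1e-9
    hit = ok & (u >= -margin) & (v >= -margin) & (u + v <= 1 + margin) & \
        (t >= -margin) & (t <= 1 + margin)
    if not hit.any():
        return np.empty(0), True
    uu, vv, tt = u[hit], v[hit], t[hit]
    near_edge = (
        (np.abs(uu) < margin) | (np.abs(vv) < margin)
        | (np.abs(1 - uu - vv) < margin)
        | (np.abs(tt) < margin) | (np.abs(1 - tt) < margin)
    )
    parallel_touch = (~ok) & (np.abs(np.einsum("ij,ij->i", np.cross(e1, e2), p0 - a)) < 1e-9 * np.linalg.norm(d))
    clean = not near_edge.any() and not parallel_touch.any()
    return np.sort(tt), clean


class MeshSolid(Solid):
    """A closed triangle mesh served through the three basic functions."""

    def __init__(self, mesh: TriangleMesh, resolution: float, _validate: bool = True):
        if mesh.is_empty():
            raise MeshValidationError("empty mesh cannot form a solid")
        if _validate:
            edges, counts = mesh.edge_counts()
            bad = edges[counts != 2]
            if len(bad):
                raise MeshValidationError(
                    f"mesh is not closed: {len(bad)} boundary/non-manifold edges, "
                    f"first few {bad[:5].tolist()}"
                )
        areas = mesh.triangle_areas()
        degenerate = areas <= 1e-18
        if degenerate.any():
            log.warning("dropping %d zero-area triangles", int(degenerate.sum()))
            mesh = TriangleMesh(mesh.vertices, mesh.faces[~degenerate], dict(mesh.metadata))
        self.mesh = mesh
        self._tri = mesh.vertices[mesh.faces]  # (m, 3, 3)

        lo, hi = mesh.bounds()
        lo_i = np.floor(lo / resolution).astype(np.int64) - 2
        hi_i = np.ceil(hi / resolution).astype(np.int64) + 2
        self.lattice = Lattice(lo_i * resolution, resolution, np.maximum(hi_i - lo_i, 1))
        self.resolution = float(resolution)
        self._vote_cache: dict = {}
        self._build_hash()
        self._label_components()

    # -- preparation ---------------------------------------------------

    def _build_hash(self):
        lat = self.lattice
        tlo = self._tri.min(axis=1)
        thi = self._tri.max(axis=1)
        lo_c = np.maximum(lat.cubes_of_points(tlo), 0)
        hi_c = np.minimum(lat.cubes_of_points(thi) + 1, lat.dims)
        cells: dict = {}
        nonempty = np.zeros(tuple(lat.dims), dtype=bool)
        for tid in range(len(self._tri)):
            a, b = lo_c[tid], hi_c[tid]
            nonempty[a[0]:b[0], a[1]:b[1], a[2]:b[2]] = True
            for i in range(a[0], b[0]):
                for j in range(a[1], b[1]):
                    for k in range(a[2], b[2]):
                        cells.setdefault((i, j, k), []).append(tid)
        self._cells = {k: np.array(v, dtype=np.int64) for k, v in cells.items()}
        self.nonempty = nonempty

    def _outside_point(self) -> np.ndarray:
        lat = self.lattice
        return lat.origin - np.array([0.731, 0.577, 0.419]) * lat.resolution

    def _count_crossings(self, p0, p1, tries: int = 12, rng=None):
        """Parity-stable crossing count of a segment against the mesh."""
        rng = rng or np.random.default_rng(12345)
        q0, q1 = np.asarray(p0, float), np.asarray(p1, float)
        for _ in range(tries):
            ts, clean = segment_triangle_hits(q0, q1, self._tri)
            if clean:
                return len(ts)
            q0 = np.asarray(p0, float) + rng.normal(0.0, _JITTER, 3)
            q1 = np.asarray(p1, float) + rng.normal(0.0, _JITTER, 3)
        log.warning("crossing count stayed degenerate after jittering; using last")
        return len(ts)

    def _label_components(self):
        lat = self.lattice
        self.nonempty_labels, self.n_nonempty_components = ndimage.label(
            self.nonempty, structure=_FACE_STRUCTURE
        )
        empty_labels, n_empty = ndimage.label(~self.nonempty, structure=_FACE_STRUCTURE)
        self.empty_labels = empty_labels
        self.n_empty_components = n_empty
        border = np.zeros_like(self.nonempty)
        border[[0, -1], :, :] = True
        border[:, [0, -1], :] = True
        border[:, :, [0, -1]] = True
        border_labels = set(np.unique(empty_labels[border & ~self.nonempty])) - {0}
        interior = np.zeros(n_empty + 1, dtype=bool)
        out = self._outside_point()
        for lab in range(1, n_empty + 1):
            if lab in border_labels:
                continue  # lattice-border components are exterior by definition
            cells = np.argwhere(empty_labels == lab)
            rep = lat.origin + (cells[0] + 0.5) * lat.resolution
            crossings = self._count_crossings(rep, out)
            interior[lab] = bool(crossings % 2)
        self.empty_interior = interior  # index by empty label

    # -- triangle lookup ----------------------------------------------

    def _triangles_near_segment(self, p0, p1) -> np.ndarray:
        ids = []
        for idx in self.lattice.walk_cubes(p0, p1):
            got = self._cells.get(idx)
            if got is not None:
                ids.append(got)
        if not ids:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(ids))

    # -- basic functions ----------------------------------------------

    def _nearby_empty_cells(self, cell, want: int = 5):
        """Up to ``want`` nearby empty cells, preferring distinct octants."""
        lat = self.lattice
        found = []
        cell = np.asarray(cell)
        for ring in range(1, int(max(lat.dims)) + 1):
            lo = np.maximum(cell - ring, 0)
            hi = np.minimum(cell + ring + 1, lat.dims)
            block = ~self.nonempty[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            cand = np.argwhere(block) + lo
            if len(cand) == 0:
                continue
            d2 = np.sum((cand - cell) ** 2, axis=1)
            order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], d2))
            cand = cand[order]
            octants = np.sign(cand - cell)
            chosen, seen_oct = [], set()
            for c, o in zip(cand, octants):
                key = tuple(o)
                if key in seen_oct and len(seen_oct) < want:
                    continue
                seen_oct.add(key)
                chosen.append(c)
                if len(chosen) >= want:
                    break
            if len(chosen) < want:
                for c in cand:
                    if not any(np.array_equal(c, x) for x in chosen):
                        chosen.append(c)
                    if len(chosen) >= want:
                        break
            found = chosen
            if len(found) >= want:
                break
        return found

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lat = self.lattice
        out = np.zeros(len(pts), dtype=bool)
        idx = lat.cubes_of_points(pts)
        inb = lat.in_bounds_mask(idx)
        if not inb.any():
            return out
        ii = idx[inb]
        empty_here = ~self.nonempty[ii[:, 0], ii[:, 1], ii[:, 2]]
        labels = self.empty_labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        res = np.zeros(len(ii), dtype=bool)
        res[empty_here] = self.empty_interior[labels[empty_here]]
        hard = np.flatnonzero(~empty_here)
        for h in hard:
            res[h] = self._vote_point(pts[np.flatnonzero(inb)[h]], ii[h])
        out[inb] = res
        return out

    def _vote_point(self, p: np.ndarray, cell) -> bool:
        key = p.tobytes()
        cached = self._vote_cache.get(key)
        if cached is not None:
            return cached
        result = self._vote_point_uncached(p, cell)
        self._vote_cache[key] = result
        return result

    def _vote_point_uncached(self, p: np.ndarray, cell) -> bool:
        lat = self.lattice
        seed = int(np.abs(hash((round(float(p[0]), 9), round(float(p[1]), 9),
                                round(float(p[2]), 9)))) % (2**31))
        rng = np.random.default_rng(seed)
        targets = self._nearby_empty_cells(cell, want=5)
        votes_in = 0
        votes_out = 0
        for tc in targets:
            center = lat.origin + (np.asarray(tc) + 0.5) * lat.resolution
            center = center + rng.normal(0.0, 0.05 * lat.resolution, 3)
            tids = self._triangles_near_segment(p, center)
            if len(tids) == 0:
                n = 0
            else:
                tri = self._tri[tids]
                for attempt in range(8):
                    ts, clean = segment_triangle_hits(p, center, tri)
                    if clean:
                        break
                    center = lat.origin + (np.asarray(tc) + 0.5) * lat.resolution \
                        + rng.normal(0.0, 0.2 * lat.resolution, 3)
                    tids = self._triangles_near_segment(p, center)
                    tri = self._tri[tids] if len(tids) else np.empty((0, 3, 3))
                n = len(ts)
            target_interior = bool(self.empty_interior[self.empty_labels[tuple(tc)]])
            even = n % 2 == 0
            # even crossings to an interior target vote interior; to an
            # exterior target they vote exterior
            if even == target_interior:
                votes_in += 1
            else:
                votes_out += 1
        return votes_in > votes_out

    def intersect_segment(self, seg: Segment) -> IntervalSet:
        p0 = seg.point(0.0)
        p1 = seg.point(seg.t_max)
        tids = self._triangles_near_segment(p0, p1)
        start_inside = bool(self.contains(p0[None])[0])
        if len(tids) == 0:
            return IntervalSet([(0.0, seg.t_max)]) if start_inside else IntervalSet.empty()
        tri = self._tri[tids]
        rng = np.random.default_rng(987654321)
        q0, q1 = p0, p1
        for attempt in range(8):
            ts, clean = segment_triangle_hits(q0, q1, tri)
            end_inside = bool(self.contains(p1[None])[0])
            parity_ok = (len(ts) % 2 == 0) == (start_inside == end_inside)
            if clean and parity_ok:
                break
            q0 = p0 + rng.normal(0.0, _JITTER, 3)
            q1 = p1 + rng.normal(0.0, _JITTER, 3)
            log.debug("re-cast jittered segment (attempt %d)", attempt + 1)
        cuts = ts * seg.t_max  # hits parametrized on [0, 1] of p0->p1
        pairs = []
        state = start_inside
        prev = 0.0
        for t in cuts:
            if state:
                pairs.append((prev, t))
            state = not state
            prev = t
        if state:
            pairs.append((prev, seg.t_max))
        return IntervalSet(pairs)

    def starting_cubes(self, lattice) -> set:
        """Seed cubes in an external lattice, >= 1 per nonempty component."""
        out = set()
        lat = self.lattice
        for lab in range(1, self.n_nonempty_components + 1):
            cells = np.argwhere(self.nonempty_labels == lab)
            got = False
            for cell in cells:
                lo = lat.origin + cell * lat.resolution
                hi = lo + lat.resolution
                a = lattice.cubes_of_points(lo[None])[0]
                b = lattice.cubes_of_points(hi[None])[0] + 1
                a = np.maximum(a, 0)
                b = np.minimum(b, lattice.dims)
                for i in range(a[0], b[0]):
                    for j in range(a[1], b[1]):
                        for k in range(a[2], b[2]):
                            if is_surface_cube(self, lattice, (i, j, k)):
                                out.add((i, j, k))
                                got = True
                if got:
                    break
        return out

    def bounds(self):
        return self.mesh.bounds()


def prepare_mesh_solid(mesh: TriangleMesh, resolution: float) -> MeshSolid:
    """Validate and lattice-classify a closed mesh for use as a solid."""
    return MeshSolid(mesh, resolution)


def extract_isopotential_mesh(values: np.ndarray, origin, spacing, k: float) -> TriangleMesh:
    """Closed isopotential mesh at threshold ``k`` from a scalar grid.

    Positive ``k`` bounds the region with potential >= k; negative ``k``
    bounds the region with potential <= k.  Open isosurfaces are capped
    at the grid box.
    """
    if k == 0:
        raise ValueError("isopotential threshold k must be nonzero")
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("grid contains non-finite values")
    inside_above = k > 0
    if (inside_above and v.max() < k) or (not inside_above and v.min() > k):
        log.warning("threshold %g outside grid value range; empty isosurface", k)
        return TriangleMesh.empty()
    return marching_cubes_grid(v, origin, spacing, level=k, inside_above=inside_above)
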