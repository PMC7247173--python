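"""Cubic lattices, surface-cube floodfill and corner classification.

The mesher discretizes space into an axis-aligned cubic lattice whose
cube side equals the requested output resolution.  Surface cubes — cubes
with at least one corner inside and one outside a solid — are discovered
by a level-synchronous breadth-first floodfill over face-adjacent cubes,
seeded by each solid's ``starting_cubes``.  Corner classifications are
cached so every distinct lattice corner is evaluated exactly once per
solid; the ``workers`` argument splits those point-classification batches
across threads without changing any result.
"""

from __future__ import annotations

import logging
import warnings
from concurrent.futures import ThreadPoolExecutor

import numpy as np

from .mc_table import CORNER_OFFSETS
from .primitives import Solid

log = logging.getLogger(__name__)

#: Hard cap on lattice cube counts; exceeding it raises LatticeSizeError.
DEFAULT_MAX_CUBES = 200_000_000

_NEIGHBOR_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


class LatticeSizeError(RuntimeError):
    pass


class Lattice:
    """Axis-aligned cubic grid; cubes indexed by integer triples.

    ``origin`` is the minimum corner, ``resolution`` the cube side in
    Angstroms, ``dims`` the cube counts per axis.  Corner ``(i, j, k)``
    sits at ``origin + (i, j, k) * resolution``.
    """

    def __init__(self, origin, resolution: float, dims):
        if resolution <= 0:
            raise ValueError("lattice resolution must be positive")
        self.origin = np.asarray(origin, dtype=float)
        self.resolution = float(resolution)
        self.dims = np.asarray(dims, dtype=np.int64)
        if np.any(self.dims < 1):
            raise ValueError("lattice dims must be >= 1")
        self.corner_dims = self.dims + 1
        self._cube_strides = np.array(
            [self.dims[1] * self.dims[2], self.dims[2], 1], dtype=np.int64
        )
        self._corner_strides = np.array(
            [self.corner_dims[1] * self.corner_dims[2], self.corner_dims[2], 1],
            dtype=np.int64,
        )
        # linear-id offsets of a cube's 8 corners from its base corner
        self._corner_offsets_lin = CORNER_OFFSETS @ self._corner_strides

    @property
    def n_cubes(self) -> int:
        return int(np.prod(self.dims))

    @property
    def n_corners(self) -> int:
        return int(np.prod(self.corner_dims))

    def __repr__(self):
        return f"Lattice(origin={self.origin}, resolution={self.resolution}, dims={tuple(self.dims)})"

    # -- index conversions --------------------------------------------

    def cube_lin(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=np.int64) @ self._cube_strides

    def cube_idx(self, lin: np.ndarray) -> np.ndarray:
        lin = np.asarray(lin, dtype=np.int64)
        i, rem = np.divmod(lin, self._cube_strides[0])
        j, k = np.divmod(rem, self._cube_strides[1])
        return np.stack([i, j, k], axis=-1)

    def corner_lin(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=np.int64) @ self._corner_strides

    def corner_idx(self, lin: np.ndarray) -> np.ndarray:
        lin = np.asarray(lin, dtype=np.int64)
        i, rem = np.divmod(lin, self._corner_strides[0])
        j, k = np.divmod(rem, self._corner_strides[1])
        return np.stack([i, j, k], axis=-1)

    def corner_positions(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.resolution

    def corner_positions_lin(self, lin: np.ndarray) -> np.ndarray:
        return self.corner_positions(self.corner_idx(lin))

    def cube_corner_lins(self, cube_lin: np.ndarray) -> np.ndarray:
        """(n, 8) corner linear ids for each cube, ordered per CORNER_OFFSETS."""
        idx = self.cube_idx(np.asarray(cube_lin, dtype=np.int64))
        base = self.corner_lin(idx)
        return base[:, None] + self._corner_offsets_lin[None, :]

    # -- geometry ------------------------------------------------------

    def in_bounds(self, idx) -> bool:
        idx = np.asarray(idx)
        return bool(np.all(idx >= 0) and np.all(idx < self.dims))

    def in_bounds_mask(self, idx: np.ndarray) -> np.ndarray:
        return np.all((idx >= 0) & (idx < self.dims), axis=-1)

    def cube_of_point(self, p):
        idx = np.floor((np.asarray(p, dtype=float) - self.origin) / self.resolution).astype(np.int64)
        return tuple(int(v) for v in idx) if self.in_bounds(idx) else None

    def cubes_of_points(self, pts: np.ndarray) -> np.ndarray:
        return np.floor((np.asarray(pts, dtype=float) - self.origin) / self.resolution).astype(np.int64)

    def cube_corners(self, idx) -> np.ndarray:
        """(8, 3) corner positions of one cube, ordered per CORNER_OFFSETS."""
        base = np.asarray(idx, dtype=np.int64)
        return self.origin + (base + CORNER_OFFSETS) * self.resolution

    def walk_cubes(self, p0, p1):
        """Yield in-bounds cube index triples crossed by the segment p0->p1.

        Standard voxel traversal: step from cube to cube through the face
        the segment exits.
        """
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        d = p1 - p0
        idx = np.floor((p0 - self.origin) / self.resolution).astype(np.int64)
        end = np.floor((p1 - self.origin) / self.resolution).astype(np.int64)
        step = np.where(d > 0, 1, -1).astype(np.int64)
        tmax = np.full(3, np.inf)
        tdelta = np.full(3, np.inf)
        for ax in range(3):
            if d[ax] != 0.0:
                boundary = self.origin[ax] + (idx[ax] + (1 if d[ax] > 0 else 0)) * self.resolution
                tmax[ax] = (boundary - p0[ax]) / d[ax]
                tdelta[ax] = self.resolution / abs(d[ax])
        guard = int(np.abs(end - idx).sum()) + 4
        for _ in range(2 * guard):
            if self.in_bounds(idx):
                yield tuple(int(v) for v in idx)
            if np.all(idx == end):
                return
            ax = int(np.argmin(tmax))
            if tmax[ax] > 1.0 + 1e-12:
                return
            idx[ax] += step[ax]
            tmax[ax] += tdelta[ax]


def build_lattice(operands, resolution: float, padding: int = 1,
                  max_cubes: int = DEFAULT_MAX_CUBES) -> Lattice:
    """Lattice covering all operand bounding boxes with >= 1 cube padding.

    The origin is snapped to integer multiples of the resolution so that
    identical inputs always yield identical lattices.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if isinstance(operands, Solid):
        operands = [operands]
    if not operands:
        raise ValueError("no operands")
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for s in operands:
        slo, shi = s.bounds()
        lo = np.minimum(lo, slo)
        hi = np.maximum(hi, shi)
    lo_i = np.floor(lo / resolution).astype(np.int64) - padding
    hi_i = np.ceil(hi / resolution).astype(np.int64) + padding
    dims = np.maximum(hi_i - lo_i, 1)
    if int(np.prod(dims)) > max_cubes:
        raise LatticeSizeError(
            f"lattice of {int(np.prod(dims))} cubes exceeds the cap of "
            f"{max_cubes}; use a coarser resolution"
        )
    return Lattice(lo_i * resolution, resolution, dims)


class CornerClassifier:
    """Cached inside/outside classification of lattice corners for a solid.

    Each distinct corner is evaluated at most once; batches may be split
    across ``workers`` threads (numpy releases the GIL for the bulk of the
    arithmetic), with results written by index so the outcome does not
    depend on the worker count.
    """

    def __init__(self, solid: Solid, lattice: Lattice, workers: int = 1):
        self.solid = solid
        self.lattice = lattice
        self.workers = max(1, int(workers))
        self.states = np.full(lattice.n_corners, -1, dtype=np.int8)
        self.n_evaluated = 0

    def _evaluate(self, pts: np.ndarray) -> np.ndarray:
        if self.workers == 1 or len(pts) < 4 * self.workers:
            return self.solid.contains(pts)
        chunks = np.array_split(pts, self.workers)
        with ThreadPoolExecutor(max_workers=self.workers) as pool:
            parts = list(pool.map(self.solid.contains, chunks))
        return np.concatenate(parts)

    def classify(self, corner_lin: np.ndarray) -> np.ndarray:
        corner_lin = np.asarray(corner_lin, dtype=np.int64)
        unknown = np.unique(corner_lin[self.states[corner_lin] == -1])
        if len(unknown):
            pts = self.lattice.corner_positions_lin(unknown)
            self.states[unknown] = self._evaluate(pts).astype(np.int8)
            self.n_evaluated += len(unknown)
        return self.states[corner_lin].astype(bool)


def _mixed_mask(classifier: CornerClassifier, cube_lin: np.ndarray) -> np.ndarray:
    corners = classifier.lattice.cube_corner_lins(cube_lin)
    states = classifier.classify(corners.ravel()).reshape(-1, 8)
    return states.any(axis=1) & ~states.all(axis=1)


def flood_surface_cubes(solid: Solid, starts, lattice: Lattice, workers: int = 1,
                        classifier: CornerClassifier | None = None) -> np.ndarray:
    """All surface cubes of ``solid`` reachable from ``starts``.

    Level-synchronous BFS over face-adjacent cubes: the whole frontier is
    classified, surviving surface cubes emit their unexamined neighbors,
    and the frontier swaps.  Returns sorted cube linear ids.
    """
    cls = classifier or CornerClassifier(solid, lattice, workers)
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64)
    start_idx = np.array(sorted(starts), dtype=np.int64).reshape(-1, 3)
    start_idx = start_idx[lattice.in_bounds_mask(start_idx)]
    frontier = np.unique(lattice.cube_lin(start_idx))
    examined = np.zeros(lattice.n_cubes, dtype=bool)
    examined[frontier] = True
    surface = []
    while len(frontier):
        mixed = _mixed_mask(cls, frontier)
        surf = frontier[mixed]
        surface.append(surf)
        if not len(surf):
            break
        nbr_idx = lattice.cube_idx(surf)[:, None, :] + _NEIGHBOR_STEPS[None, :, :]
        nbr_idx = nbr_idx.reshape(-1, 3)
        nbr_idx = nbr_idx[lattice.in_bounds_mask(nbr_idx)]
        nbr = np.unique(lattice.cube_lin(nbr_idx))
        nbr = nbr[~examined[nbr]]
        examined[nbr] = True
        frontier = nbr
    if not surface:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(surface))


def exhaustive_surface_cubes(solid: Solid, lattice: Lattice,
                             chunk: int = 2_000_000) -> np.ndarray:
    """Surface cubes by classifying every lattice corner (scan oracle)."""
    n = lattice.n_corners
    states = np.empty(n, dtype=bool)
    for s in range(0, n, chunk):
        lin = np.arange(s, min(s + chunk, n), dtype=np.int64)
        states[s : s + len(lin)] = solid.contains(lattice.corner_positions_lin(lin))
    grid = states.reshape(tuple(lattice.corner_dims))
    nx, ny, nz = lattice.dims
    any_in = np.zeros((nx, ny, nz), dtype=bool)
    all_in = np.ones((nx, ny, nz), dtype=bool)
    for dx, dy, dz in CORNER_OFFSETS:
        v = grid[dx : dx + nx, dy : dy + ny, dz : dz + nz]
        any_in |= v
        all_in &= v
    return np.flatnonzero(any_in & ~all_in)


def _bbox_scan_cubes(solid: Solid, lattice: Lattice, cap: int = 4_000_000):
    """Fallback seed scan over the solid's bounding box (thin solids)."""
    lo, hi = solid.bounds()
    lo_i = np.maximum(lattice.cubes_of_points(lo[None])[0] - 1, 0)
    hi_i = np.minimum(lattice.cubes_of_points(hi[None])[0] + 2, lattice.dims)
    span = np.maximum(hi_i - lo_i, 0)
    if int(np.prod(span)) == 0 or int(np.prod(span)) > cap:
        return np.empty(0, dtype=np.int64)
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo_i, hi_i)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    lin = lattice.cube_lin(idx)
    cls = CornerClassifier(solid, lattice)
    return lin[_mixed_mask(cls, lin)]


def find_all_surface_cubes(root: Solid, lattice: Lattice, workers: int = 1,
                           starts: dict | None = None):
    """Surface cubes of the CSG output.

    Per input solid, its starting cubes seed a floodfill over that
    solid's own surface; the per-solid sets are unioned and the final set
    is the subset whose corners straddle the root (output) region.
    Returns ``(cube_lin, root_classifier)``.

    If a solid's seeds find nothing but its bounding box overlaps the
    lattice, a bounding-box corner scan is used as a fallback seed source
    (thin solids can occupy a cube without straddling any corner).
    """
    candidates = []
    for leaf in root.leaves():
        leaf_starts = starts.get(id(leaf)) if starts else None
        if leaf_starts is None:
            leaf_starts = leaf.starting_cubes(lattice)
        cls = CornerClassifier(leaf, lattice, workers)
        cubes = flood_surface_cubes(leaf, leaf_starts, lattice, workers, classifier=cls)
        if len(cubes) == 0:
            fallback = _bbox_scan_cubes(leaf, lattice)
            if len(fallback):
                warnings.warn(
                    "starting-cube search found no seeds; falling back to a "
                    "bounding-box corner scan",
                    RuntimeWarning,
                    stacklevel=2,
                )
                cubes = flood_surface_cubes(
                    leaf, [tuple(v) for v in lattice.cube_idx(fallback)], lattice,
                    workers, classifier=cls,
                )
        candidates.append(cubes)
    if not candidates:
        return np.empty(0, dtype=np.int64), CornerClassifier(root, lattice, workers)
    cand = np.unique(np.concatenate(candidates))
    root_cls = CornerClassifier(root, lattice, workers)
    if len(cand) == 0:
        return cand, root_cls
    seeds = cand[_mixed_mask(root_cls, cand)]
    # flood once more over the output surface itself: a leaf surface can be
    # face-disconnected on the lattice, so root-straddling cubes adjacent to
    # the seeds may not appear among the per-leaf candidates
    final = flood_surface_cubes(
        root, [tuple(v) for v in lattice.cube_idx(seeds)], lattice, workers,
        classifier=root_cls,
    )
    return final, root_cls
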