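"""The 256-case marching-cubes triangulation table.

The table is generated once at import time instead of being typed in by
hand.  For each of the 256 inside/outside corner masks, the surface
contour on every cube face is built from the face's crossed edges; the
ambiguous face case (two diagonally-inside corners, four crossed edges)
is resolved by a fixed rule — the two inside corners are never connected
through the face, i.e. each inside corner keeps its own contour segment.
Because the rule depends only on the shared face's corner states, the two
cubes flanking any face always agree on the contour, which makes every
produced mesh watertight, including across ambiguous (saddle)
configurations where the classic table leaves holes.

Face segments chain into closed loops (every crossed cube edge lies on
exactly two faces, so every contour vertex has degree two); each loop is
fan-triangulated and oriented so triangle normals point from the inside
region toward the outside.

Corner ``i`` sits at offset ``(i & 1, (i >> 1) & 1, (i >> 2) & 1)`` and
bit ``i`` of the mask is set when corner ``i`` is inside the solid.
"""

from __future__ import annotations

import numpy as np

CORNER_OFFSETS = np.array(
    [[(i >> 0) & 1, (i >> 1) & 1, (i >> 2) & 1] for i in range(8)], dtype=np.int64
)

#: The 12 cube edges as corner-index pairs: x-edges, y-edges, z-edges.
EDGES = (
    (0, 1), (2, 3), (4, 5), (6, 7),
    (0, 2), (1, 3), (4, 6), (5, 7),
    (0, 4), (1, 5), (2, 6), (3, 7),
)

_EDGE_ID = {frozenset(e): i for i, e in enumerate(EDGES)}

#: The 6 faces as cyclically ordered corner quadruples.
FACES = (
    (0, 1, 3, 2),  # z = 0
    (4, 5, 7, 6),  # z = 1
    (0, 1, 5, 4),  # y = 0
    (2, 3, 7, 6),  # y = 1
    (0, 2, 6, 4),  # x = 0
    (1, 3, 7, 5),  # x = 1
)


def _face_segments(mask: int, face) -> list:
    """Contour segments (pairs of global edge ids) on one face."""
    states = [(mask >> c) & 1 for c in face]
    crossed = [
        k for k in range(4) if states[k] != states[(k + 1) % 4]
    ]  # positions of crossed face edges (between corner k and k+1)
    if not crossed:
        return []

    def edge_id(k):
        return _EDGE_ID[frozenset((face[k], face[(k + 1) % 4]))]

    if len(crossed) == 2:
        return [(edge_id(crossed[0]), edge_id(crossed[1]))]
    # ambiguous face: states alternate around the face; pair the two edges
    # incident to each inside corner so diagonal inside corners stay apart
    segs = []
    for k in range(4):
        if states[k]:
            segs.append((edge_id((k - 1) % 4), edge_id(k)))
    return segs


def _loops_for_mask(mask: int) -> list:
    adjacency = {}
    for face in FACES:
        for a, b in _face_segments(mask, face):
            adjacency.setdefault(a, []).append(b)
            adjacency.setdefault(b, []).append(a)
    for v, nbrs in adjacency.items():
        if len(nbrs) != 2:  # pragma: no cover - structural guarantee
            raise AssertionError(f"contour vertex of degree {len(nbrs)} in mask {mask}")
    loops = []
    seen = set()
    for start in sorted(adjacency):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            a, b = adjacency[cur]
            nxt = b if a == prev else a
            if nxt == start:
                break
            loop.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        loops.append(loop)
    return loops


def _edge_midpoint(edge_id: int) -> np.ndarray:
    a, b = EDGES[edge_id]
    return 0.5 * (CORNER_OFFSETS[a] + CORNER_OFFSETS[b])


def _orient_loop(mask: int, loop: list) -> list:
    # outward estimate: sum of (outside corner - inside corner) over the
    # loop's crossed edges
    w = np.zeros(3)
    for e in loop:
        a, b = EDGES[e]
        if (mask >> a) & 1:
            w += CORNER_OFFSETS[b] - CORNER_OFFSETS[a]
        else:
            w += CORNER_OFFSETS[a] - CORNER_OFFSETS[b]
    pts = np.array([_edge_midpoint(e) for e in loop], dtype=float)
    # Newell normal of the (possibly non-planar) midpoint polygon
    n = np.zeros(3)
    for i in range(len(pts)):
        p, q = pts[i], pts[(i + 1) % len(pts)]
        n += np.cross(p, q)
    d = float(np.dot(n, w))
    if d == 0.0:  # pragma: no cover - no mask triggers this
        raise AssertionError(f"undecidable loop orientation in mask {mask}")
    return loop if d > 0 else loop[::-1]


def _build_table():
    table = []
    for mask in range(256):
        tris = []
        if mask not in (0, 255):
            for loop in _loops_for_mask(mask):
                loop = _orient_loop(mask, loop)
                for i in range(1, len(loop) - 1):
                    tris.append((loop[0], loop[i], loop[i + 1]))
        table.append(tuple(tris))
    return tuple(table)


#: TRIANGLE_TABLE[mask] is a tuple of triangles, each a triple of cube-edge
#: ids, oriented with outward (inside-to-outside) normals.
TRIANGLE_TABLE = _build_table()
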