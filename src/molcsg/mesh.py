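"""Triangle-mesh container and topology helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TriangleMesh:
    """Closed triangle soup: (n, 3) float vertices, (m, 3) int faces.

    Meshes produced by the lattice mesher are watertight (every edge
    shared by exactly two triangles) and consistently oriented with
    outward normals.
    """

    vertices: np.ndarray
    faces: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @classmethod
    def empty(cls) -> "TriangleMesh":
        return cls(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_empty(self) -> bool:
        return self.n_faces == 0

    def edges(self) -> np.ndarray:
        """All undirected edges, one row per face edge (with repeats)."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        return np.sort(e, axis=1)

    def edge_counts(self):
        """Unique undirected edges and their incidence counts."""
        e = self.edges()
        if len(e) == 0:
            return np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.unique(e, axis=0, return_counts=True)

    def is_watertight(self) -> bool:
        _, counts = self.edge_counts()
        return bool(len(counts) == 0 or np.all(counts == 2))

    def euler_characteristic(self) -> int:
        uniq, _ = self.edge_counts()
        return self.n_vertices - len(uniq) + self.n_faces

    def signed_volume(self) -> float:
        """Signed enclosed volume via signed tetrahedra against the origin."""
        if self.is_empty():
            return 0.0
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def bounds(self):
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, dtype=float), self.faces.copy(), dict(self.metadata))

    def shell_labels(self) -> np.ndarray:
        """Connected-component label per face (components = shells)."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        if self.is_empty():
            return np.empty(0, dtype=np.int64)
        e = self.edges()
        face_ids = np.tile(np.arange(self.n_faces), 3)
        uniq, inv = np.unique(e, axis=0, return_inverse=True)
        # faces sharing an undirected edge are adjacent
        order = np.argsort(inv, kind="stable")
        inv_s, face_s = inv[order], face_ids[order]
        starts = np.searchsorted(inv_s, np.arange(len(uniq)))
        ends = np.append(starts[1:], len(inv_s))
        rows, cols = [], []
        for s, t in zip(starts, ends):
            group = face_s[s:t]
            for i in range(len(group) - 1):
                rows.append(group[i])
                cols.append(group[i + 1])
        adj = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n_faces, self.n_faces)
        )
        _, labels = connected_components(adj, directed=False)
        return labels

    def submesh(self, face_mask) -> "TriangleMesh":
        faces = self.faces[face_mask]
        used, new_faces = np.unique(faces, return_inverse=True)
        return TriangleMesh(self.vertices[used], new_faces.reshape(-1, 3), dict(self.metadata))

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices.copy(), faces=self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))
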