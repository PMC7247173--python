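"""Binding-cavity construction, fragment volumetrics and mesh metrics.

A ligand-bound binding cavity is carved out of a receptor by CSG: the
union of large spheres centered on the ligand atoms describes the
ligand's neighborhood, the small-probe molecular solid removes the
solvent-inaccessible receptor interior, and a large-probe *envelope*
solid bounds the outer extent of the pocket:

    cavity = (union of ligand spheres - receptor solid, probe 1.4)
             intersected with (receptor solid, probe 5.0)

The connected shells of a cavity (or of a cavity difference) are its
*fragments*; fragment volumes feed downstream specificity statistics.
Volumes come from the Surveyor's formula (signed tetrahedra against the
origin) and shape agreement is summarized by the displacement distance:
per-vertex nearest-point distance from one mesh onto the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .csg import difference, intersection, union_all
from .mesh import TriangleMesh
from .mesher import mesh_solid_boundary
from .molecular import build_molecular_solid
from .primitives import Sphere

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CavitySpec:
    """Radii of the cavity construction, in Angstroms."""

    ligand_sphere_radius: float = 5.0
    probe_small: float = 1.4
    probe_large: float = 5.0

    def __post_init__(self):
        if min(self.ligand_sphere_radius, self.probe_small, self.probe_large) <= 0:
            raise ValueError("all cavity radii must be positive")
        if self.probe_large <= self.probe_small:
            raise ValueError("envelope probe must exceed the solvent probe")


@dataclass
class Fragment:
    """One connected shell of a cavity mesh, with any nested voids."""

    mesh: TriangleMesh
    volume: float
    centroid: np.ndarray


def cavity_solid(receptor_atoms, ligand_atoms, spec: CavitySpec = CavitySpec()):
    """The binding-cavity CSG tree (unmeshed)."""
    if not receptor_atoms or not ligand_atoms:
        raise ValueError("receptor and ligand atom sets must be nonempty")
    lig = union_all(
        [Sphere(a.center, spec.ligand_sphere_radius) for a in ligand_atoms]
    )
    excluded = build_molecular_solid(receptor_atoms, spec.probe_small)
    envelope = build_molecular_solid(receptor_atoms, spec.probe_large)
    return intersection(difference(lig, excluded), envelope)


def build_binding_cavity(receptor_atoms, ligand_atoms, spec: CavitySpec,
                         resolution: float, workers: int = 1) -> TriangleMesh:
    """Meshed solid representation of the ligand-bound cavity."""
    root = cavity_solid(receptor_atoms, ligand_atoms, spec)
    mesh = mesh_solid_boundary(root, resolution, workers=workers)
    if mesh.is_empty():
        log.warning("cavity is empty: ligand neighborhood does not reach the envelope")
    mesh.metadata.update(
        ligand_sphere_radius=spec.ligand_sphere_radius,
        probe_small=spec.probe_small,
        probe_large=spec.probe_large,
    )
    return mesh


def surveyor_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume by the Surveyor's formula.

    Each triangle contributes the signed volume of its tetrahedron
    against the origin; cancellations handle nonconvexity, and shells
    oriented inward (nested voids) subtract automatically.  For a single
    inward-oriented shell the sign is corrected to nonnegative.
    """
    if mesh.is_empty():
        return 0.0
    edges, counts = mesh.edge_counts()
    if np.any(counts != 2):
        raise ValueError("Surveyor volume requires a closed mesh")
    vol = mesh.signed_volume()
    if vol < 0 and len(np.unique(mesh.shell_labels())) == 1:
        vol = -vol
    return vol


def extract_fragments(mesh: TriangleMesh) -> list:
    """Connected fragments of a (possibly multi-shell) closed mesh.

    Shells are connected components of the triangle adjacency graph.
    Shells with negative signed volume are nested voids; each is assigned
    to the smallest positive shell containing it and subtracts from that
    fragment's volume.  Fragments are sorted by descending volume.
    """
    if mesh.is_empty():
        return []
    labels = mesh.shell_labels()
    shells = []
    for lab in np.unique(labels):
        sub = mesh.submesh(labels == lab)
        shells.append((sub, sub.signed_volume()))
    outers = [(s, v) for s, v in shells if v >= 0]
    voids = [(s, v) for s, v in shells if v < 0]
    frags = [
        {"mesh": s, "volume": v, "parts": [s]} for s, v in outers
    ]
    for s, v in voids:
        probe = s.vertices[0]
        best = None
        best_vol = np.inf
        for f in frags:
            if _point_in_shell(probe, f["mesh"]) and f["volume"] + v > -1e-9:
                if f["volume"] < best_vol:
                    best, best_vol = f, f["volume"]
        if best is None:
            log.warning("void shell without an enclosing fragment; keeping |volume|")
            frags.append({"mesh": s, "volume": -v, "parts": [s]})
        else:
            best["volume"] += v
            best["parts"].append(s)
    out = []
    for f in frags:
        verts = np.vstack([p.vertices for p in f["parts"]])
        faces = []
        off = 0
        for p in f["parts"]:
            faces.append(p.faces + off)
            off += p.n_vertices
        merged = TriangleMesh(verts, np.vstack(faces), dict(mesh.metadata))
        centroid = _mesh_centroid(f["parts"][0])
        out.append(Fragment(merged, float(f["volume"]), centroid))
    out.sort(key=lambda fr: -fr.volume)
    return out


def _mesh_centroid(mesh: TriangleMesh) -> np.ndarray:
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    w = np.einsum("ij,ij->i", a, np.cross(b, c))  # 6 x signed tetra volumes
    total = w.sum()
    if abs(total) < 1e-30:
        return v.mean(axis=0)
    return ((a + b + c) / 4.0 * w[:, None]).sum(axis=0) / total


def _point_in_shell(p: np.ndarray, shell: TriangleMesh) -> bool:
    """Ray-parity containment of a point against one closed shell."""
    tri = shell.vertices[shell.faces]
    lo, hi = shell.bounds()
    target = hi + np.array([1.123, 0.857, 0.641])
    from .meshsolid import segment_triangle_hits

    for k in range(8):
        ts, clean = segment_triangle_hits(p, target, tri)
        if clean:
            return len(ts) % 2 == 1
        target = hi + np.array([1.123, 0.857, 0.641]) + np.random.default_rng(k).normal(0, 1e-4, 3)
    return len(ts) % 2 == 1


# ---------------------------------------------------------------------------
# Displacement distance


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances from one point to each triangle in (m, 3, 3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    closest = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    def settle(mask, pts):
        todo = mask & ~done
        closest[todo] = pts[todo] if pts.ndim == 2 else pts
        done[todo] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex a
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex b
    settle((d6 >= 0) & (d5 <= d6), c)  # vertex c
    vc = d1 * d4 - d3 * d2
    edge_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = np.where(np.abs(d1 - d3) > 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0)
    settle(edge_ab, a + t[:, None] * ab)
    vb = d5 * d2 - d1 * d6
    edge_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = np.where(np.abs(d2 - d6) > 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0)
    settle(edge_ac, a + w[:, None] * ac)
    va = d3 * d6 - d5 * d4
    edge_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    u = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0)
    settle(edge_bc, b + u[:, None] * (c - b))
    # face interior
    denom_f = va + vb + vc
    denom_f = np.where(denom_f == 0, 1, denom_f)
    v = vb / denom_f
    w2 = vc / denom_f
    settle(np.ones(len(a), dtype=bool), a + v[:, None] * ab + w2[:, None] * ac)
    return np.linalg.norm(closest - p, axis=1)


def displacement_distance(mesh_a: TriangleMesh, mesh_b: TriangleMesh):
    """(min, mean, max) of per-vertex nearest-surface distances A -> B.

    Every vertex of ``mesh_a`` is measured to its nearest point anywhere
    on ``mesh_b`` — triangle interiors and edges included, not only
    vertices.  The measure is directional: displacement(A, B) and
    displacement(B, A) differ in general.
    """
    if mesh_a.is_empty() or mesh_b.is_empty():
        raise ValueError("displacement distance requires two nonempty meshes")
    tri = mesh_b.vertices[mesh_b.faces]
    centroids = tri.mean(axis=1)
    spread = float(np.max(np.linalg.norm(tri - centroids[:, None, :], axis=2)))
    ctree = cKDTree(centroids)
    vtree = cKDTree(mesh_b.vertices)
    pts = mesh_a.vertices
    upper, _ = vtree.query(pts)  # nearest B vertex bounds the true distance
    dists = np.empty(len(pts))
    for i, p in enumerate(pts):
        cand = ctree.query_ball_point(p, upper[i] + spread + 1e-12)
        if not cand:
            dists[i] = upper[i]
            continue
        dists[i] = float(_point_triangle_distance(p, tri[cand]).min())
    return float(dists.min()), float(dists.mean()), float(dists.max())
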