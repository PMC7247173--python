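"""Readers and writers: PDB atoms, triangle meshes, OpenDX scalar grids.

Mesh writers emit a provenance comment header (resolution, probe radii,
configuration hash) so any output can be traced back to the run that
produced it.  ASCII OFF/OBJ are written at full double precision; STL is
float32 by format.  Reading goes through trimesh for all mesh dialects.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np

from .mesh import TriangleMesh
from .molecular import DEFAULT_VDW_RADIUS, VDW_RADII, Atom

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PDB


def read_pdb_atoms(path, model: int | None = None, chains=None,
                   include_het: bool = True, het_only: bool = False,
                   resnames=None, radius_table=None):
    """Atoms from a PDB file, with van der Waals radii assigned by element.

    Alternate locations keep the highest-occupancy conformer (ties go to
    altloc 'A').  ``chains`` restricts to chain names, ``resnames`` to
    residue names (useful for picking a HETATM ligand), ``het_only``
    keeps only HETATM records.  Unknown elements get the default radius
    with a warning.
    """
    import gemmi

    table = dict(VDW_RADII)
    if radius_table:
        table.update(radius_table)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    md = st[model - 1] if model is not None else st[0]
    best: dict = {}
    n_seen = 0
    for chain in md:
        if chains and chain.name not in chains:
            continue
        for res in chain:
            is_het = res.het_flag == "H"
            if het_only and not is_het:
                continue
            if not include_het and is_het:
                continue
            if resnames and res.name not in resnames:
                continue
            for at in res:
                n_seen += 1
                key = (chain.name, res.seqid.num, res.name, at.name)
                rank = (-at.occ, at.altloc or "A")
                if key not in best or rank < best[key][0]:
                    best[key] = (rank, chain.name, res, at)
    atoms = []
    unknown = set()
    for _, chain_name, res, at in best.values():
        elem = at.element.name.upper()
        if elem not in table:
            unknown.add(elem)
        r = table.get(elem, DEFAULT_VDW_RADIUS)
        atoms.append(Atom(np.array([at.pos.x, at.pos.y, at.pos.z]), r, elem, at.serial))
    if unknown:
        log.warning("unknown elements %s assigned default radius %.2f",
                    sorted(unknown), DEFAULT_VDW_RADIUS)
    dropped = n_seen - len(atoms)
    log.info("read %d atoms from %s (%d alternate conformers dropped)",
             len(atoms), path, dropped)
    atoms.sort(key=lambda a: a.serial)
    return atoms


def write_pdb_atoms(path, atoms, het: bool = False, resname: str = "UNK"):
    """Minimal single-chain PDB writer for synthetic fixtures."""
    record = "HETATM" if het else "ATOM  "
    with open(path, "w") as fh:
        for i, a in enumerate(atoms, start=1):
            name = (a.element[:2] if len(a.element) > 1 else f" {a.element}").ljust(4)
            fh.write(
                f"{record}{i:5d} {name}{resname:>4s} A{i:4d}    "
                f"{a.center[0]:8.3f}{a.center[1]:8.3f}{a.center[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Meshes


def _provenance_lines(metadata: dict) -> list:
    items = sorted((str(k), repr(v)) for k, v in metadata.items())
    digest = hashlib.sha1(repr(items).encode()).hexdigest()[:12]
    lines = [f"{k}={v}" for k, v in items]
    lines.append(f"config_hash={digest}")
    return lines


def write_off(mesh: TriangleMesh, path):
    with open(path, "w") as fh:
        fh.write("OFF\n")
        for line in _provenance_lines(mesh.metadata):
            fh.write(f"# {line}\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_obj(mesh: TriangleMesh, path):
    with open(path, "w") as fh:
        for line in _provenance_lines(mesh.metadata):
            fh.write(f"# {line}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:  # OBJ indices are 1-based
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def write_stl(mesh: TriangleMesh, path, binary: bool = True):
    tm = mesh.to_trimesh()
    data = tm.export(file_type="stl" if binary else "stl_ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def write_mesh(mesh: TriangleMesh, path, binary_stl: bool = True):
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".off":
        write_off(mesh, path)
    elif ext == ".obj":
        write_obj(mesh, path)
    elif ext == ".stl":
        write_stl(mesh, path, binary=binary_stl)
    else:
        raise ValueError(f"unsupported mesh format {ext!r}")


def read_mesh(path) -> TriangleMesh:
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    if hasattr(tm, "geometry") and not hasattr(tm, "faces"):  # scene
        geoms = list(tm.geometry.values())
        if len(geoms) != 1:
            raise ValueError(f"{path} holds {len(geoms)} meshes, expected 1")
        tm = geoms[0]
    if str(path).lower().endswith(".stl"):
        tm.merge_vertices()  # STL stores triangles independently
    mesh = TriangleMesh.from_trimesh(tm)
    edges, counts = mesh.edge_counts()
    if len(counts) and np.any(counts != 2):
        log.warning("%s is not a closed manifold mesh (%d odd edges)",
                    path, int(np.sum(counts != 2)))
    return mesh


# ---------------------------------------------------------------------------
# OpenDX scalar grids


def write_dx(path, values: np.ndarray, origin, spacing, comments=()):
    """Scalar grid in the OpenDX dialect common to Poisson-Boltzmann tools.

    Data order is C order over (nx, ny, nz): the z index varies fastest.
    """
    v = np.asarray(values, dtype=float)
    nx, ny, nz = v.shape
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float) * np.ones(3)
    flat = v.ravel()
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"delta {spacing[0]:.9g} 0 0\n")
        fh.write(f"delta 0 {spacing[1]:.9g} 0\n")
        fh.write(f"delta 0 0 {spacing[2]:.9g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {flat.size} data follows\n")
        for s in range(0, flat.size, 3):
            fh.write(" ".join(f"{x:.10g}" for x in flat[s:s + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path):
    """Parse an OpenDX scalar grid; returns (values, origin, spacing)."""
    counts = None
    origin = None
    deltas = []
    values = []
    n_items = None
    reading = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if reading:
                if s.startswith(("attribute", "object", "component")):
                    reading = False
                else:
                    values.extend(float(x) for x in s.split())
                    if n_items is not None and len(values) >= n_items:
                        reading = False
                    continue
            if s.startswith("object") and "gridpositions" in s:
                counts = tuple(int(x) for x in s.split()[-3:])
            elif s.startswith("origin"):
                origin = np.array([float(x) for x in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append([float(x) for x in s.split()[1:4]])
            elif "data follows" in s:
                n_items = int(s.split("items")[1].split()[0])
                reading = True
    if counts is None or origin is None or len(deltas) < 3:
        raise ValueError(f"{path} is not a recognizable OpenDX scalar grid")
    delta = np.array(deltas[:3])
    if not np.allclose(delta, np.diag(np.diag(delta))):
        raise ValueError("only axis-aligned OpenDX grids are supported")
    spacing = np.diag(delta)
    v = np.array(values, dtype=float)
    if n_items is not None and v.size != n_items:
        raise ValueError(f"expected {n_items} grid values, found {v.size}")
    return v.reshape(counts), origin, spacing
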