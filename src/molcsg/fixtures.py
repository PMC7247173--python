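"""Seed-deterministic synthetic inputs.

Everything the test-suite and examples consume is generated here: mixed
collections of random primitives (the stress protocol uses unions of 30
of them), toy molecules of a few atoms shaped to exercise each stage of
the molecular-solid construction, and analytic Coulomb potential grids
standing in for the output of a Poisson-Boltzmann solver.  Identical
arguments always produce identical fixtures.
"""

from __future__ import annotations

import numpy as np

from .molecular import Atom, atom
from .primitives import Sphere, Spindle, Tetrahedron
from .molecular import spindle_between


def random_primitives(n: int, seed: int, bbox=((-10.0, -10.0, -10.0), (10.0, 10.0, 10.0))):
    """``n`` mixed spheres / tetrahedra / spindles inside ``bbox``.

    Radii and edge scales are drawn in 0.5-3 Angstroms; spindles are
    realized as the solvent-excluded neck between two synthetic atoms so
    their geometry is always valid.
    """
    if n < 1:
        raise ValueError("need n >= 1 primitives")
    rng = np.random.default_rng(seed)
    lo = np.asarray(bbox[0], dtype=float)
    hi = np.asarray(bbox[1], dtype=float)
    solids = []
    while len(solids) < n:
        kind = rng.integers(0, 3)
        center = rng.uniform(lo + 3.0, hi - 3.0)
        if kind == 0:
            solids.append(Sphere(center, float(rng.uniform(0.5, 3.0))))
        elif kind == 1:
            corners = center + rng.uniform(-1.0, 1.0, (4, 3)) * rng.uniform(0.5, 3.0)
            try:
                solids.append(Tetrahedron(corners))
            except ValueError:
                continue
        else:
            r1, r2 = rng.uniform(1.2, 2.0, 2)
            rs = float(rng.uniform(0.8, 1.6))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            d = float(rng.uniform(0.6, 0.95) * (r1 + r2 + 2 * rs))
            a = Atom(center - 0.5 * d * direction, r1)
            b = Atom(center + 0.5 * d * direction, r2)
            sp = spindle_between(a, b, rs)
            if sp is None:
                continue
            solids.append(sp)
    return solids


def toy_molecule(kind: str, seed: int = 0, n: int = 20, blocker: bool = False):
    """Small atom sets standing in for protein fixtures.

    Kinds:

    * ``dimer`` — two 1.9 Angstrom atoms 3.0 Angstroms apart (one spindle);
    * ``tetra_cluster`` — four atoms at tetrahedron corners, side 4.0;
    * ``pocket`` — a two-ring cup of atoms with a floor, optionally with a
      ``blocker`` atom inside the pocket mouth; returns
      ``(receptor_atoms, ligand_atoms)``;
    * ``chain`` — ``n`` atoms along a helix, 1.5 Angstrom rise.
    """
    rng = np.random.default_rng(seed)
    if kind == "dimer":
        return [atom(0, 0, 0, radius=1.9, serial=1), atom(3.0, 0, 0, radius=1.9, serial=2)]
    if kind == "tetra_cluster":
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        pts *= 4.0 / np.sqrt(8.0)
        return [atom(*p, radius=1.9, serial=i + 1) for i, p in enumerate(pts)]
    if kind == "pocket":
        receptor = []
        serial = 1
        for radius, z, count in ((4.0, 0.0, 8), (3.0, -2.0, 8)):
            for t in np.linspace(0.0, 2 * np.pi, count, endpoint=False):
                receptor.append(
                    atom(radius * np.cos(t), radius * np.sin(t), z, radius=1.9, serial=serial)
                )
                serial += 1
        receptor.append(atom(0.0, 0.0, -3.5, radius=1.9, serial=serial))
        serial += 1
        if blocker:
            receptor.append(atom(0.0, 0.0, -1.0, radius=1.9, serial=serial))
            serial += 1
        ligand = [atom(0.0, 0.0, 0.8, element="N", serial=serial)]
        return receptor, ligand
    if kind == "chain":
        out = []
        for i in range(n):
            t = 0.6 * i
            out.append(
                atom(2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * i * 0.5, radius=1.9, serial=i + 1)
            )
        return out
    raise ValueError(f"unknown toy molecule kind {kind!r}")


def point_charge_grid(charges, origin, spacing, shape):
    """Coulomb potential of point charges sampled on a regular grid.

    ``charges`` is a list of ``(q, (x, y, z))``; the potential is
    ``sum q_i / |x - c_i|`` in units of e/Angstrom (vacuum, unscreened).
    Distances are floored at 1e-6 Angstrom to avoid the singularity.
    """
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float) * np.ones(3)
    nx, ny, nz = shape
    ax = origin[0] + spacing[0] * np.arange(nx)
    ay = origin[1] + spacing[1] * np.arange(ny)
    az = origin[2] + spacing[2] * np.arange(nz)
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    phi = np.zeros(shape, dtype=float)
    for q, c in charges:
        r = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        phi += q / np.maximum(r, 1e-6)
    return phi
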