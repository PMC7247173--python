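"""Molecular solids: power dual, probe placement, assembly, semantics."""

import numpy as np
import pytest

from molcsg.csg import union_all
from molcsg.fixtures import toy_molecule
from molcsg.lattice import build_lattice
from molcsg.mesher import mesh_solid_boundary
from molcsg.molecular import (
    atom,
    build_molecular_solid,
    compute_power_dual,
    place_solvent_tangent_sphere,
    spindle_between,
)
from molcsg.primitives import Segment, Sphere, is_surface_cube


# ---------------------------------------------------------------------------
# Power dual


def test_two_atoms_make_one_edge_not_overlong():
    atoms = [atom(0, 0, 0, radius=1.9), atom(3.0, 0, 0, radius=1.9)]
    g = compute_power_dual(atoms, 1.4)
    assert g.edges == {(0, 1)}
    assert not g.is_overlong((0, 1))  # 3.0 < 1.9 + 1.9 + 2.8 = 6.6


def test_far_pair_is_overlong():
    atoms = [atom(0, 0, 0, radius=1.9), atom(7.0, 0, 0, radius=1.9)]
    g = compute_power_dual(atoms, 1.4)
    assert g.is_overlong((0, 1))  # 7.0 > 6.6
    assert spindle_between(atoms[0], atoms[1], 1.4) is None


def test_four_atoms_general_position_combinatorics():
    atoms = toy_molecule("tetra_cluster")
    g = compute_power_dual(atoms, 1.4)
    assert len(g.tetrahedra) == 1
    assert len(g.triangles) == 4
    assert len(g.edges) == 6


def test_larger_cluster_dual_is_consistent():
    from itertools import combinations

    atoms = toy_molecule("chain", n=12)
    g = compute_power_dual(atoms, 1.4)
    for quad in g.tetrahedra:
        for tri in combinations(quad, 3):
            assert tri in g.triangles
    for tri in g.triangles:
        for e in combinations(tri, 2):
            assert e in g.edges


# ---------------------------------------------------------------------------
# Probe placement


def test_tangent_probe_on_equilateral_triangle():
    side = 4.0
    h = side / np.sqrt(3.0)
    atoms = [
        atom(h * np.cos(a), h * np.sin(a), 0.0, radius=1.9)
        for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)
    ]
    cands = place_solvent_tangent_sphere(*atoms, 1.4)
    assert len(cands) == 2
    for c in cands:
        for a in atoms:
            assert np.linalg.norm(c - a.center) == pytest.approx(3.3, abs=1e-9)
    # mirror pair across the atom plane (z = 0)
    np.testing.assert_allclose(cands[0][:2], cands[1][:2], atol=1e-9)
    assert cands[0][2] == pytest.approx(-cands[1][2], abs=1e-9)


def test_colinear_triple_has_no_tangent_probe():
    atoms = [atom(0, 0, 0), atom(2, 0, 0), atom(4, 0, 0)]
    assert place_solvent_tangent_sphere(*atoms, 1.4) == []


def test_too_distant_triple_has_no_tangent_probe():
    atoms = [atom(0, 0, 0, radius=1.0), atom(20, 0, 0, radius=1.0), atom(0, 20, 0, radius=1.0)]
    assert place_solvent_tangent_sphere(*atoms, 1.4) == []


# ---------------------------------------------------------------------------
# Assembly


def test_single_atom_solid_is_its_sphere(rng):
    ms = build_molecular_solid([atom(1.0, 2.0, 3.0, radius=1.7)], 1.4)
    assert len(ms.spheres) == 1 and not ms.spindles and not ms.cups
    s = Sphere(np.array([1.0, 2.0, 3.0]), 1.7)
    pts = rng.uniform(-2, 6, (5000, 3))
    np.testing.assert_array_equal(ms.contains(pts), s.contains(pts))


def test_dimer_has_spindle_and_neck_is_excluded(dimer_solid):
    assert len(dimer_solid.spindles) == 1
    # analytic neck boundary at the mid-plane: rho = R - r
    sp = dimer_solid.spindles[0]
    rho_neck = sp.R - sp.r
    # a point in the neck, outside both vdW spheres, is solvent-excluded
    mid = np.array([[1.5, rho_neck - 0.1, 0.0]])
    vdw = [Sphere(a.center, a.vdw_radius) for a in dimer_solid.atoms]
    assert not any(s.contains(mid)[0] for s in vdw)
    assert dimer_solid.contains(mid)[0]
    assert dimer_solid.contains(np.array([[1.5, rho_neck - 1e-6, 0.0]]))[0]
    assert not dimer_solid.contains(np.array([[1.5, rho_neck + 1e-6, 0.0]]))[0]


def test_cluster_construction_counts(cluster_solid):
    assert len(cluster_solid.spheres) == 4
    assert len(cluster_solid.spindles) == 6
    assert len(cluster_solid.tetrahedra) == 1
    assert len(cluster_solid.cups) == 4


def test_cup_negspheres_are_tangent_to_their_atoms(cluster_solid):
    for cup in cluster_solid.cups:
        for t in cup.atom_ids:
            a = cluster_solid.atoms[t]
            d = np.linalg.norm(cup.negsphere.center - a.center)
            assert d == pytest.approx(a.vdw_radius + 1.4, abs=1e-6)


def test_negsphere_dominates_containment(cluster_solid):
    cup = cluster_solid.cups[0]
    # a point strictly inside both the cup tetra and its negsphere
    probe = cup.negsphere.center + 0.4 * (
        cup.tetra.corners[:3].mean(axis=0) - cup.negsphere.center
    )
    assert cup.tetra.contains(probe[None])[0]
    assert cup.negsphere.contains(probe[None])[0]
    assert not cluster_solid.contains(probe[None])[0]


def test_hash_equals_exhaustive_evaluation(cluster_solid, dimer_solid, rng):
    for ms in (cluster_solid, dimer_solid):
        lo, hi = ms.bounds()
        pts = rng.uniform(lo - 1, hi + 1, (10_000, 3))
        np.testing.assert_array_equal(ms.contains(pts), ms.contains_exhaustive(pts))


def test_segment_intervals_agree_with_containment(cluster_solid, rng):
    lo, hi = cluster_solid.bounds()
    for _ in range(100):
        seg = Segment.between(rng.uniform(lo - 1, hi + 1, 3), rng.uniform(lo - 1, hi + 1, 3))
        iv = cluster_solid.intersect_segment(seg)
        mids = iv.midpoints()
        if len(mids):
            assert cluster_solid.contains(seg.point(mids)).all()
        cuts = np.concatenate([[0.0], iv.boundaries(), [seg.t_max]])
        gaps = [0.5 * (a + b) for a, b in zip(cuts[:-1], cuts[1:])
                if b - a > 1e-6 and not iv.contains_t(0.5 * (a + b))]
        if gaps:
            assert not cluster_solid.contains(seg.point(np.array(gaps))).any()


def test_lone_atom_segment_is_sphere_chord():
    ms = build_molecular_solid([atom(0, 0, 0, radius=1.7)], 1.4)
    iv = ms.intersect_segment(Segment.between([-3, 0, 0], [3, 0, 0]))
    assert len(iv) == 1
    assert iv.total_length() * 6.0 == pytest.approx(3.4, rel=1e-9)


def test_starting_cubes_pass_mixed_corner_test(cluster_solid):
    lat = build_lattice(cluster_solid, 0.5)
    cubes = cluster_solid.starting_cubes(lat)
    assert len(cubes) >= 1
    for c in cubes:
        assert is_surface_cube(cluster_solid, lat, c)


def test_tangency_points_cover_all_cups(cluster_solid):
    assert all(cup.tangency_points.shape == (3, 3) for cup in cluster_solid.cups)
    # 4 cups x 3 tangency points on this fixture
    pts = np.vstack([c.tangency_points for c in cluster_solid.cups])
    assert len(pts) == 12


# ---------------------------------------------------------------------------
# Meshed molecular solids


def test_toy_molecule_meshes_are_watertight(cluster_solid, dimer_solid, watertight_check):
    for ms in (cluster_solid, dimer_solid):
        watertight_check(mesh_solid_boundary(ms, 0.25), expect_shells=1)


def test_chain_surface_watertight(watertight_check):
    ms = build_molecular_solid(toy_molecule("chain", n=12), 1.4)
    watertight_check(mesh_solid_boundary(ms, 0.5))


def test_solvent_exclusion_only_adds_volume(cluster_solid):
    vdw = union_all([Sphere(a.center, a.vdw_radius) for a in cluster_solid.atoms])
    v_vdw = mesh_solid_boundary(vdw, 0.25).signed_volume()
    v_ses = mesh_solid_boundary(cluster_solid, 0.25).signed_volume()
    assert v_ses >= v_vdw


def test_volume_monotone_in_probe_radius():
    atoms = toy_molecule("tetra_cluster")
    vols = [
        mesh_solid_boundary(build_molecular_solid(atoms, rs), 0.25).signed_volume()
        for rs in (1.0, 1.4, 2.0)
    ]
    assert vols[0] <= vols[1] <= vols[2]
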