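"""Exact leaf solids: containment, segment intersection, starting cubes."""

import numpy as np
import pytest

from molcsg.intervals import EPS_TANGENT
from molcsg.lattice import build_lattice, exhaustive_surface_cubes
from molcsg.primitives import (
    Segment,
    Sphere,
    Spindle,
    Tetrahedron,
    is_surface_cube,
    solve_torus_quartic,
    torus_implicit,
)

UNIT_TETRA = Tetrahedron([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)])


# ---------------------------------------------------------------------------
# Spheres


@pytest.mark.parametrize(
    "point,inside",
    [
        ((0, 0, 0.5), True),       # interior
        ((1.0, 0, 0), True),       # exactly on the surface counts as inside
        ((1.0000001, 0, 0), False),
    ],
)
def test_sphere_containment_boundary_rule(unit_sphere, point, inside):
    assert unit_sphere.contains_point(point) == inside


def test_sphere_chord_interval(unit_sphere):
    seg = Segment.between([-2, 0, 0], [2, 0, 0])
    iv = unit_sphere.intersect_segment(seg)
    assert len(iv) == 1
    (lo, hi), = iv
    np.testing.assert_allclose([lo, hi], [0.25, 0.75], atol=1e-12)


def test_sphere_miss_is_empty(unit_sphere):
    assert not unit_sphere.intersect_segment(Segment.between([0, 0, 5], [1, 0, 5]))


def test_sphere_tangency_yields_trivially_separated_pair(unit_sphere):
    seg = Segment.between([-2, 0, 1], [2, 0, 1])
    iv = unit_sphere.intersect_segment(seg)
    assert len(iv) == 1
    (lo, hi), = iv
    assert hi - lo == pytest.approx(2 * EPS_TANGENT, rel=1e-6)
    assert 0.5 * (lo + hi) == pytest.approx(0.5, abs=1e-12)


def test_sphere_chord_length_matches_analytic(rng):
    """Total inside length on long random segments equals the analytic chord."""
    for _ in range(50):
        c = rng.uniform(-3, 3, 3)
        r = rng.uniform(0.5, 2.5)
        s = Sphere(c, r)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        offset = rng.uniform(-0.9, 0.9) * r  # impact parameter
        perp = np.cross(d, [0.77, 0.31, 0.55])
        perp /= np.linalg.norm(perp)
        p0 = c + offset * perp - 10 * d
        seg = Segment(p0, d, 20.0)
        chord = 2.0 * np.sqrt(r * r - offset * offset)
        got = s.intersect_segment(seg).total_length()
        assert got == pytest.approx(chord, rel=1e-9)


def test_sphere_starting_cubes_are_six_surface_cubes(unit_sphere):
    lat = build_lattice(unit_sphere, 0.25)
    cubes = unit_sphere.starting_cubes(lat)
    assert len(cubes) == 6
    oracle = set(map(tuple, lat.cube_idx(exhaustive_surface_cubes(unit_sphere, lat))))
    assert cubes <= oracle
    for c in cubes:
        assert is_surface_cube(unit_sphere, lat, c)


def test_tiny_sphere_straddling_no_corner_yields_empty():
    # sphere strictly inside one cube, away from all corners
    s = Sphere(np.array([0.5, 0.5, 0.5]), 0.2)
    lat = build_lattice(Sphere(np.zeros(3), 2.0), 1.0)
    assert s.starting_cubes(lat) == set()


# ---------------------------------------------------------------------------
# Tetrahedra


@pytest.mark.parametrize(
    "point,inside",
    [
        ((0.1, 0.1, 0.1), True),
        ((0.0, 0.2, 0.2), True),  # on the x=0 face: surface is inside
        ((1.0, 1.0, 1.0), False),
    ],
)
def test_tetra_containment(point, inside):
    assert UNIT_TETRA.contains_point(point) == inside


def test_tetra_segment_clipped_by_half_planes():
    seg = Segment.between([-1, 0.2, 0.2], [2, 0.2, 0.2])
    iv = UNIT_TETRA.intersect_segment(seg)
    assert len(iv) == 1
    (lo, hi), = iv
    np.testing.assert_allclose([lo, hi], [1 / 3, 1.6 / 3], atol=1e-12)


def test_tetra_segment_along_edge_returns_overlap():
    seg = Segment.between([0, 0, 0], [1, 0, 0])
    iv = UNIT_TETRA.intersect_segment(seg)
    assert len(iv) == 1
    (lo, hi), = iv
    np.testing.assert_allclose([lo, hi], [0.0, 1.0], atol=1e-9)


def test_tetra_segment_outside_is_empty():
    assert not UNIT_TETRA.intersect_segment(Segment.between([2, 2, 2], [3, 3, 3]))


def test_degenerate_tetra_rejected():
    with pytest.raises(ValueError):
        Tetrahedron([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)])


def test_tetra_starting_cubes_pass_mixed_corner_test():
    big = Tetrahedron(np.array([(0, 0, 0), (10, 0, 0), (0, 10, 0), (0, 0, 10)], float))
    lat = build_lattice(big, 0.25)
    cubes = big.starting_cubes(lat)
    assert len(cubes) >= 1
    for c in cubes:
        assert is_surface_cube(big, lat, c)


def test_tetra_inside_one_cube_yields_empty():
    t = Tetrahedron([(0.4, 0.4, 0.4), (0.6, 0.4, 0.4), (0.4, 0.6, 0.4), (0.4, 0.4, 0.6)])
    lat = build_lattice(Sphere(np.zeros(3), 2.0), 1.0)
    assert t.starting_cubes(lat) == set()


# ---------------------------------------------------------------------------
# Torus quartic and spindles


def test_torus_quartic_annulus_cross_section():
    # in the x=0 plane the torus R=2, r=1 cuts the y axis at |y| in {1, 3}
    roots = solve_torus_quartic(2.0, 1.0, [0.0, -4.0, 0.0], [0.0, 1.0, 0.0])
    np.testing.assert_allclose(roots, [1.0, 3.0, 5.0, 7.0], atol=1e-8)


def test_torus_quartic_far_segment_has_no_real_roots():
    roots = solve_torus_quartic(2.0, 1.0, [0.0, 10.0, 10.0], [1.0, 0.0, 0.0])
    assert len(roots) == 0


def test_torus_quartic_root_residuals(rng):
    """Every returned root satisfies the torus implicit equation."""
    checked = 0
    for _ in range(200):
        R = rng.uniform(1.0, 3.0)
        r = rng.uniform(0.2, 0.9 * R)
        o = rng.uniform(-4, 4, 3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        roots = solve_torus_quartic(R, r, o, d)
        for t in roots:
            p = o + t * d
            scale = max(1.0, np.dot(p, p) ** 2)
            assert abs(torus_implicit(R, r, p[None])[0]) / scale < 1e-6
            checked += 1
    assert checked > 100


@pytest.fixture(scope="module")
def spindle():
    return Spindle(np.zeros(3), [1.0, 0.0, 0.0], R=2.0, r=1.0, cap_lo=-0.8, cap_hi=0.8)


@pytest.mark.parametrize(
    "point,inside",
    [
        ((0, 0, 0), True),        # axis center: distance to tube circle = R >= r
        ((0, 1.0, 0), True),      # exactly on the torus tube: boundary is inside
        ((0, 2.0, 0), False),     # on the tube circle itself: distance 0 < r
        ((0.9, 0, 0), False),     # beyond cap_hi
    ],
)
def test_spindle_cross_section_containment(spindle, point, inside):
    assert spindle.contains_point(point) == inside


def test_spindle_axial_segment_spans_caps(spindle):
    iv = spindle.intersect_segment(Segment.between([-2, 0, 0], [2, 0, 0]))
    assert len(iv) == 1
    (lo, hi), = iv
    np.testing.assert_allclose([lo, hi], [0.3, 0.7], atol=1e-9)


def test_spindle_radial_segment_stops_at_tube(spindle):
    iv = spindle.intersect_segment(Segment.between([0, 0, 0], [0, 3, 0]))
    assert len(iv) == 1
    (lo, hi), = iv
    assert lo == pytest.approx(0.0, abs=1e-9)
    assert hi == pytest.approx(1.0 / 3.0, abs=1e-9)  # rho = R - r = 1


def test_spindle_interval_boundaries_match_dense_sampling(spindle, rng):
    ts = np.linspace(0.0, 1.0, 10_000)
    for _ in range(10):
        p0 = rng.uniform(-3, 3, 3)
        p1 = rng.uniform(-3, 3, 3)
        seg = Segment.between(p0, p1)
        iv = spindle.intersect_segment(seg)
        inside = spindle.contains(seg.point(ts))
        flips = ts[np.flatnonzero(np.diff(inside.astype(int)))]
        bounds = iv.boundaries()
        interior_bounds = bounds[(bounds > 1e-4) & (bounds < 1 - 1e-4)]
        # every sampled sign change has a reported boundary nearby
        for f in flips:
            assert np.min(np.abs(interior_bounds - f)) < 2e-4
        # and midpoints of reported intervals are truly inside
        for m in iv.midpoints():
            assert spindle.contains(seg.point(np.array([m])))[0]


def test_spindle_starting_cubes(spindle):
    lat = build_lattice(spindle, 0.25)
    cubes = spindle.starting_cubes(lat)
    assert len(cubes) >= 1
    for c in cubes:
        assert is_surface_cube(spindle, lat, c)


def test_broken_spindle_walks_from_both_caps():
    sp = Spindle(np.zeros(3), [1.0, 0, 0], R=0.6, r=1.0, cap_lo=-0.5, cap_hi=0.5)
    assert sp.broken
    # the axis midpoint is outside a broken spindle (probe dips past it)
    assert not sp.contains_point((0.0, 0.0, 0.0))
    lat = build_lattice(sp, 0.1)
    cubes = sp.starting_cubes(lat)
    for c in cubes:
        assert is_surface_cube(sp, lat, c)


# ---------------------------------------------------------------------------
# Cross-primitive property: segment midpoints agree with containment


def _random_primitive(rng):
    kind = rng.integers(0, 3)
    if kind == 0:
        return Sphere(rng.uniform(-2, 2, 3), rng.uniform(0.3, 2.0))
    if kind == 1:
        while True:
            try:
                return Tetrahedron(rng.uniform(-2, 2, (4, 3)))
            except ValueError:
                continue
    R = rng.uniform(0.8, 2.5)
    r = rng.uniform(0.2, 1.2)
    cap = rng.uniform(0.2, 0.95) * min(r, R)
    axis = rng.normal(size=3)
    return Spindle(rng.uniform(-2, 2, 3), axis, R, r, -cap, cap)


def test_interval_midpoints_and_gaps_agree_with_containment(rng):
    for _ in range(300):
        prim = _random_primitive(rng)
        seg = Segment.between(rng.uniform(-5, 5, 3), rng.uniform(-5, 5, 3))
        iv = prim.intersect_segment(seg)
        for m in iv.midpoints():
            assert prim.contains(seg.point(np.array([m])))[0]
        outside_probes = []
        cuts = np.concatenate([[0.0], iv.boundaries(), [seg.t_max]])
        for a, b in zip(cuts[:-1], cuts[1:]):
            m = 0.5 * (a + b)
            if b - a > 1e-6 and not iv.contains_t(m):
                outside_probes.append(m)
        if outside_probes:
            got = prim.contains(seg.point(np.array(outside_probes)))
            assert not got.any()
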