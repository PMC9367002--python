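"""Energy terms: published reference points, analytic minima, invariances,
and agreement with a brute-force double-loop oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from glycocg import (
    angle_energy_g96,
    angle_energy_restricted,
    bond_energy,
    dihedral_energy,
    improper_energy,
    lj_energy,
    total_energy,
)
from glycocg.tables import AngleTerm, BondTerm, DihedralTerm, ImproperTerm, LJPair


# ---------------------------------------------------------------------------
# scalar term functions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "b,k,b0,expected",
    [
        (0.268, 12000, 0.268, 0.0),
        (0.278, 12000, 0.268, 0.6),
        (0.251, 18000, 0.251, 0.0),
    ],
)
def test_bond_energy_reference_points(b, k, b0, expected):
    assert bond_energy(b, BondTerm(1, 2, k, b0)) == pytest.approx(expected)


def test_g96_angle_reference_points():
    term = AngleTerm((1, 4, 2), 340, 85)
    assert angle_energy_g96(85, term) == 0.0
    expected = 0.5 * 340 * (math.cos(math.radians(95))
                            - math.cos(math.radians(85))) ** 2
    assert angle_energy_g96(95, term) == pytest.approx(expected)
    assert expected == pytest.approx(5.17, abs=0.01)


def test_g96_angle_symmetric_about_90():
    term = AngleTerm((1, 2, 3), 100, 90)
    for delta in (1, 5, 20):
        assert angle_energy_g96(90 + delta, term) == pytest.approx(
            angle_energy_g96(90 - delta, term))


def test_restricted_angle_dominates_g96_and_diverges():
    reb = AngleTerm((2, 8, 6), 240, 148, form="restricted")
    plain = AngleTerm((2, 8, 6), 240, 148)
    assert angle_energy_restricted(148, reb) == 0.0
    assert angle_energy_restricted(170, reb) > angle_energy_g96(170, plain)
    # divergence toward 180 deg: monotone growth, ~1/sin^2 asymptotics
    assert (angle_energy_restricted(179.99, reb)
            > angle_energy_restricted(179.9, reb)
            > angle_energy_restricted(179.0, reb)
            > angle_energy_restricted(170.0, reb))
    assert angle_energy_restricted(179.9, reb) > 1e4 * angle_energy_restricted(
        160, reb)
    assert angle_energy_restricted(179.99, reb) > 1e6 * angle_energy_restricted(
        160, reb)
    assert angle_energy_restricted(180, reb) == math.inf
    assert angle_energy_restricted(0, reb) == math.inf


def test_improper_energy_wraps_minimum_image():
    term = ImproperTerm((4, 3, 2, 1), 200, 9)
    assert improper_energy(9, term) == 0.0
    assert improper_energy(11, term) == pytest.approx(0.5 * 200 * 4)  # 400
    wrap = ImproperTerm((4, 3, 2, 1), 200, 179)
    assert improper_energy(-179, wrap) == pytest.approx(0.5 * 200 * 4)


def test_dihedral_energy_reference_points():
    term = DihedralTerm((4, 2, 8, 6), -12.8, 161, 1)
    assert dihedral_energy(161, term) == pytest.approx(-25.6)
    assert dihedral_energy(161 + 180, term) == pytest.approx(0.0, abs=1e-12)


@given(st.floats(-720, 720), st.integers(1, 6))
def test_dihedral_energy_periodic(phi, m):
    term = DihedralTerm((1, 2, 3, 4), 3.0, 60.0, m)
    assert dihedral_energy(phi, term) == pytest.approx(
        dihedral_energy(phi + 360.0 / m, term), abs=1e-9)


def test_lj_energy_shape():
    pair = LJPair("P3", "P3", 0.19402, 2.0914e-3)
    rmin = (2 * pair.C12 / pair.C6) ** (1 / 6)
    assert lj_energy(rmin, pair) == pytest.approx(-pair.C6**2 / (4 * pair.C12))
    assert lj_energy(10.0, pair) < 0  # attractive tail approaches 0 from below
    assert abs(lj_energy(10.0, pair)) < 1e-6
    repulsive = LJPair("X", "X", 0.0, 1e-4)
    assert lj_energy(0.3, repulsive) > 0
    assert lj_energy(0.0, pair) == math.inf


# ---------------------------------------------------------------------------
# analytic minima vs numerical minimization
# ---------------------------------------------------------------------------


def _numeric_min(fn, lo, hi):
    grid = np.arange(lo, hi, 1e-2)
    best = grid[np.argmin([fn(v) for v in grid])]
    res = minimize_scalar(fn, bounds=(best - 2e-2, best + 2e-2),
                          method="bounded", options={"xatol": 1e-6})
    return res.x, res.fun


def test_each_term_minimum_matches_numeric_scan():
    bond = BondTerm(1, 2, 24000, 0.291)
    x, v = _numeric_min(lambda b: bond_energy(b, bond), 0.1, 0.6)
    assert x == pytest.approx(0.291, abs=1e-4) and v == pytest.approx(0, abs=1e-9)

    ang = AngleTerm((1, 2, 3), 450, 81)
    x, v = _numeric_min(lambda t: angle_energy_g96(t, ang), 1, 179)
    assert x == pytest.approx(81, abs=1e-4) and v == pytest.approx(0, abs=1e-9)

    reb = AngleTerm((1, 2, 3), 80, 148, form="restricted")
    x, v = _numeric_min(lambda t: angle_energy_restricted(t, reb), 1, 179)
    assert x == pytest.approx(148, abs=1e-4) and v == pytest.approx(0, abs=1e-9)

    imp = ImproperTerm((1, 2, 3, 4), 200, 9)
    x, v = _numeric_min(lambda t: improper_energy(t, imp), -179, 180)
    assert x == pytest.approx(9, abs=1e-4) and v == pytest.approx(0, abs=1e-9)

    # negative k: torsion minimum sits at the phase shift itself
    neg = DihedralTerm((1, 2, 3, 4), -12.8, 161, 1)
    x, v = _numeric_min(lambda t: dihedral_energy(t, neg), -179, 180)
    assert x == pytest.approx(161, abs=1e-4)
    assert v == pytest.approx(2 * -12.8, abs=1e-9)
    # positive k: minimum offset by half a period
    pos = DihedralTerm((1, 2, 3, 4), 3.0, 60, 2)
    x, v = _numeric_min(lambda t: dihedral_energy(t, pos), 0, 180)
    assert x == pytest.approx((60 + 180) / 2, abs=1e-4)
    assert v == pytest.approx(0, abs=1e-9)

    pair = LJPair("A", "A", 0.0646, 3.0686e-4)
    x, v = _numeric_min(lambda r: lj_energy(r, pair), 0.2, 1.5)
    assert x == pytest.approx((2 * pair.C12 / pair.C6) ** (1 / 6), abs=1e-4)
    assert v == pytest.approx(-pair.C6**2 / (4 * pair.C12), rel=1e-6)


# ---------------------------------------------------------------------------
# total energy: oracle, invariance, cutoff behaviour
# ---------------------------------------------------------------------------


def _angle_deg(p0, p1, p2):
    u, v = p0 - p1, p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _dihedral_deg(p0, p1, p2, p3):
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))


def brute_force_total(topology, positions, lj_table, cutoff=1.1):
    """Independent O(n^2) double-loop evaluation over all terms and pairs."""
    pos = np.asarray(positions)
    e = 0.0
    for t in topology.bonds:
        i, j = (b - 1 for b in t.beads)
        e += bond_energy(np.linalg.norm(pos[j] - pos[i]), t)
    for t in topology.angles:
        i, j, k = (b - 1 for b in t.beads)
        theta = _angle_deg(pos[i], pos[j], pos[k])
        if t.form == "restricted":
            e += angle_energy_restricted(theta, t)
        else:
            e += angle_energy_g96(theta, t)
    for t in topology.impropers:
        i, j, k, l = (b - 1 for b in t.beads)
        e += improper_energy(_dihedral_deg(pos[i], pos[j], pos[k], pos[l]), t)
    for t in topology.dihedrals:
        i, j, k, l = (b - 1 for b in t.beads)
        e += dihedral_energy(_dihedral_deg(pos[i], pos[j], pos[k], pos[l]), t)
    types = [b.bead_type for b in topology.beads]
    n = len(pos)
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i + 1, j + 1)) in topology.exclusions:
                continue
            r = np.linalg.norm(pos[j] - pos[i])
            if r <= cutoff:
                pair = lj_table.lookup(types[i], types[j])
                e += lj_energy(r, pair) - lj_energy(cutoff, pair)
    return e


def test_total_energy_equals_brute_force_oracle(
        tables, octamer_topologies, a14_octamer_conformation, rng):
    top = octamer_topologies["a14"]
    for _ in range(3):
        pos = a14_octamer_conformation.positions + 0.02 * rng.standard_normal(
            (top.n_beads, 3))
        expected = brute_force_total(top, pos, tables.lj_table)
        got = total_energy(top, pos, lj_table=tables.lj_table).total
        assert got == pytest.approx(expected, rel=1e-9)


def test_total_energy_equals_oracle_on_monomer(tables, monomer_topology, rng):
    pos = rng.uniform(-0.3, 0.3, size=(4, 3))
    expected = brute_force_total(monomer_topology, pos, tables.lj_table)
    got = total_energy(monomer_topology, pos, lj_table=tables.lj_table).total
    assert got == pytest.approx(expected, rel=1e-9)


def test_energy_invariant_under_rigid_motion(
        octamer_topologies, a14_octamer_conformation, tables, rng):
    top = octamer_topologies["a14"]
    pos = a14_octamer_conformation.positions
    e0 = total_energy(top, pos, lj_table=tables.lj_table).total
    for i in range(5):
        rot = Rotation.random(random_state=np.random.RandomState(i))
        moved = rot.apply(pos) + rng.uniform(-5, 5, size=3)
        e = total_energy(top, moved, lj_table=tables.lj_table).total
        assert e == pytest.approx(e0, rel=1e-9)


def test_lj_shift_vanishes_at_cutoff(tables, dimer_topologies):
    """Two beads exactly at (or beyond) the 1.1 nm cutoff contribute zero."""
    top = dimer_topologies["a14"]
    base = np.zeros((8, 3))
    base[:, 0] = np.arange(8) * 10.0  # everything far apart
    rep0 = total_energy(top, base, lj_table=tables.lj_table)
    assert rep0.lj == 0.0
    # bead pair precisely at the cutoff distance
    base[1] = base[0] + np.array([1.1, 0.0, 0.0])
    rep1 = total_energy(top, base, lj_table=tables.lj_table)
    assert rep1.lj == pytest.approx(0.0, abs=1e-12)
    # just inside the cutoff the shifted potential is continuous and nonzero
    base[1] = base[0] + np.array([1.0999, 0.0, 0.0])
    rep2 = total_energy(top, base, lj_table=tables.lj_table)
    assert rep2.lj != 0.0 and abs(rep2.lj) < 1e-3


def test_report_classes_sum_to_total(
        octamer_topologies, a14_octamer_conformation, tables):
    rep = total_energy(octamer_topologies["a14"],
                       a14_octamer_conformation, lj_table=tables.lj_table)
    assert rep.total == pytest.approx(rep.bonded + rep.lj)
    assert rep.bonded == pytest.approx(
        rep.bond + rep.angle_g96 + rep.angle_restricted + rep.improper
        + rep.dihedral)


def test_size_mismatch_raises(monomer_topology):
    with pytest.raises(ValueError, match="shape"):
        total_energy(monomer_topology, np.zeros((5, 3)))
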