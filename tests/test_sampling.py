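"""Monte Carlo sampling, parameter recovery, descriptors and SASA."""

import math

import numpy as np
import pytest

from glycocg.sampling import (
    KB_KJ_PER_MOL_K,
    RunningStats,
    bead_sasa,
    compute_descriptors,
    default_selections,
    dihedral_histogram,
    mc_sample,
)
from glycocg.sampling import DescriptorSelections
from glycocg.tables import AngleTerm, BondTerm, DihedralTerm, ImproperTerm
from glycocg.topology import Bead, Topology


def toy_topology(bonds=(), angles=(), impropers=(), dihedrals=(), n_beads=2):
    beads = [Bead(i + 1, f"B{i % 4 + 1}", i // 4 + 1, "P3", "R", 72.0)
             for i in range(n_beads)]
    top = Topology("toy", beads, list(bonds), list(angles), list(impropers),
                   list(dihedrals))
    top.exclusions = {frozenset(b.beads) for b in top.bonds}
    return top


def chain_coords(lengths, angles_deg_, dihedral_deg=None):
    """Place a 2-4 bead chain from internal coordinates (NERF-style)."""
    pts = [np.zeros(3), np.array([lengths[0], 0.0, 0.0])]
    if len(lengths) > 1:
        t = math.radians(180.0 - angles_deg_[0])
        pts.append(pts[1] + lengths[1]
                   * np.array([math.cos(t), math.sin(t), 0.0]))
    if len(lengths) > 2:
        t = math.radians(180.0 - angles_deg_[1])
        phi = math.radians(dihedral_deg)
        d = np.array([math.cos(t),
                      math.sin(t) * math.cos(phi),
                      math.sin(t) * math.sin(phi)])
        b2 = pts[2] - pts[1]
        b2 /= np.linalg.norm(b2)
        b1 = pts[1] - pts[0]
        n = np.cross(b1, b2)
        n /= np.linalg.norm(n)
        m = np.cross(n, b2)
        frame = np.column_stack([b2, m, n])
        pts.append(pts[2] + lengths[2] * frame @ d)
    return np.array(pts)


# ---------------------------------------------------------------------------
# sampler behaviour
# ---------------------------------------------------------------------------

BOND = BondTerm(1, 2, 12000, 0.268)


def test_mc_deterministic_for_seed():
    top = toy_topology([BOND])
    start = np.array([[0.0, 0, 0], [0.268, 0, 0]])
    kwargs = dict(temperature=298.0, n_steps=3000, step_size=0.02, seed=5,
                  start=start, include_lj=False)
    a = mc_sample(top, **kwargs)
    b = mc_sample(top, **kwargs)
    assert np.array_equal(a.frames, b.frames)
    assert a.acceptance_rate == b.acceptance_rate


def test_mc_rejects_empty_topology():
    with pytest.raises(ValueError, match="no beads"):
        mc_sample(toy_topology(n_beads=0), 300.0, 100)


def test_mc_validates_conditions():
    top = toy_topology([BOND])
    with pytest.raises(ValueError, match="temperature"):
        mc_sample(top, -1.0, 100)
    with pytest.raises(ValueError, match="n_steps"):
        mc_sample(top, 300.0, 0)


def test_bond_fluctuation_matches_equipartition():
    """var(b) ~ k_B T / k_b for the harmonic stretch, within 5%."""
    top = toy_topology([BOND])
    start = np.array([[0.0, 0, 0], [0.268, 0, 0]])
    ens = mc_sample(top, 298.0, 150000, step_size=0.03, seed=7, start=start,
                    sample_every=10, include_lj=False)
    b = np.linalg.norm(ens.frames[:, 1] - ens.frames[:, 0], axis=1)
    expected = KB_KJ_PER_MOL_K * 298.0 / BOND.k_b
    assert b.var() == pytest.approx(expected, rel=0.05)


def test_low_temperature_recovers_reference_geometry():
    """Low-T means recover b0, theta0 and xi0 within 1% on minimal systems."""
    # bond
    top = toy_topology([BOND])
    start = np.array([[0.0, 0, 0], [0.268, 0, 0]])
    ens = mc_sample(top, 5.0, 40000, step_size=0.004, seed=3, start=start,
                    sample_every=10, include_lj=False)
    b = np.linalg.norm(ens.frames[:, 1] - ens.frames[:, 0], axis=1)
    assert b.mean() == pytest.approx(0.268, rel=0.01)
    # angle
    top3 = toy_topology(
        bonds=[BondTerm(1, 2, 20000, 0.28), BondTerm(2, 3, 20000, 0.28)],
        angles=[AngleTerm((1, 2, 3), 340, 85)], n_beads=3)
    start3 = chain_coords([0.28, 0.28], [85])
    ens3 = mc_sample(top3, 30.0, 60000, step_size=0.008, seed=9, start=start3,
                     sample_every=10, include_lj=False)
    d = compute_descriptors(ens3.frames,
                            DescriptorSelections(angles=[(1, 2, 3)],
                                                 end_to_end=False,
                                                 radius_of_gyration=False))
    mean_theta = d.summary["theta(1-2-3)"][0]
    assert mean_theta == pytest.approx(85, rel=0.01)
    # improper
    top4 = toy_topology(
        bonds=[BondTerm(1, 2, 20000, 0.28), BondTerm(2, 3, 20000, 0.28),
               BondTerm(3, 4, 20000, 0.28)],
        angles=[AngleTerm((1, 2, 3), 340, 100), AngleTerm((2, 3, 4), 340, 100)],
        impropers=[ImproperTerm((1, 2, 3, 4), 200, 9)], n_beads=4)
    start4 = chain_coords([0.28, 0.28, 0.28], [100, 100], dihedral_deg=9)
    ens4 = mc_sample(top4, 30.0, 80000, step_size=0.008, seed=13, start=start4,
                     sample_every=10, include_lj=False)
    d4 = compute_descriptors(ens4.frames,
                             DescriptorSelections(impropers=[(1, 2, 3, 4)],
                                                  end_to_end=False,
                                                  radius_of_gyration=False))
    assert d4.summary["xi(1-2-3-4)"][0] == pytest.approx(9, rel=0.01)


def test_torsion_mode_at_analytic_minimum():
    """Low-T sampling of the alpha(1->4) glycosidic torsion puts the
    distribution mode within one bin of the term's analytic minimum."""
    term = DihedralTerm((1, 2, 3, 4), -12.8, 161, 1)
    top = toy_topology(
        bonds=[BondTerm(1, 2, 60000, 0.292), BondTerm(2, 3, 32000, 0.280),
               BondTerm(3, 4, 60000, 0.292)],
        angles=[AngleTerm((1, 2, 3), 180, 103, form="restricted"),
                AngleTerm((2, 3, 4), 240, 148, form="restricted")],
        dihedrals=[term], n_beads=4)
    start = chain_coords([0.292, 0.280, 0.292], [103, 148], dihedral_deg=100)
    ens = mc_sample(top, 50.0, 60000, step_size=0.01, seed=21, start=start,
                    sample_every=20, include_lj=False)
    centers, probs = dihedral_histogram(ens, quadruplet=(1, 2, 3, 4),
                                        bin_width=10.0)
    mode = centers[np.argmax(probs)]
    assert abs(mode - 161.0) <= 10.0


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------


def test_histogram_uniform_is_flat(rng):
    values = rng.uniform(-180, 180, size=200000)
    centers, probs = dihedral_histogram(values, bin_width=10.0)
    assert len(centers) == 36
    assert probs.sum() == 1.0
    assert np.all(np.abs(probs - 1 / 36) < 0.002)


def test_histogram_bin_width_must_divide_360():
    with pytest.raises(ValueError, match="divide 360"):
        dihedral_histogram(np.zeros(10), bin_width=7.0)


def test_histogram_wraps_into_half_open_interval():
    centers, probs = dihedral_histogram(np.array([180.0, -180.0, 540.0]),
                                        bin_width=10.0)
    assert probs.sum() == 1.0
    assert probs[-1] == 1.0  # all three values are the same angle, +180


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------


def test_two_bead_descriptors_closed_form():
    frames = np.array([[[0.0, 0, 0], [0.8, 0, 0]]])
    d = compute_descriptors(frames)
    assert d.summary["e2e"][0] == pytest.approx(0.8)
    assert d.summary["rg"][0] == pytest.approx(0.4)  # equal masses: d/2


def test_collinear_angle_is_180():
    frames = np.array([[[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]])
    d = compute_descriptors(frames, DescriptorSelections(
        angles=[(1, 2, 3)], end_to_end=False, radius_of_gyration=False))
    assert d.summary["theta(1-2-3)"][0] == pytest.approx(180.0)


def test_streaming_and_two_pass_statistics_agree(rng):
    values = rng.standard_normal(5000) * 3.2 + 1.7
    stats = RunningStats()
    for v in values:
        stats.push(float(v))
    assert stats.mean == pytest.approx(values.mean(), rel=1e-12)
    assert stats.variance == pytest.approx(values.var(), rel=1e-12)


def test_invalid_selection_rejected():
    frames = np.zeros((2, 4, 3))
    with pytest.raises(ValueError, match="nonexistent"):
        compute_descriptors(frames, DescriptorSelections(distances=[(1, 9)]))


def test_default_selections_use_chain_centre(octamer_topologies):
    sel = default_selections(octamer_topologies["a14"])
    referenced = {b for group in (sel.distances, sel.angles, sel.impropers,
                                  sel.dihedrals) for term in group for b in term}
    # residues 4 and 5 occupy beads 13..20
    assert referenced and min(referenced) >= 13 and max(referenced) <= 24


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def test_single_bead_sasa_matches_sphere_area():
    r, probe = 0.235, 0.14
    total, per = bead_sasa(np.zeros((1, 3)), [r], probe=probe, n_points=1000)
    exact = 4 * math.pi * (r + probe) ** 2
    assert total == pytest.approx(exact, rel=0.01)
    assert per[0] == total


def test_distant_beads_sasa_additive():
    pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
    total, per = bead_sasa(pos, [0.2, 0.3], probe=0.1, n_points=1000)
    assert total == pytest.approx(per.sum())
    assert per[0] == pytest.approx(4 * math.pi * 0.3**2, rel=0.01)
    assert per[1] == pytest.approx(4 * math.pi * 0.4**2, rel=0.01)


def test_buried_bead_contributes_nothing():
    pos = np.zeros((2, 3))
    total, per = bead_sasa(pos, [0.5, 0.1], probe=0.05, n_points=1000)
    assert per[1] == 0.0
    assert per[0] == pytest.approx(4 * math.pi * 0.55**2, rel=0.01)


def test_sasa_validates_inputs():
    with pytest.raises(ValueError, match="positive"):
        bead_sasa(np.zeros((1, 3)), [-0.1])
    with pytest.raises(ValueError, match="n_points"):
        bead_sasa(np.zeros((1, 3)), [0.2], n_points=10)
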