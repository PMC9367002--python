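"""Potential-energy evaluation for the coarse-grained carbohydrate model.

Functional forms
----------------
* bond stretch           V = 1/2 k_b (b - b0)^2
* angle bend (cosine)    V = 1/2 k_t (cos t - cos t0)^2
* restricted bend        V = 1/2 k_t (cos t - cos t0)^2 / sin^2 t
* improper dihedral      V = 1/2 k_x (dxi)^2, dxi wrapped minimum-image
* proper dihedral        V = k_p (1 + cos(m phi - phi0))
* Lennard-Jones 12/6     V = C12/r^12 - C6/r^6, shifted to zero at the cutoff

Angles are degrees at every public interface and radians internally.  The
restricted bend is reported as +inf within 1e-6 degrees of 0/180 rather than
NaN.  Nonbonded interactions run over all bead pairs except the first covalent
neighbours (the exclusion list of the topology).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tables import AngleTerm, BondTerm, DihedralTerm, ImproperTerm, LJPair, LJTable
from .topology import Topology

__all__ = [
    "bond_energy",
    "angle_energy_g96",
    "angle_energy_restricted",
    "improper_energy",
    "dihedral_energy",
    "lj_energy",
    "total_energy",
    "EnergyReport",
    "CompiledSystem",
    "distances",
    "angles_deg",
    "dihedrals_deg",
    "wrap_angle",
]

_RESTRICTED_GUARD_DEG = 1e-6
DEFAULT_CUTOFF_NM = 1.1


# ---------------------------------------------------------------------------
# scalar term functions
# ---------------------------------------------------------------------------


def bond_energy(b: float, term: BondTerm) -> float:
    """Harmonic stretch energy at bond length ``b`` (nm), in kJ/mol."""
    return 0.5 * term.k_b * (b - term.b0) ** 2


def angle_energy_g96(theta: float, term: AngleTerm) -> float:
    """Cosine-harmonic bend energy at angle ``theta`` (degrees)."""
    d = math.cos(math.radians(theta)) - math.cos(math.radians(term.theta0))
    return 0.5 * term.k_theta * d * d


def angle_energy_restricted(theta: float, term: AngleTerm) -> float:
    """Restricted bend energy; diverges as theta approaches 0 or 180 deg."""
    if theta <= _RESTRICTED_GUARD_DEG or theta >= 180.0 - _RESTRICTED_GUARD_DEG:
        return math.inf
    t = math.radians(theta)
    d = math.cos(t) - math.cos(math.radians(term.theta0))
    return 0.5 * term.k_theta * d * d / math.sin(t) ** 2


def wrap_angle(delta: float):
    """Wrap an angle difference (degrees) to the minimum image (-180, 180]."""
    return -((-np.asarray(delta) + 180.0) % 360.0 - 180.0)


def improper_energy(xi: float, term: ImproperTerm) -> float:
    """Harmonic improper energy using the minimum-image angle difference."""
    d = float(wrap_angle(xi - term.xi0))
    return 0.5 * term.k_xi * d * d


def dihedral_energy(phi: float, term: DihedralTerm) -> float:
    """Periodic torsion energy; period 360/m degrees."""
    arg = math.radians(term.multiplicity * phi - term.phi0)
    return term.k_phi * (1.0 + math.cos(arg))


def lj_energy(r: float, pair: LJPair) -> float:
    """Unshifted 12/6 Lennard-Jones energy at separation ``r`` (nm)."""
    if r == 0:
        return math.inf
    inv6 = 1.0 / r**6
    return pair.C12 * inv6 * inv6 - pair.C6 * inv6


# ---------------------------------------------------------------------------
# vectorized geometry
# ---------------------------------------------------------------------------


def distances(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pairwise distances for an (m, 2) array of 0-based bead indices."""
    d = x[idx[:, 1]] - x[idx[:, 0]]
    return np.linalg.norm(d, axis=1)


def angles_deg(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Bend angles (degrees) for an (m, 3) index array, vertex in column 1."""
    u = x[idx[:, 0]] - x[idx[:, 1]]
    v = x[idx[:, 2]] - x[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedrals_deg(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Signed torsion angles (degrees) for an (m, 4) index array."""
    b1 = x[idx[:, 1]] - x[idx[:, 0]]
    b2 = x[idx[:, 2]] - x[idx[:, 1]]
    b3 = x[idx[:, 3]] - x[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    m1 = np.cross(n1, b2n)
    y = np.einsum("ij,ij->i", m1, n2)
    xcomp = np.einsum("ij,ij->i", n1, n2)
    return np.degrees(np.arctan2(y, xcomp))


# ---------------------------------------------------------------------------
# compiled system and totals
# ---------------------------------------------------------------------------


@dataclass
class EnergyReport:
    """Per-class and per-term potential-energy breakdown, kJ/mol."""

    bond: float = 0.0
    angle_g96: float = 0.0
    angle_restricted: float = 0.0
    improper: float = 0.0
    dihedral: float = 0.0
    lj: float = 0.0
    per_term: dict = field(default_factory=dict)

    @property
    def bonded(self) -> float:
        return (self.bond + self.angle_g96 + self.angle_restricted
                + self.improper + self.dihedral)

    @property
    def total(self) -> float:
        return self.bonded + self.lj

    def as_dict(self) -> dict:
        return {
            "bond": self.bond,
            "angle_g96": self.angle_g96,
            "angle_restricted": self.angle_restricted,
            "improper": self.improper,
            "dihedral": self.dihedral,
            "lj": self.lj,
            "total": self.total,
        }


class CompiledSystem:
    """Topology flattened into index/parameter arrays for fast evaluation.

    ``clamp_restricted`` replaces the restricted-bend divergence by a very
    large finite value, which keeps gradient-based relaxations out of NaN
    territory; the default (False) reports +inf as the public contract states.
    """

    def __init__(self, topology: Topology, lj_table: LJTable | None = None,
                 cutoff: float = DEFAULT_CUTOFF_NM, shift: bool = True,
                 clamp_restricted: bool = False, include_lj: bool = True):
        self.topology = topology
        self.cutoff = float(cutoff)
        self.shift = shift
        self.clamp_restricted = clamp_restricted
        n = topology.n_beads

        def idx(terms, width=2):
            if not terms:
                return np.empty((0, width), dtype=int)
            arr = [t.beads for t in terms]
            return np.asarray(arr, dtype=int) - 1

        self.bond_idx = idx(topology.bonds)
        self.bond_k = np.array([t.k_b for t in topology.bonds])
        self.bond_b0 = np.array([t.b0 for t in topology.bonds])

        g96 = [t for t in topology.angles if t.form == "g96"]
        res = [t for t in topology.angles if t.form == "restricted"]
        self.g96_idx = idx(g96)
        self.g96_k = np.array([t.k_theta for t in g96])
        self.g96_cos0 = np.cos(np.radians([t.theta0 for t in g96]))
        self.res_idx = idx(res)
        self.res_k = np.array([t.k_theta for t in res])
        self.res_cos0 = np.cos(np.radians([t.theta0 for t in res]))

        self.imp_idx = idx(topology.impropers)
        self.imp_k = np.array([t.k_xi for t in topology.impropers])
        self.imp_xi0 = np.array([t.xi0 for t in topology.impropers])

        self.dih_idx = idx(topology.dihedrals)
        self.dih_k = np.array([t.k_phi for t in topology.dihedrals])
        self.dih_phi0 = np.array([t.phi0 for t in topology.dihedrals])
        self.dih_m = np.array([t.multiplicity for t in topology.dihedrals])

        # nonbonded pair list: all i<j except first covalent neighbours
        self.include_lj = include_lj
        if include_lj and n > 1:
            if lj_table is None:
                from .tables import ForceFieldTables
                lj_table = ForceFieldTables().lj_table
            types = [b.bead_type for b in topology.beads]
            ii, jj = np.triu_indices(n, k=1)
            keep = np.array(
                [frozenset((int(i) + 1, int(j) + 1)) not in topology.exclusions
                 for i, j in zip(ii, jj)]
            )
            ii, jj = ii[keep], jj[keep]
            self.pair_idx = np.column_stack([ii, jj])
            c6 = np.empty(len(ii))
            c12 = np.empty(len(ii))
            for m, (i, j) in enumerate(zip(ii, jj)):
                p = lj_table.lookup(types[i], types[j])
                c6[m], c12[m] = p.C6, p.C12
            self.pair_c6 = c6
            self.pair_c12 = c12
            rc6 = self.cutoff**6
            self.pair_vshift = (c12 / rc6**2 - c6 / rc6) if shift else 0.0
        else:
            self.pair_idx = np.empty((0, 2), dtype=int)
            self.pair_c6 = np.empty(0)
            self.pair_c12 = np.empty(0)
            self.pair_vshift = np.empty(0)

    # -- evaluators ---------------------------------------------------------

    def energy_report(self, x: np.ndarray) -> EnergyReport:
        x = np.asarray(x, dtype=float).reshape(-1, 3)
        rep = EnergyReport()
        if len(self.bond_idx):
            b = distances(x, self.bond_idx)
            per = 0.5 * self.bond_k * (b - self.bond_b0) ** 2
            rep.per_term["bond"] = per
            rep.bond = float(per.sum())
        if len(self.g96_idx):
            th = np.radians(angles_deg(x, self.g96_idx))
            per = 0.5 * self.g96_k * (np.cos(th) - self.g96_cos0) ** 2
            rep.per_term["angle_g96"] = per
            rep.angle_g96 = float(per.sum())
        if len(self.res_idx):
            thdeg = angles_deg(x, self.res_idx)
            th = np.radians(thdeg)
            sin2 = np.sin(th) ** 2
            bad = (thdeg <= _RESTRICTED_GUARD_DEG) | (
                thdeg >= 180.0 - _RESTRICTED_GUARD_DEG)
            with np.errstate(divide="ignore", invalid="ignore"):
                per = 0.5 * self.res_k * (np.cos(th) - self.res_cos0) ** 2 / sin2
            if self.clamp_restricted:
                per = np.where(bad | ~np.isfinite(per), 1e12, per)
            else:
                per = np.where(bad, np.inf, per)
            rep.per_term["angle_restricted"] = per
            rep.angle_restricted = float(per.sum())
        if len(self.imp_idx):
            xi = dihedrals_deg(x, self.imp_idx)
            d = wrap_angle(xi - self.imp_xi0)
            per = 0.5 * self.imp_k * d * d
            rep.per_term["improper"] = per
            rep.improper = float(per.sum())
        if len(self.dih_idx):
            phi = dihedrals_deg(x, self.dih_idx)
            per = self.dih_k * (
                1.0 + np.cos(np.radians(self.dih_m * phi - self.dih_phi0))
            )
            rep.per_term["dihedral"] = per
            rep.dihedral = float(per.sum())
        if len(self.pair_idx):
            r = distances(x, self.pair_idx)
            with np.errstate(divide="ignore"):
                inv6 = 1.0 / r**6
            v = self.pair_c12 * inv6 * inv6 - self.pair_c6 * inv6 - self.pair_vshift
            per = np.where(r <= self.cutoff, v, 0.0)
            rep.per_term["lj"] = per
            rep.lj = float(per.sum())
        return rep

    def energy(self, x: np.ndarray) -> float:
        return self.energy_report(x).total

    def bonded_energy(self, x: np.ndarray) -> float:
        rep = self.energy_report(np.asarray(x))
        return rep.bonded

    # -- analytic bonded gradient (used by the structure relaxer) -----------

    def bonded_energy_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Bonded energy and its analytic gradient.

        The restricted-bend denominator is clamped away from zero here so a
        gradient-based relaxation sees a steep but finite wall at collinear
        triplets instead of an infinity.
        """
        x = np.asarray(x, dtype=float).reshape(-1, 3)
        grad = np.zeros_like(x)
        energy = 0.0

        if len(self.bond_idx):
            i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
            d = x[j] - x[i]
            b = np.linalg.norm(d, axis=1)
            db = b - self.bond_b0
            energy += float((0.5 * self.bond_k * db**2).sum())
            f = (self.bond_k * db / b)[:, None] * d
            np.add.at(grad, i, -f)
            np.add.at(grad, j, f)

        def angle_contrib(idx, k, cos0, restricted):
            nonlocal energy
            i, j, l = idx[:, 0], idx[:, 1], idx[:, 2]
            u = x[i] - x[j]
            v = x[l] - x[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
            dc = c - cos0
            if restricted:
                sin2 = np.maximum(1.0 - c * c, 1e-6)
                energy += float((0.5 * k * dc**2 / sin2).sum())
                dVdc = k * dc * (1.0 - cos0 * c) / sin2**2
            else:
                energy += float((0.5 * k * dc**2).sum())
                dVdc = k * dc
            dcdi = (v / (nu * nv)[:, None]) - (c / nu**2)[:, None] * u
            dcdl = (u / (nu * nv)[:, None]) - (c / nv**2)[:, None] * v
            gi = dVdc[:, None] * dcdi
            gl = dVdc[:, None] * dcdl
            np.add.at(grad, i, gi)
            np.add.at(grad, l, gl)
            np.add.at(grad, j, -(gi + gl))

        if len(self.g96_idx):
            angle_contrib(self.g96_idx, self.g96_k, self.g96_cos0, False)
        if len(self.res_idx):
            angle_contrib(self.res_idx, self.res_k, self.res_cos0, True)

        def torsion_contrib(idx, dVdphi_rad_fn, energy_fn):
            """Shared machinery for proper and improper dihedrals."""
            nonlocal energy
            p1, p2, p3, p4 = (x[idx[:, m]] for m in range(4))
            b1 = p2 - p1
            b2 = p3 - p2
            b3 = p4 - p3
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            m1 = np.cross(n1, b2 / nb2[:, None])
            phi = np.degrees(
                np.arctan2(np.einsum("ij,ij->i", m1, n2),
                           np.einsum("ij,ij->i", n1, n2))
            )
            energy += energy_fn(phi)
            dVdphi = dVdphi_rad_fn(phi)
            n1sq = np.einsum("ij,ij->i", n1, n1)
            n2sq = np.einsum("ij,ij->i", n2, n2)
            dphid1 = (nb2 / n1sq)[:, None] * n1
            dphid4 = -(nb2 / n2sq)[:, None] * n2
            s = (np.einsum("ij,ij->i", b1, b2) / nb2**2)[:, None]
            t = (np.einsum("ij,ij->i", b3, b2) / nb2**2)[:, None]
            dphid2 = -(1.0 + s) * dphid1 + t * dphid4
            dphid3 = -(dphid1 + dphid2 + dphid4)
            for m, dphi in enumerate((dphid1, dphid2, dphid3, dphid4)):
                np.add.at(grad, idx[:, m], dVdphi[:, None] * dphi)

        if len(self.imp_idx):
            def imp_energy(phi):
                d = wrap_angle(phi - self.imp_xi0)
                return float((0.5 * self.imp_k * d * d).sum())

            def imp_dV(phi):
                # k_xi is per squared degree; the torsion gradient is per rad
                d = wrap_angle(phi - self.imp_xi0)
                return self.imp_k * d * (180.0 / math.pi)

            torsion_contrib(self.imp_idx, imp_dV, imp_energy)
        if len(self.dih_idx):
            def dih_energy(phi):
                arg = np.radians(self.dih_m * phi - self.dih_phi0)
                return float((self.dih_k * (1.0 + np.cos(arg))).sum())

            def dih_dV(phi):
                arg = np.radians(self.dih_m * phi - self.dih_phi0)
                return -self.dih_k * self.dih_m * np.sin(arg)

            torsion_contrib(self.dih_idx, dih_dV, dih_energy)
        return energy, grad


def total_energy(topology: Topology, conformation, cutoff: float = DEFAULT_CUTOFF_NM,
                 lj_table: LJTable | None = None, shift: bool = True) -> EnergyReport:
    """Full per-term energy breakdown of a conformation under a topology.

    The LJ sum runs over all non-excluded pairs within ``cutoff`` (nm); with
    ``shift=True`` (the default) the pair potential is shifted so that it
    vanishes exactly at the cutoff.
    """
    positions = getattr(conformation, "positions", conformation)
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (topology.n_beads, 3):
        raise ValueError(
            f"conformation has shape {positions.shape}, topology expects "
            f"({topology.n_beads}, 3)"
        )
    system = CompiledSystem(topology, lj_table=lj_table, cutoff=cutoff, shift=shift)
    return system.energy_report(positions)
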