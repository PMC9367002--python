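"""Coarse-grained coordinates: COG mapping, initial structures and file I/O.

Coordinates are nanometres internally (the GROMACS convention); PDB output is
converted to angstroms.  Bead indexing is 0-based internally and 1-based in
every file written.

The initial-structure generator places one relaxed four-bead residue template
per residue along a gently twisted chain axis and then relaxes the bonded
terms (plus a soft overlap penalty) by L-BFGS.  The bonded reference geometry
alone determines the result up to a small seeded jitter, so the output is
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .energetics import CompiledSystem, angles_deg, distances
from .topology import Topology

__all__ = [
    "Conformation",
    "MappingScheme",
    "map_aa_to_cg",
    "generate_initial_coords",
    "write_gro",
    "read_gro",
    "write_pdb",
]


@dataclass
class Conformation:
    """Bead positions (nm) of one molecule, ordered as the topology beads."""

    positions: np.ndarray
    box: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if self.positions.shape[0] == 0:
            raise ValueError("conformation must contain at least one bead")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


# ---------------------------------------------------------------------------
# center-of-geometry mapping
# ---------------------------------------------------------------------------


@dataclass
class MappingScheme:
    """Atom-name groups defining each bead, one group per bead.

    Atom labels are ``(residue_index, atom_name)`` pairs so the same scheme
    covers whole chains; groups list every contributing atom, including the
    aliphatic hydrogens (hydroxyl hydrogens are left out).
    """

    groups: list[list[tuple[int, str]]]

    def __post_init__(self):
        seen = set()
        for g, group in enumerate(self.groups):
            if not group:
                raise ValueError(f"bead group {g} is empty")
            for label in group:
                heavy = not str(label[1]).startswith("H")
                if heavy and label in seen:
                    raise ValueError(
                        f"heavy atom {label} assigned to more than one bead")
                seen.add(label)

    @property
    def n_beads(self) -> int:
        return len(self.groups)


def map_aa_to_cg(atom_coords: np.ndarray, atom_labels: Sequence[tuple[int, str]],
                 scheme: MappingScheme) -> Conformation:
    """Map atomistic coordinates onto beads by center of geometry.

    Each bead is the unweighted mean of its group's atoms.  Atoms required by
    the scheme but absent from ``atom_labels`` raise a ``ValueError`` listing
    the unmatched names.
    """
    atom_coords = np.asarray(atom_coords, dtype=float)
    index = {}
    for i, label in enumerate(atom_labels):
        index[(int(label[0]), str(label[1]))] = i
    missing = [
        label for group in scheme.groups for label in group
        if (int(label[0]), str(label[1])) not in index
    ]
    if missing:
        raise ValueError(
            "atoms required by the mapping scheme are missing: "
            + ", ".join(f"res{r}:{n}" for r, n in missing)
        )
    beads = np.empty((scheme.n_beads, 3))
    for g, group in enumerate(scheme.groups):
        rows = [index[(int(r), str(n))] for r, n in group]
        beads[g] = atom_coords[rows].mean(axis=0)
    return Conformation(beads)


# ---------------------------------------------------------------------------
# initial-structure generation
# ---------------------------------------------------------------------------

BOND_TOL_REL = 0.10
ANGLE_TOL_DEG = 25.0
MIN_SEPARATION_NM = 0.15

_TEMPLATE_GUESS = np.array(
    [[0.30, 0.18, 0.12], [0.30, 0.0, 0.0], [0.16, 0.12, -0.10], [0.0, 0.0, 0.0]]
)


_OVERLAP_D0 = 0.21
_OVERLAP_K = 2500.0


def _relax(system: CompiledSystem, x0: np.ndarray, maxiter: int = 2000,
           bond_guard: bool = False) -> np.ndarray:
    n = x0.shape[0]

    def objective(flat):
        x = flat.reshape(n, 3)
        e, grad = system.bonded_energy_grad(x)
        if bond_guard and len(system.bond_idx):
            # keep very soft bonds inside the advertised 10% tolerance even
            # where the frustrated bonded minimum would let them drift
            i, j = system.bond_idx[:, 0], system.bond_idx[:, 1]
            d = x[j] - x[i]
            b = np.linalg.norm(d, axis=1)
            slack = np.abs(b - system.bond_b0) - 0.08 * system.bond_b0
            active = slack > 0
            if np.any(active):
                e += float(5.0e4 * (slack[active] ** 2).sum())
                f = np.zeros_like(b)
                f[active] = (2.0 * 5.0e4 * slack[active]
                             * np.sign(b[active] - system.bond_b0[active]))
                fv = (f / b)[:, None] * d
                np.add.at(grad, i, -fv)
                np.add.at(grad, j, fv)
        # soft overlap penalty keeping non-bonded beads apart during relaxation
        d = x[None, :, :] - x[:, None, :]
        r = np.sqrt((d * d).sum(axis=2) + np.eye(n))
        close = np.clip(_OVERLAP_D0 - r, 0.0, None)
        np.fill_diagonal(close, 0.0)
        e += _OVERLAP_K * (close**2).sum()
        # d[i, j] = x_j - x_i; each pair contributes twice to the matrix sum
        coef = np.where(close > 0, 2.0 * _OVERLAP_K * close / r, 0.0)
        grad += 2.0 * np.einsum("ij,ijx->ix", coef, d)
        return e, grad.ravel()

    res = minimize(objective, x0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})
    return res.x.reshape(n, 3)


def _residue_template(topology: Topology) -> np.ndarray:
    """Relaxed geometry of the first residue's intra-ring terms."""
    sub = Topology(
        molecule_name="tmpl",
        beads=topology.beads[:4],
        bonds=[b for b in topology.bonds if max(b.beads) <= 4],
        angles=[a for a in topology.angles if max(a.beads) <= 4],
        impropers=[i for i in topology.impropers if max(i.beads) <= 4],
        dihedrals=[],
    )
    sub.exclusions = {frozenset(b.beads) for b in sub.bonds}
    system = CompiledSystem(sub, include_lj=False, clamp_restricted=True)
    return _relax(system, _TEMPLATE_GUESS.copy(), maxiter=300)


def _check_geometry(system: CompiledSystem, x: np.ndarray) -> bool:
    if len(system.bond_idx):
        b = distances(x, system.bond_idx)
        if np.any(np.abs(b - system.bond_b0) / system.bond_b0 > BOND_TOL_REL):
            return False
    for idx, cos0 in ((system.g96_idx, system.g96_cos0),
                      (system.res_idx, system.res_cos0)):
        if len(idx):
            th = angles_deg(x, idx)
            th0 = np.degrees(np.arccos(np.clip(cos0, -1, 1)))
            if np.any(np.abs(th - th0) > ANGLE_TOL_DEG):
                return False
    dmat = np.linalg.norm(x[None, :, :] - x[:, None, :], axis=2)
    np.fill_diagonal(dmat, np.inf)
    if dmat.min() < MIN_SEPARATION_NM:
        return False
    return np.isfinite(system.bonded_energy(x))


def _partial_system(topology: Topology, n_res: int,
                    torsions: bool = True) -> CompiledSystem:
    """Compiled bonded system restricted to the first ``n_res`` residues.

    With ``torsions=False`` the improper/proper dihedral terms are left out:
    the bond/angle subsystem has mutually compatible minima and relaxing it
    first keeps the torsions from trapping the chain in a distorted state.
    """
    hi = 4 * n_res
    sub = Topology(
        molecule_name=topology.molecule_name,
        beads=topology.beads[:hi],
        bonds=[t for t in topology.bonds if max(t.beads) <= hi],
        angles=[t for t in topology.angles if max(t.beads) <= hi],
        impropers=[t for t in topology.impropers
                   if torsions and max(t.beads) <= hi
                   and t.end_restriction == "none"],
        dihedrals=[t for t in topology.dihedrals
                   if torsions and max(t.beads) <= hi],
    )
    sub.exclusions = {frozenset(b.beads) for b in sub.bonds}
    return CompiledSystem(sub, include_lj=False, clamp_restricted=True)


def generate_initial_coords(topology: Topology, seed: int = 0,
                            max_attempts: int = 8) -> Conformation:
    """Starting coordinates consistent with the bonded reference geometry.

    The chain is grown residue by residue: each new four-bead block is placed
    ahead of the growing end and the partial chain is relaxed on its bonded
    terms (internal-coordinate-style growth followed by gradient descent),
    which keeps every linkage out of the bad local minima a one-shot global
    relaxation can fall into.

    Guarantees on success: every bond within 10% of its b0, every angle within
    25 degrees of its theta0, no bead pair closer than 0.15 nm, and a finite
    bonded energy.  Deterministic for a given seed; raises ``RuntimeError`` if
    the tolerances cannot be met after bounded refinement.
    """
    if topology.n_beads == 0:
        raise ValueError("topology has no beads")
    template = _residue_template(topology)
    template -= template.mean(axis=0)
    n_res = topology.n_residues
    full = CompiledSystem(topology, include_lj=False, clamp_restricted=True)
    for attempt in range(max_attempts):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) % 2**31, attempt]))
        coords = template + 0.01 * rng.standard_normal((4, 3))
        coords = _relax(_partial_system(topology, 1), coords, maxiter=400)
        for r in range(2, n_res + 1):
            prev = coords[4 * (r - 2): 4 * (r - 1)].mean(axis=0)
            if r == 2:
                direction = np.array([1.0, 0.0, 0.0])
            else:
                older = coords[4 * (r - 3): 4 * (r - 2)].mean(axis=0)
                direction = prev - older
                direction /= max(np.linalg.norm(direction), 1e-9)
            rot = Rotation.from_euler(
                "xyz", rng.uniform(-40.0, 40.0, size=3), degrees=True)
            block = rot.apply(template) + prev + 0.50 * direction
            block += 0.01 * rng.standard_normal((4, 3))
            coords = np.vstack([coords, block])
            coords = _relax(_partial_system(topology, r, torsions=False),
                            coords, maxiter=300 + 50 * r)
            coords = _relax(_partial_system(topology, r), coords,
                            maxiter=400 + 100 * r)
        relaxed = _relax(full, coords, bond_guard=True)
        if _check_geometry(full, relaxed):
            return Conformation(relaxed - relaxed.mean(axis=0),
                                metadata={"seed": int(seed)})
    raise RuntimeError(
        "failed to generate coordinates within geometric tolerances after "
        f"{max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _bead_names(topology: Topology | None, n: int) -> list[tuple[int, str]]:
    if topology is not None:
        return [(b.residue, b.name) for b in topology.beads]
    return [(i // 4 + 1, f"B{i % 4 + 1}") for i in range(n)]


def write_gro(conformation, path, topology: Topology | None = None,
              title: str = "glycocg coarse-grained glucan") -> None:
    """Write one frame (or a list of frames) in GROMACS .gro format (nm)."""
    frames = conformation if isinstance(conformation, (list, tuple)) else [conformation]
    if not frames:
        raise ValueError("no frames to write")
    lines = []
    for frame in frames:
        pos = np.asarray(frame.positions if isinstance(frame, Conformation) else frame)
        n = pos.shape[0]
        if topology is not None and n != topology.n_beads:
            raise ValueError(
                f"frame has {n} beads but the topology defines {topology.n_beads}")
        names = _bead_names(topology, n)
        box = getattr(frame, "box", None)
        if box is None:
            span = pos.max(axis=0) - pos.min(axis=0) + 2.0
            box = span
        lines.append(title)
        lines.append(f"{n:5d}")
        for i, ((resid, name), xyz) in enumerate(zip(names, pos), start=1):
            lines.append(
                f"{resid:5d}{'GLC':<5s}{name:>5s}{i:5d}"
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            )
        lines.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gro(path) -> list[Conformation]:
    """Read one or more concatenated .gro frames."""
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        title = lines[i]
        n = int(lines[i + 1])
        pos = np.empty((n, 3))
        for j in range(n):
            row = lines[i + 2 + j]
            pos[j] = [float(row[20:28]), float(row[28:36]), float(row[36:44])]
        box = np.array([float(t) for t in lines[i + 2 + n].split()[:3]])
        frames.append(Conformation(pos, box=box, metadata={"title": title}))
        i += n + 3
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return frames


def write_pdb(conformation, path, topology: Topology | None = None) -> None:
    """Write bead coordinates as a PDB file (angstroms, HETATM records)."""
    frames = conformation if isinstance(conformation, (list, tuple)) else [conformation]
    if not frames:
        raise ValueError("no frames to write")
    lines = []
    for model, frame in enumerate(frames, start=1):
        pos = np.asarray(frame.positions if isinstance(frame, Conformation) else frame)
        n = pos.shape[0]
        if topology is not None and n != topology.n_beads:
            raise ValueError(
                f"frame has {n} beads but the topology defines {topology.n_beads}")
        names = _bead_names(topology, n)
        if len(frames) > 1:
            lines.append(f"MODEL     {model:4d}")
        for i, ((resid, name), xyz) in enumerate(zip(names, pos), start=1):
            x, y, z = xyz * 10.0  # nm -> angstrom
            lines.append(
                f"HETATM{i:5d} {name:<4s}{'GLC':<4s}A{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
        if len(frames) > 1:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
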