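"""Synthetic atomistic glucan structures for exercising the COG mapping.

The generator emits idealized 4C1-chair-like glucopyranose residues with
CHARMM-style atom names (C1..C6, O1..O6 minus the oxygens consumed by
linkages, aliphatic H1..H5/H61/H62, hydroxyl HO*).  The geometry is a
deterministic template per residue, placed along the chain axis with a small
seeded jitter: it stands in for force-field-minimized atomistic structures in
mapping tests and is labelled synthetic for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coordinates import MappingScheme
from .tables import LINKAGE_TYPES, UnknownLinkageError

__all__ = [
    "AtomisticStructure",
    "generate_fixture_glucan",
    "default_mapping_scheme",
    "write_scheme",
    "read_scheme",
]

#: ring position of the oxygen consumed by each glycosidic linkage type
_LINKAGE_OXYGEN = {"b12": "O2", "b13": "O3", "a14": "O4", "b14": "O4", "a16": "O6"}


@dataclass
class AtomisticStructure:
    """Atom names, residue indices and coordinates (nm) of one molecule."""

    names: list[str]
    resids: list[int]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.names) != len(self.resids) or len(self.names) != len(self.coords):
            raise ValueError("names, resids and coords must have equal length")

    @property
    def labels(self) -> list[tuple[int, str]]:
        return list(zip(self.resids, self.names))

    def to_pdb(self, path) -> None:
        lines = []
        for i, (name, resid, xyz) in enumerate(
                zip(self.names, self.resids, self.coords), start=1):
            x, y, z = xyz * 10.0
            lines.append(
                f"HETATM{i:5d} {name:<4s}{'GLC':<4s}A{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_pdb(cls, path) -> "AtomisticStructure":
        names, resids, coords = [], [], []
        for line in Path(path).read_text().splitlines():
            if line.startswith(("ATOM", "HETATM")):
                names.append(line[12:16].strip())
                resids.append(int(line[22:26]))
                coords.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
        if not names:
            raise ValueError(f"no atom records found in {path}")
        return cls(names, resids, np.asarray(coords) / 10.0)  # angstrom -> nm


def _residue_template() -> dict[str, np.ndarray]:
    """Idealized chair-like residue template (nm), atom name -> position."""
    atoms: dict[str, np.ndarray] = {}
    ring = ["O5", "C1", "C2", "C3", "C4", "C5"]
    for k, name in enumerate(ring):
        ang = np.radians(60.0 * k)
        z = 0.025 if k % 2 == 0 else -0.025
        atoms[name] = np.array([0.145 * np.cos(ang), 0.145 * np.sin(ang), z])
    for carbon, oxy in (("C1", "O1"), ("C2", "O2"), ("C3", "O3"), ("C4", "O4")):
        c = atoms[carbon]
        out = c.copy()
        out[:2] *= (np.linalg.norm(c[:2]) + 0.130) / np.linalg.norm(c[:2])
        out[2] = c[2] - 0.055
        atoms[oxy] = out
    c5 = atoms["C5"]
    atoms["C6"] = c5 + np.array([0.04, -0.02, 0.145])
    atoms["O6"] = atoms["C6"] + np.array([0.10, 0.02, 0.085])
    for k, carbon in enumerate(["C1", "C2", "C3", "C4", "C5"], start=1):
        c = atoms[carbon]
        atoms[f"H{k}"] = c + np.array([0.0, 0.0, 0.105 if c[2] < 0 else -0.105])
    atoms["H61"] = atoms["C6"] + np.array([-0.09, 0.05, 0.03])
    atoms["H62"] = atoms["C6"] + np.array([-0.02, -0.10, 0.03])
    for oxy in ("O1", "O2", "O3", "O4", "O6"):
        atoms[f"H{oxy}"] = atoms[oxy] + np.array([0.03, 0.03, -0.08])
    return atoms


def generate_fixture_glucan(n_residues: int, linkage: str | None = None,
                            seed: int = 0) -> AtomisticStructure:
    """Synthetic atomistic coordinates of a glucan chain.

    Residue 1 is the reducing end and carries the anomeric hydroxyl (O1);
    each glycosidic bond consumes the hydroxyl hydrogen of the parent-carbon
    oxygen of the upstream residue, so every oxygen appears exactly once.
    Deterministic for a given seed.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if n_residues >= 2:
        if linkage is None:
            raise ValueError("chains of two or more residues require a linkage")
        if linkage not in LINKAGE_TYPES:
            raise UnknownLinkageError(linkage)
    elif linkage is not None:
        raise ValueError("a single residue takes no linkage")
    template = _residue_template()
    rng = np.random.default_rng(int(seed) % 2**31)
    names, resids, coords = [], [], []
    for r in range(1, n_residues + 1):
        shift = np.array([0.55 * (r - 1), 0.04 * ((r - 1) % 2), 0.0])
        flip = -1.0 if (r - 1) % 2 else 1.0
        for name, pos in template.items():
            if name == "O1" and r != 1:
                continue
            if name == "HO1" and r != 1:
                continue
            # glycosidic oxygen of residue r (r < n) loses its hydroxyl H
            if (linkage is not None and r < n_residues
                    and name == "H" + _LINKAGE_OXYGEN[linkage]):
                continue
            p = pos.copy()
            p[2] *= flip
            names.append(name)
            resids.append(r)
            coords.append(p + shift)
    coords = np.asarray(coords) + 0.002 * rng.standard_normal((len(names), 3))
    return AtomisticStructure(names, resids, coords)


def default_mapping_scheme(n_residues: int, linkage: str | None = None
                           ) -> MappingScheme:
    """Atom-to-bead assignment matching :func:`generate_fixture_glucan`.

    Per residue: B1 <- hydroxymethyl (C6, O6 + aliphatic H); B2 <- ring O,
    anomeric C (+ anomeric OH oxygen at the reducing end); B3 <- vicinal diol
    (C2, O2, C3, O3); B4 <- hydroxyethyl (C4, O4, C5).  Glycosidic oxygens sit
    in the bead of their parent carbon, so the same groups serve every
    linkage context; hydroxyl hydrogens are not mapped.
    """
    if n_residues >= 2 and linkage is not None and linkage not in LINKAGE_TYPES:
        raise UnknownLinkageError(linkage)
    groups: list[list[tuple[int, str]]] = []
    for r in range(1, n_residues + 1):
        b2 = [(r, "O5"), (r, "C1"), (r, "H1")]
        if r == 1:
            b2.append((1, "O1"))
        groups.append([(r, "C6"), (r, "O6"), (r, "H61"), (r, "H62")])
        groups.append(b2)
        groups.append([(r, "C2"), (r, "O2"), (r, "C3"), (r, "O3"),
                       (r, "H2"), (r, "H3")])
        groups.append([(r, "C4"), (r, "O4"), (r, "C5"), (r, "H4"), (r, "H5")])
    return MappingScheme(groups)


def write_scheme(scheme: MappingScheme, path) -> None:
    """Write a mapping scheme as one whitespace-separated line per bead:
    ``resid name1 name2 ...`` (atoms of one group share a residue index)."""
    lines = ["# bead mapping: resid atom1 atom2 ... (one line per bead)"]
    for group in scheme.groups:
        parts = []
        for resid, name in group:
            parts.append(f"{resid}:{name}")
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_scheme(path) -> MappingScheme:
    groups = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        group = []
        for tok in line.split():
            resid, name = tok.split(":", 1)
            group.append((int(resid), name))
        groups.append(group)
    if not groups:
        raise ValueError(f"no bead groups found in {path}")
    return MappingScheme(groups)
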