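"""GROMACS topology include (.itp) writer and reader.

Interaction-type bindings: harmonic bonds are ``funct 1``, cosine-harmonic
angles ``funct 2``, restricted bending angles ``funct 10``, periodic torsions
``dihedrals funct 1`` and harmonic impropers ``dihedrals funct 2``.  Charges
are always 0.0 (all modelled compounds are electrically neutral).  The
suggested MD timestep is written as a header comment, not enforced.
"""

from __future__ import annotations

from pathlib import Path

from .tables import (
    AngleTerm,
    BondTerm,
    DihedralTerm,
    ImproperTerm,
    size_class_of,
)
from .topology import Bead, Topology, build_exclusions

__all__ = ["write_itp", "read_itp", "ItpParseError"]


class ItpParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def write_itp(topology: Topology, path) -> None:
    """Write a topology as a GROMACS molecule include file."""
    lines = []
    ts = topology.metadata.get("timestep_fs")
    lines.append("; coarse-grained glucan topology written by glycocg")
    if ts is not None:
        lines.append(f"; suggested MD timestep: {ts} fs")
    lines.append("")
    lines.append("[ moleculetype ]")
    lines.append("; name  nrexcl")
    lines.append(f"{topology.molecule_name}  1")
    lines.append("")
    lines.append("[ atoms ]")
    lines.append(";  nr  type  resnr  residue  atom  cgnr  charge  mass")
    for b in topology.beads:
        lines.append(
            f"{b.index:5d}  {b.bead_type:<4s}  {b.residue:4d}  GLC  "
            f"{b.name:<3s}  {b.index:4d}  {b.charge:6.3f}  {_fmt(b.mass)}"
        )
    if topology.bonds:
        lines.append("")
        lines.append("[ bonds ]")
        lines.append(";   i    j  funct   b0 [nm]   kb")
        for t in topology.bonds:
            lines.append(
                f"{t.bead_i:5d}{t.bead_j:5d}    1  {_fmt(t.b0):>9s}  "
                f"{_fmt(t.k_b):>10s}  ; {t.source}"
            )
    if topology.angles:
        lines.append("")
        lines.append("[ angles ]")
        lines.append(";   i    j    k  funct  theta0   ktheta")
        for t in topology.angles:
            funct = 10 if t.form == "restricted" else 2
            i, j, k = t.beads
            lines.append(
                f"{i:5d}{j:5d}{k:5d}   {funct:2d}  {_fmt(t.theta0):>7s}  "
                f"{_fmt(t.k_theta):>8s}  ; {t.source}"
            )
    if topology.dihedrals or topology.impropers:
        lines.append("")
        lines.append("[ dihedrals ]")
        lines.append(";   i    j    k    l  funct  ref   k   (mult)")
        for t in topology.dihedrals:
            i, j, k, l = t.beads
            lines.append(
                f"{i:5d}{j:5d}{k:5d}{l:5d}    1  {_fmt(t.phi0):>7s}  "
                f"{_fmt(t.k_phi):>8s}  {t.multiplicity:d}  ; {t.source}"
            )
        for t in topology.impropers:
            i, j, k, l = t.beads
            flag = " nonreducing_end" if t.end_restriction != "none" else ""
            lines.append(
                f"{i:5d}{j:5d}{k:5d}{l:5d}    2  {_fmt(t.xi0):>7s}  "
                f"{_fmt(t.k_xi):>8s}  ; {t.source}{flag}"
            )
    if topology.exclusions:
        lines.append("")
        lines.append("[ exclusions ]")
        pairs = sorted(tuple(sorted(p)) for p in topology.exclusions)
        for i, j in pairs:
            lines.append(f"{i:5d}{j:5d}")
    Path(path).write_text("\n".join(lines) + "\n")


def _strip(line: str) -> str:
    return line.split(";", 1)[0].strip()


def read_itp(path) -> Topology:
    """Read a topology written by :func:`write_itp` (or an equivalent file).

    Malformed lines raise :class:`ItpParseError` carrying the line number.
    """
    text = Path(path).read_text()
    section = None
    name = "GLC"
    beads: list[Bead] = []
    top = Topology(molecule_name=name, beads=beads)
    metadata = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if raw.startswith("; suggested MD timestep:"):
            metadata["timestep_fs"] = int(raw.split(":")[1].split()[0])
        comment = ";" in raw
        source = raw.split(";", 1)[1].strip() if comment else ""
        line = _strip(raw)
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        fields = line.split()
        try:
            if section == "moleculetype":
                top.molecule_name = fields[0]
            elif section == "atoms":
                nr = int(fields[0])
                btype = fields[1]
                beads.append(
                    Bead(
                        index=nr,
                        name=fields[4],
                        residue=int(fields[2]),
                        bead_type=btype,
                        size_class=size_class_of(btype),
                        mass=float(fields[7]),
                        charge=float(fields[6]),
                    )
                )
            elif section == "bonds":
                i, j, funct = int(fields[0]), int(fields[1]), int(fields[2])
                if funct != 1:
                    raise ValueError(f"unsupported bond funct {funct}")
                top.bonds.append(
                    BondTerm(i, j, float(fields[4]), float(fields[3]),
                             source=source)
                )
            elif section == "angles":
                i, j, k, funct = (int(fields[0]), int(fields[1]),
                                  int(fields[2]), int(fields[3]))
                if funct not in (2, 10):
                    raise ValueError(f"unsupported angle funct {funct}")
                top.angles.append(
                    AngleTerm(
                        (i, j, k),
                        float(fields[5]),
                        float(fields[4]),
                        form="restricted" if funct == 10 else "g96",
                        source=source,
                    )
                )
            elif section == "dihedrals":
                quad = tuple(int(f) for f in fields[:4])
                funct = int(fields[4])
                if funct == 1:
                    top.dihedrals.append(
                        DihedralTerm(quad, float(fields[6]), float(fields[5]),
                                     int(fields[7]), source=source)
                    )
                elif funct == 2:
                    end = ("nonreducing_end_only"
                           if source.endswith("nonreducing_end") else "none")
                    top.impropers.append(
                        ImproperTerm(quad, float(fields[6]), float(fields[5]),
                                     end_restriction=end, source=source)
                    )
                else:
                    raise ValueError(f"unsupported dihedral funct {funct}")
            elif section == "exclusions":
                idx = [int(f) for f in fields]
                for j in idx[1:]:
                    top.exclusions.add(frozenset((idx[0], j)))
            elif section is None:
                raise ValueError("data before any [ section ]")
            # other sections are ignored
        except ItpParseError:
            raise
        except (ValueError, IndexError) as exc:
            raise ItpParseError(lineno, f"{exc} in {raw!r}") from exc
    if not beads:
        raise ItpParseError(len(text.splitlines()), "no [ atoms ] entries found")
    top.metadata = metadata
    if not top.exclusions:
        top.exclusions = build_exclusions(top)
    top.validate()
    return top
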