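"""Force-field parameter registry for glucopyranose-based coarse-grained chains.

The model maps one glucopyranose residue onto four Martini 3 beads and describes
five homoglycosidic linkage types: beta(1->2), beta(1->3), alpha(1->4),
beta(1->4) and alpha(1->6).  Bonded parameters are stored as plain TSV data
files (one per parameter table) so that an alternative, chemically sound bead
assignment can be swapped in by configuration; the shipped default is the
P3 + N4 bead-type set.

Bead numbering convention: beads B1..B4 belong to residue 1 (the reducing end),
B5..B8 to residue 2, and so on; the parameters of the n-th linkage are obtained
from those of the first one by adding 4n to every bead index.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

LINKAGE_TYPES = ("b12", "b13", "a14", "b14", "a16")
LINKAGE_LABELS = {
    "b12": "beta(1->2)",
    "b13": "beta(1->3)",
    "a14": "alpha(1->4)",
    "b14": "beta(1->4)",
    "a16": "alpha(1->6)",
}
ANOMERS = ("alpha", "beta")
BEADS_PER_RESIDUE = 4

#: Martini 3 convention masses per bead size class, in daltons.
SIZE_MASS_DA = {"R": 72.0, "S": 54.0, "T": 36.0}


def size_class_of(bead_type: str) -> str:
    """Size class (R, S or T) implied by a Martini bead-type label prefix."""
    return bead_type[0] if bead_type[:1] in ("S", "T") else "R"


class UnknownLinkageError(ValueError):
    def __init__(self, linkage: str):
        super().__init__(
            f"unknown linkage type {linkage!r}; supported types are "
            + ", ".join(LINKAGE_TYPES)
        )


# ---------------------------------------------------------------------------
# Term dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeadDef:
    """One bead of the four-bead residue representation."""

    index_in_residue: int
    bead_type: str
    size_class: str
    mass: float
    mapped_region: str = ""

    def __post_init__(self):
        if self.index_in_residue not in (1, 2, 3, 4):
            raise ValueError("index_in_residue must be 1-4")
        if self.size_class != size_class_of(self.bead_type):
            raise ValueError(
                f"size class {self.size_class} inconsistent with bead type "
                f"{self.bead_type}"
            )
        if self.mass <= 0:
            raise ValueError("mass must be positive")


@dataclass(frozen=True)
class BondTerm:
    """Harmonic stretch V = 1/2 k_b (b - b0)^2 between two beads."""

    bead_i: int
    bead_j: int
    k_b: float
    b0: float
    source: str = ""

    def __post_init__(self):
        if self.bead_i == self.bead_j:
            raise ValueError("bond endpoints must differ")
        if self.k_b <= 0:
            raise ValueError("k_b must be positive")
        if not 0 < self.b0 < 1.0:
            raise ValueError("b0 must lie in (0, 1) nm")

    @property
    def beads(self) -> tuple[int, int]:
        return (self.bead_i, self.bead_j)


@dataclass(frozen=True)
class AngleTerm:
    """Cosine-harmonic bend; ``form`` selects the plain (g96) or restricted
    variant, the latter diverging at 180 degrees."""

    beads: tuple[int, int, int]
    k_theta: float
    theta0: float
    form: str = "g96"
    source: str = ""

    def __post_init__(self):
        if self.form not in ("g96", "restricted"):
            raise ValueError("form must be 'g96' or 'restricted'")
        if not 0 < self.theta0 < 180:
            raise ValueError("theta0 must lie in (0, 180) degrees")
        if self.k_theta <= 0:
            raise ValueError("k_theta must be positive")


@dataclass(frozen=True)
class ImproperTerm:
    """Harmonic improper dihedral fixing pseudo-chiral bead geometry."""

    beads: tuple[int, int, int, int]
    k_xi: float
    xi0: float
    end_restriction: str = "none"
    source: str = ""

    def __post_init__(self):
        if self.end_restriction not in ("none", "nonreducing_end_only"):
            raise ValueError("bad end_restriction")
        if self.k_xi <= 0:
            raise ValueError("k_xi must be positive")
        if not -180 <= self.xi0 <= 180:
            raise ValueError("xi0 must lie in [-180, 180] degrees")


@dataclass(frozen=True)
class DihedralTerm:
    """Periodic torsion V = k_phi (1 + cos(m phi - phi0)); k_phi may be
    negative, and several terms may share one bead quadruplet."""

    beads: tuple[int, int, int, int]
    k_phi: float
    phi0: float
    multiplicity: int
    source: str = ""

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass(frozen=True)
class LJPair:
    """12/6 Lennard-Jones pair parameters, V = C12/r^12 - C6/r^6."""

    type_a: str
    type_b: str
    C6: float
    C12: float

    def __post_init__(self):
        if self.C6 < 0 or self.C12 <= 0:
            raise ValueError("require C6 >= 0 and C12 > 0")


@dataclass
class TermSet:
    """Bonded terms of one molecule or one parameter table."""

    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    impropers: list[ImproperTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)

    def counts(self) -> tuple[int, int, int, int]:
        return (
            len(self.bonds),
            len(self.angles),
            len(self.impropers),
            len(self.dihedrals),
        )

    def all_terms(self):
        return [*self.bonds, *self.angles, *self.impropers, *self.dihedrals]

    def max_bead_index(self) -> int:
        return max(max(_term_beads(t)) for t in self.all_terms())


def _term_beads(term) -> tuple[int, ...]:
    if isinstance(term, BondTerm):
        return term.beads
    return term.beads


def _offset_term(term, offset: int):
    """Shift every bead index of a term by ``offset`` (the +4n rule)."""
    if isinstance(term, BondTerm):
        return replace(term, bead_i=term.bead_i + offset, bead_j=term.bead_j + offset)
    return replace(term, beads=tuple(b + offset for b in term.beads))


@dataclass(frozen=True)
class LinkageRules:
    """Term lists of one linkage table, in first-linkage bead numbering.

    Rows whose bead indices all lie within 1..4 are intra-ring terms that
    override the free-monomer parameters of every residue in the chain; rows
    reaching beyond bead 4 describe the glycosidic linkage itself.
    """

    linkage_type: str
    terms: TermSet

    def intra(self) -> TermSet:
        return self._split(lambda beads: max(beads) <= BEADS_PER_RESIDUE)

    def inter(self) -> TermSet:
        return self._split(lambda beads: max(beads) > BEADS_PER_RESIDUE)

    def _split(self, keep) -> TermSet:
        out = TermSet()
        for name in ("bonds", "angles", "impropers", "dihedrals"):
            out_list = getattr(out, name)
            for term in getattr(self.terms, name):
                if keep(_term_beads(term)):
                    out_list.append(term)
        return out


# ---------------------------------------------------------------------------
# TSV parsing
# ---------------------------------------------------------------------------


def _parse_beads(pattern: str) -> tuple[int, ...]:
    try:
        return tuple(int(tok.lstrip("Bb")) for tok in pattern.split("-"))
    except ValueError as exc:
        raise ValueError(f"malformed bead pattern {pattern!r}") from exc


def _rows(text: str) -> Iterable[dict]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter="\t")
    yield from reader


def _make_term(kind, beads, k, ref, mult, form, flags, source):
    if kind == "bond":
        i, j = beads
        return BondTerm(i, j, k, ref, source=source)
    if kind == "angle":
        return AngleTerm(beads, k, ref, form=form, source=source)
    if kind == "improper":
        end = (
            "nonreducing_end_only" if "nonreducing_end" in flags else "none"
        )
        return ImproperTerm(beads, k, ref, end_restriction=end, source=source)
    if kind == "dihedral":
        return DihedralTerm(beads, k, ref, int(mult), source=source)
    raise ValueError(f"unknown term kind {kind!r}")


def _load_linkage_text(text: str, linkage_type: str) -> LinkageRules:
    terms = TermSet()
    for row in _rows(text):
        kind = row["kind"]
        beads = _parse_beads(row["beads"])
        source = f"{linkage_type}:{kind}:{row['beads']}"
        term = _make_term(
            kind,
            beads,
            float(row["k"]),
            float(row["ref"]),
            row.get("mult", "."),
            row.get("form", "."),
            row.get("flags", ""),
            source,
        )
        getattr(terms, kind + "s").append(term)
    return LinkageRules(linkage_type, terms)


def _load_monomer_text(text: str) -> dict[str, TermSet]:
    out = {a: TermSet() for a in ANOMERS}
    for row in _rows(text):
        kind = row["kind"]
        beads = _parse_beads(row["beads"])
        for anomer in ANOMERS:
            source = f"monomer:{anomer}:{kind}:{row['beads']}"
            term = _make_term(
                kind,
                beads,
                float(row[f"{anomer}_k"]),
                float(row[f"{anomer}_ref"]),
                row.get("mult", "."),
                row.get("form", "."),
                row.get("flags", ""),
                source,
            )
            getattr(out[anomer], kind + "s").append(term)
    return out


class LJTable:
    """Symmetric lookup of Lennard-Jones C6/C12 by bead-type pair."""

    def __init__(self, pairs: Sequence[LJPair]):
        self._pairs: dict[frozenset, LJPair] = {}
        for p in pairs:
            self._pairs[frozenset((p.type_a, p.type_b))] = p

    @classmethod
    def from_tsv(cls, path_or_text) -> "LJTable":
        if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
            text = Path(path_or_text).read_text()
        else:
            text = str(path_or_text)
        pairs = [
            LJPair(row["type_a"], row["type_b"], float(row["C6"]), float(row["C12"]))
            for row in _rows(text)
        ]
        return cls(pairs)

    def lookup(self, type_a: str, type_b: str) -> LJPair:
        try:
            return self._pairs[frozenset((type_a, type_b))]
        except KeyError:
            raise KeyError(
                f"no LJ parameters for bead-type pair ({type_a}, {type_b})"
            ) from None

    def types(self) -> set[str]:
        return set().union(*self._pairs.keys())


# ---------------------------------------------------------------------------
# ForceFieldTables
# ---------------------------------------------------------------------------


def _read_data(name: str, data_dir: Path | None) -> str:
    if data_dir is not None:
        return (Path(data_dir) / name).read_text()
    return resources.files("glycocg.data").joinpath(name).read_text()


class ForceFieldTables:
    """The complete bonded/nonbonded parameter registry.

    Parameters
    ----------
    variant:
        ``"default"`` (TP3/SN4/P3/TN4 ring) or ``"s_ring"`` (the regular ring
        bead replaced by its small-size counterpart, SP3).
    data_dir:
        Optional directory of replacement TSV tables; defaults to the files
        shipped with the package.
    masses:
        Override of the per-size-class bead masses in Da.
    lj_table:
        Optional :class:`LJTable`; defaults to the shipped *synthetic* pair
        table (see ``data/lj_pairs_synthetic.tsv``).
    """

    def __init__(self, variant="default", data_dir=None, masses=None, lj_table=None):
        if variant not in ("default", "s_ring"):
            raise ValueError("variant must be 'default' or 's_ring'")
        self.variant = variant
        self.masses = dict(SIZE_MASS_DA if masses is None else masses)
        self._monomer = _load_monomer_text(_read_data("monomer.tsv", data_dir))
        self._linkages = {
            lt: _load_linkage_text(_read_data(f"{lt}.tsv", data_dir), lt)
            for lt in LINKAGE_TYPES
        }
        if lj_table is None:
            lj_table = LJTable.from_tsv(
                _read_data("lj_pairs_synthetic.tsv", data_dir)
            )
        self.lj_table = lj_table
        self._bead_defs = self._load_bead_defs(data_dir)

    def _load_bead_defs(self, data_dir) -> list[BeadDef]:
        col = "s_ring_type" if self.variant == "s_ring" else "default_type"
        defs = []
        for row in _rows(_read_data("bead_types.tsv", data_dir)):
            btype = row[col]
            size = size_class_of(btype)
            defs.append(
                BeadDef(
                    index_in_residue=int(row["index"]),
                    bead_type=btype,
                    size_class=size,
                    mass=self.masses[size],
                    mapped_region=row.get("mapped_region", ""),
                )
            )
        defs.sort(key=lambda d: d.index_in_residue)
        return defs

    # -- queries ------------------------------------------------------------

    def bead_defs(self) -> list[BeadDef]:
        """The four per-residue bead definitions, in bead order."""
        return list(self._bead_defs)

    def monomer_terms(self, anomer: str) -> TermSet:
        """Bonded terms of a free glucopyranose monomer of the given anomer."""
        if anomer not in ANOMERS:
            raise ValueError(f"anomer must be one of {ANOMERS}, got {anomer!r}")
        src = self._monomer[anomer]
        return TermSet(
            list(src.bonds), list(src.angles), list(src.impropers), list(src.dihedrals)
        )

    def linkage_rules(self, linkage_type: str) -> LinkageRules:
        try:
            return self._linkages[linkage_type]
        except KeyError:
            raise UnknownLinkageError(linkage_type) from None

    def lj(self, type_a: str, type_b: str) -> LJPair:
        return self.lj_table.lookup(type_a, type_b)

    # -- expansion ----------------------------------------------------------

    def lookup_terms(self, linkage_type: str, n_residues: int) -> TermSet:
        """Expanded term lists for a homopolymer of ``n_residues`` residues.

        Intra-ring rows of the linkage table are replicated for every residue
        (offset 4r); linkage rows are replicated for every glycosidic bond
        (offset 4l), dropping any replica that would reference a bead beyond
        the end of the chain.  The ring improper flagged as
        ``nonreducing_end_only`` is emitted only at residue ``n_residues``.
        """
        if n_residues < 2:
            raise ValueError("lookup_terms requires n_residues >= 2")
        return self.expand_chain_terms([linkage_type] * (n_residues - 1))

    def expand_chain_terms(self, linkages: Sequence[str]) -> TermSet:
        """Expanded term lists for a chain with per-bond linkage types."""
        for lt in linkages:
            if lt not in LINKAGE_TYPES:
                raise UnknownLinkageError(lt)
        n_residues = len(linkages) + 1
        n_beads = BEADS_PER_RESIDUE * n_residues
        out = TermSet()
        # intra-ring terms: residue r parameterized by the adjacent linkage
        # table (the linkage on its nonreducing side; the last residue reuses
        # the final linkage table).
        for r in range(n_residues):
            rules = self._linkages[linkages[min(r, n_residues - 2)]]
            offset = BEADS_PER_RESIDUE * r
            for name in ("bonds", "angles", "impropers", "dihedrals"):
                for term in getattr(rules.intra(), name):
                    if (
                        isinstance(term, ImproperTerm)
                        and term.end_restriction == "nonreducing_end_only"
                        and r != n_residues - 1
                    ):
                        continue
                    shifted = _offset_term(term, offset)
                    shifted = replace(shifted, source=f"{term.source}+{offset}")
                    getattr(out, name).append(shifted)
        # glycosidic terms, one copy per linkage at offset 4l
        for l, lt in enumerate(linkages):
            offset = BEADS_PER_RESIDUE * l
            for name in ("bonds", "angles", "impropers", "dihedrals"):
                for term in getattr(self._linkages[lt].inter(), name):
                    if max(_term_beads(term)) + offset > n_beads:
                        continue  # e.g. the a16 B1-B9 bond at the chain end
                    shifted = _offset_term(term, offset)
                    shifted = replace(shifted, source=f"{term.source}+{offset}")
                    getattr(out, name).append(shifted)
        return out
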