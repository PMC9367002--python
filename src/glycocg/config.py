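"""Plain-text run configuration (``key: value`` lines).

Recognized keys: ``parameter_set`` (default | s_ring), ``lj_table`` (path),
``masses`` (``R=72 S=54 T=36`` style), ``seed``, ``output_dir``,
``verbosity``.  Unknown keys are rejected and referenced files must exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .tables import SIZE_MASS_DA, ForceFieldTables, LJTable

__all__ = ["RunConfig", "load_config"]

_KNOWN_KEYS = {"parameter_set", "lj_table", "masses", "seed", "output_dir",
               "verbosity"}


@dataclass
class RunConfig:
    parameter_set: str = "default"
    lj_table: str | None = None
    masses: dict = field(default_factory=lambda: dict(SIZE_MASS_DA))
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1

    def __post_init__(self):
        if self.parameter_set not in ("default", "s_ring"):
            raise ValueError("parameter_set must be 'default' or 's_ring'")
        if self.lj_table is not None and not Path(self.lj_table).is_file():
            raise FileNotFoundError(f"LJ table not found: {self.lj_table}")
        for size in ("R", "S", "T"):
            if size not in self.masses:
                raise ValueError(f"masses must define size class {size}")

    def tables(self) -> ForceFieldTables:
        lj = LJTable.from_tsv(self.lj_table) if self.lj_table else None
        return ForceFieldTables(variant=self.parameter_set, masses=self.masses,
                                lj_table=lj)


def _parse_masses(text: str) -> dict:
    masses = {}
    for tok in text.replace(",", " ").split():
        size, value = tok.split("=", 1)
        masses[size.strip()] = float(value)
    return masses


def load_config(path) -> RunConfig:
    """Parse a ``key: value`` configuration file, rejecting unknown keys."""
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: expected 'key: value', got {line!r}")
        key, value = (part.strip() for part in line.split(":", 1))
        if key not in _KNOWN_KEYS:
            raise ValueError(
                f"line {lineno}: unknown configuration key {key!r}; known keys "
                f"are {sorted(_KNOWN_KEYS)}"
            )
        if key in ("seed", "verbosity"):
            kwargs[key] = int(value)
        elif key == "masses":
            kwargs[key] = _parse_masses(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)
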