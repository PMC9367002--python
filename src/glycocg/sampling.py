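"""Metropolis Monte Carlo sampling and conformational descriptors.

The sampler replaces molecular dynamics for desk-scale validation: the
validation quantities of the model are ensemble geometric distributions
(bond/angle/dihedral statistics, gyration radius, end-to-end distance), which
Metropolis sampling over single-bead displacement moves reproduces without
force evaluation.  Temperature enters only through k_B*T in kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coordinates import Conformation, generate_initial_coords
from .energetics import CompiledSystem, DEFAULT_CUTOFF_NM, angles_deg, dihedrals_deg, distances
from .tables import LJTable
from .topology import Topology

__all__ = [
    "KB_KJ_PER_MOL_K",
    "Ensemble",
    "DescriptorSet",
    "DescriptorSelections",
    "RunningStats",
    "radii_for_topology",
    "mc_sample",
    "default_selections",
    "compute_descriptors",
    "dihedral_histogram",
    "bead_sasa",
    "DEFAULT_BEAD_RADII_NM",
]

KB_KJ_PER_MOL_K = 0.0083145

#: Default SASA radii per bead size class (half the size-class sigma), nm.
DEFAULT_BEAD_RADII_NM = {"R": 0.235, "S": 0.205, "T": 0.17}


@dataclass
class Ensemble:
    """Sampled frames plus the run conditions that produced them."""

    frames: np.ndarray  # (n_frames, n_beads, 3) in nm
    temperature: float
    seed: int
    n_steps: int
    acceptance_rate: float
    energies: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_beads, 3)")
        if not 0.0 < self.acceptance_rate < 1.0:
            # a rate of exactly 0 or 1 signals a broken move set
            raise ValueError(
                f"acceptance rate {self.acceptance_rate} outside (0, 1)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]


def mc_sample(topology: Topology, temperature: float, n_steps: int,
              step_size: float = 0.02, seed: int = 0, *,
              start: Conformation | np.ndarray | None = None,
              sample_every: int = 50, burn_in: int | None = None,
              cutoff: float = DEFAULT_CUTOFF_NM, lj_table: LJTable | None = None,
              include_lj: bool = True) -> Ensemble:
    """Metropolis sampling with single-bead displacement moves.

    Each step displaces one uniformly chosen bead by a uniform vector in
    ``[-step_size, step_size]^3`` and accepts with the Boltzmann criterion at
    ``temperature`` (K); the symmetric proposal gives detailed balance by
    construction.  Deterministic for a given seed.
    """
    if topology.n_beads == 0:
        raise ValueError("topology has no beads")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    system = CompiledSystem(topology, lj_table=lj_table, cutoff=cutoff,
                            include_lj=include_lj)
    if start is None:
        x = generate_initial_coords(topology, seed=seed).positions.copy()
    else:
        x = np.array(getattr(start, "positions", start), dtype=float)
        if x.shape != (topology.n_beads, 3):
            raise ValueError("start conformation does not match the topology")
    if burn_in is None:
        burn_in = min(n_steps // 5, 5000)
    rng = np.random.default_rng(int(seed) % 2**31)
    beta = 1.0 / (KB_KJ_PER_MOL_K * temperature)
    energy = system.energy(x)
    n = topology.n_beads
    accepted = 0
    frames = []
    energies = []
    for step in range(n_steps):
        bead = int(rng.integers(n))
        move = step_size * rng.uniform(-1.0, 1.0, size=3)
        old = x[bead].copy()
        x[bead] = old + move
        new_energy = system.energy(x)
        d = new_energy - energy
        if d <= 0 or (math.isfinite(d) and rng.random() < math.exp(-beta * d)):
            energy = new_energy
            accepted += 1
        else:
            x[bead] = old
        if step >= burn_in and (step - burn_in) % sample_every == 0:
            frames.append(x.copy())
            energies.append(energy)
    if not frames:
        frames.append(x.copy())
        energies.append(energy)
    return Ensemble(
        frames=np.array(frames),
        temperature=temperature,
        seed=int(seed),
        n_steps=n_steps,
        acceptance_rate=accepted / n_steps,
        energies=np.array(energies),
    )


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------


class RunningStats:
    """Streaming mean/variance (Welford) used for descriptor summaries."""

    def __init__(self):
        self.n = 0
        self._mean = 0.0
        self._m2 = 0.0

    def push(self, value: float) -> None:
        self.n += 1
        delta = value - self._mean
        self._mean += delta / self.n
        self._m2 += delta * (value - self._mean)

    @property
    def mean(self) -> float:
        return self._mean

    @property
    def variance(self) -> float:
        return self._m2 / self.n if self.n else float("nan")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass
class DescriptorSet:
    """Per-frame conformational descriptors with mean/SD summaries."""

    values: dict[str, np.ndarray]
    summary: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.summary:
            for key, arr in self.values.items():
                stats = RunningStats()
                for v in np.asarray(arr).ravel():
                    stats.push(float(v))
                self.summary[key] = (stats.mean, stats.sd)


@dataclass
class DescriptorSelections:
    """Bead selections (1-based indices) for geometric descriptors."""

    distances: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    end_to_end: bool = True
    radius_of_gyration: bool = True


def default_selections(topology: Topology) -> DescriptorSelections:
    """Descriptors traceable to force-field terms of the chain centre.

    For chains, bonded terms whose beads all belong to the central residue(s)
    (and their linkage) are selected; for a monomer, every term is.
    """
    n_res = topology.n_residues
    if n_res <= 2:
        lo, hi = 1, topology.n_beads
    else:
        mid = (n_res - 1) // 2  # 0-based residue index of the central linkage
        lo, hi = 4 * mid + 1, 4 * (mid + 2)
    sel = DescriptorSelections()
    for b in topology.bonds:
        if lo <= min(b.beads) and max(b.beads) <= hi:
            sel.distances.append(tuple(b.beads))
    for a in topology.angles:
        if lo <= min(a.beads) and max(a.beads) <= hi:
            sel.angles.append(tuple(a.beads))
    for im in topology.impropers:
        if lo <= min(im.beads) and max(im.beads) <= hi:
            sel.impropers.append(tuple(im.beads))
    for d in topology.dihedrals:
        if lo <= min(d.beads) and max(d.beads) <= hi:
            sel.dihedrals.append(tuple(d.beads))
    return sel


def compute_descriptors(ensemble, selections: DescriptorSelections | None = None,
                        topology: Topology | None = None,
                        masses: np.ndarray | None = None) -> DescriptorSet:
    """Per-frame geometric descriptors plus mean/SD summaries.

    ``ensemble`` may be an :class:`Ensemble` or a bare (frames, beads, 3)
    array.  The gyration radius is mass-weighted when ``masses`` (or a
    topology carrying them) is given, otherwise unweighted.
    """
    frames = np.asarray(getattr(ensemble, "frames", ensemble), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_beads = frames.shape[1]
    if selections is None:
        if topology is None:
            selections = DescriptorSelections()
        else:
            selections = default_selections(topology)
    if masses is None and topology is not None:
        masses = np.array([b.mass for b in topology.beads])
    for group in (selections.distances, selections.angles,
                  selections.impropers, selections.dihedrals):
        for sel in group:
            if min(sel) < 1 or max(sel) > n_beads:
                raise ValueError(f"selection {sel} references a nonexistent bead")
    values: dict[str, np.ndarray] = {}

    def per_frame(func, idx):
        idx0 = np.asarray(idx, dtype=int).reshape(1, -1) - 1
        return np.array([float(func(f, idx0)[0]) for f in frames])

    for sel in selections.distances:
        values[f"d({sel[0]}-{sel[1]})"] = per_frame(distances, sel)
    for sel in selections.angles:
        values["theta(" + "-".join(map(str, sel)) + ")"] = per_frame(angles_deg, sel)
    for sel in selections.impropers:
        values["xi(" + "-".join(map(str, sel)) + ")"] = per_frame(dihedrals_deg, sel)
    for sel in selections.dihedrals:
        values["phi(" + "-".join(map(str, sel)) + ")"] = per_frame(dihedrals_deg, sel)
    if selections.end_to_end:
        values["e2e"] = np.linalg.norm(frames[:, -1] - frames[:, 0], axis=1)
    if selections.radius_of_gyration:
        w = np.ones(n_beads) if masses is None else np.asarray(masses, dtype=float)
        w = w / w.sum()
        com = np.einsum("fbx,b->fx", frames, w)
        d2 = ((frames - com[:, None, :]) ** 2).sum(axis=2)
        values["rg"] = np.sqrt(np.einsum("fb,b->f", d2, w))
    return DescriptorSet(values=values)


def dihedral_histogram(ensemble, quadruplet=None, bin_width: float = 5.0):
    """Probability-normalized torsion histogram over (-180, 180].

    ``ensemble`` is an :class:`Ensemble` (with ``quadruplet`` of 1-based bead
    indices) or a bare array of angle values in degrees.  ``bin_width`` must
    divide 360; returns ``(bin_centers, probabilities)`` with the
    probabilities summing to exactly 1.
    """
    nbins = 360.0 / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin_width must divide 360")
    nbins = int(round(nbins))
    if quadruplet is not None:
        frames = np.asarray(getattr(ensemble, "frames", ensemble), dtype=float)
        idx = np.asarray(quadruplet, dtype=int).reshape(1, 4) - 1
        angles = np.array([float(dihedrals_deg(f, idx)[0]) for f in frames])
    else:
        angles = np.asarray(ensemble, dtype=float).ravel()
    # map to (-180, 180] then histogram on half-open [edge, edge) bins by
    # nudging exact +180 into the last bin
    wrapped = -((-angles + 180.0) % 360.0 - 180.0)
    wrapped = np.where(wrapped == 180.0, np.nextafter(180.0, -np.inf), wrapped)
    counts, edges = np.histogram(wrapped, bins=nbins, range=(-180.0, 180.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    probs = counts / counts.sum()
    # absorb the float-division residual so the bins sum to exactly one
    probs[np.argmax(probs)] += 1.0 - probs.sum()
    return centers, probs


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def bead_sasa(conformation, radii, probe: float = 0.14, n_points: int = 1000):
    """Shrake-Rupley solvent-accessible surface area of a bead conformation.

    ``radii`` is either a per-bead array (nm) or a mapping from size class to
    radius.  Test points lie on a deterministic Fibonacci sphere, so the
    result is reproducible for a given ``n_points``.  Returns ``(total,
    per_bead)`` in nm^2.
    """
    pos = np.asarray(getattr(conformation, "positions", conformation), dtype=float)
    n = pos.shape[0]
    radii = np.asarray(radii, dtype=float).reshape(-1)
    if radii.size == 1:
        radii = np.full(n, radii[0])
    if radii.size != n:
        raise ValueError("need one radius per bead")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    unit = _fibonacci_sphere(int(n_points))
    extended = radii + probe
    per_bead = np.empty(n)
    for i in range(n):
        points = pos[i] + extended[i] * unit
        exposed = np.ones(int(n_points), dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = ((points - pos[j]) ** 2).sum(axis=1)
            exposed &= d2 > extended[j] ** 2
        area = 4.0 * math.pi * extended[i] ** 2
        per_bead[i] = area * exposed.mean()
    return float(per_bead.sum()), per_bead


def radii_for_topology(topology: Topology,
                       table: dict[str, float] | None = None) -> np.ndarray:
    """Per-bead SASA radii from the size-class radius table."""
    table = DEFAULT_BEAD_RADII_NM if table is None else table
    return np.array([table[b.size_class] for b in topology.beads])
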