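"""Genome topology: diploid bead-on-a-string chromosomes plus free nucleolar
particles, NAD annotation from a genomic signal track, and initial
configurations.

Each chromosome is a string of 1 Mb beads typed A (euchromatin-like
compartment), B (heterochromatin-like compartment) or C (centromeric).  A
subset of chromatin beads carries a NAD flag (nucleolus-associated domain)
derived by thresholding a nucleolar-to-genomic signal track.  Homologous
chromosomes are exact copies: they share lengths, types and NAD masks by
construction, because the topology stores one haploid set and duplicates it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TYPE_A",
    "TYPE_B",
    "TYPE_C",
    "BinningError",
    "PackingError",
    "SignalTrack",
    "ChromosomeSpec",
    "GenomeTopology",
    "SimulationState",
    "annotate_nads",
    "build_topology",
    "initialize_configuration",
    "relax",
]

TYPE_A, TYPE_B, TYPE_C = 0, 1, 2
_TYPE_NAMES = {"A": TYPE_A, "B": TYPE_B, "C": TYPE_C}
_TYPE_CHARS = {v: k for k, v in _TYPE_NAMES.items()}


class BinningError(ValueError):
    """Signal track intervals do not align with the model's genomic bins."""


class PackingError(ValueError):
    """Requested particles cannot fit inside the confinement sphere."""


def _as_types(types: Sequence[int] | Sequence[str] | np.ndarray) -> np.ndarray:
    arr = np.asarray(types)
    if arr.dtype.kind in "OUS":
        arr = np.array([_TYPE_NAMES[str(t)] for t in arr], dtype=np.int8)
    else:
        arr = arr.astype(np.int8)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("chromosome types must be a non-empty 1D sequence")
    if not np.isin(arr, [TYPE_A, TYPE_B, TYPE_C]).all():
        raise ValueError("chromosome types must be A, B or C")
    return arr


@dataclass(frozen=True)
class SignalTrack:
    """Binned genomic signal (bedGraph semantics: 0-based, half-open intervals).

    ``data`` has columns chrom, start, end, value; intervals within a
    chromosome must be non-overlapping and aligned to ``bin_size``.
    """

    data: pd.DataFrame
    bin_size: int = 1_000_000

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "value"]
        if list(self.data.columns)[:4] != required:
            raise ValueError(f"track columns must be {required}")
        if not np.isfinite(self.data["value"].to_numpy(dtype=float)).all():
            raise ValueError("track values must be finite")
        for chrom, grp in self.data.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["end"].to_numpy()[:-1] > g["start"].to_numpy()[1:]).any():
                raise ValueError(f"overlapping intervals on {chrom}")

    @classmethod
    def from_bedgraph(cls, path: str | Path, bin_size: int = 1_000_000) -> "SignalTrack":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, value = line.split()[:4]
                rows.append((chrom, int(start), int(end), float(value)))
        data = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        return cls(data=data, bin_size=bin_size)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.data.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:g}\n")

    def chrom_names(self) -> list[str]:
        return list(dict.fromkeys(self.data["chrom"]))


def annotate_nads(
    track: SignalTrack,
    threshold: float = 15.0,
    resolution: int | None = None,
    chrom_bins: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Threshold a signal track into per-bin NAD masks.

    A bin is a NAD iff its signal is strictly greater than ``threshold``.
    Returns a mask per chromosome; bins absent from the track are False.
    ``chrom_bins`` may supply the number of bins per chromosome (otherwise
    inferred from the largest interval end).  Raises :class:`BinningError`
    if the track is not binned at the model resolution.
    """
    resolution = resolution or track.bin_size
    if track.bin_size != resolution:
        raise BinningError(
            f"track bin size {track.bin_size} != model resolution {resolution}"
        )
    starts = track.data["start"].to_numpy()
    ends = track.data["end"].to_numpy()
    if ((starts % resolution) != 0).any() or ((ends - starts) > resolution).any():
        raise BinningError("track intervals are not aligned to the model resolution")
    masks: dict[str, np.ndarray] = {}
    for chrom, grp in track.data.groupby("chrom", sort=False):
        n = (
            chrom_bins[chrom]
            if chrom_bins is not None
            else int(math.ceil(grp["end"].max() / resolution))
        )
        mask = np.zeros(n, dtype=bool)
        bins = (grp["start"].to_numpy() // resolution).astype(int)
        keep = bins < n
        mask[bins[keep]] = grp["value"].to_numpy()[keep] > threshold
        masks[chrom] = mask
    return masks


@dataclass(frozen=True)
class ChromosomeSpec:
    """One haploid chromosome: bead types and NAD flags at model resolution."""

    name: str
    types: np.ndarray
    nad: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "types", _as_types(self.types))
        nad = self.nad
        if nad is None:
            nad = np.zeros(self.types.size, dtype=bool)
        nad = np.asarray(nad, dtype=bool)
        if nad.shape != self.types.shape:
            raise ValueError(f"NAD mask length mismatch on {self.name}")
        object.__setattr__(self, "nad", nad)

    @property
    def n_beads(self) -> int:
        return int(self.types.size)


class GenomeTopology:
    """Diploid genome plus nucleolar particles.

    The haploid chromosome list is duplicated into two homologous copies, so
    homologs share lengths, types and NAD masks exactly.  Nucleolar particles
    are free (unbonded) spheres of diameter ``nucleolar_diameter``.
    """

    def __init__(
        self,
        chromosomes: Sequence[ChromosomeSpec],
        n_nucleolar: int = 500,
        nucleolar_diameter: float = 0.5,
        confinement_radius: float = 19.7,
        resolution: int = 1_000_000,
        ploidy: int = 2,
    ):
        if n_nucleolar < 0:
            raise ValueError("n_nucleolar must be >= 0")
        if not (nucleolar_diameter > 0 and confinement_radius > 0):
            raise ValueError("nucleolar_diameter and confinement_radius must be positive")
        self.chromosomes = list(chromosomes)
        self.n_nucleolar = int(n_nucleolar)
        self.nucleolar_diameter = float(nucleolar_diameter)
        self.confinement_radius = float(confinement_radius)
        self.resolution = int(resolution)
        self.ploidy = int(ploidy)

        chrom_id, copy_id, bin_index, types, nad = [], [], [], [], []
        bonds = []
        offset = 0
        for copy in range(self.ploidy):
            for ci, spec in enumerate(self.chromosomes):
                n = spec.n_beads
                chrom_id.append(np.full(n, ci, dtype=np.int32))
                copy_id.append(np.full(n, copy, dtype=np.int8))
                bin_index.append(np.arange(n, dtype=np.int32))
                types.append(spec.types)
                nad.append(spec.nad)
                if n > 1:
                    left = np.arange(offset, offset + n - 1, dtype=np.int64)
                    bonds.append(np.stack([left, left + 1], axis=1))
                offset += n
        self.chrom_id = (
            np.concatenate(chrom_id) if chrom_id else np.empty(0, dtype=np.int32)
        )
        self.copy_id = (
            np.concatenate(copy_id) if copy_id else np.empty(0, dtype=np.int8)
        )
        self.bin_index = (
            np.concatenate(bin_index) if bin_index else np.empty(0, dtype=np.int32)
        )
        self.types = np.concatenate(types) if types else np.empty(0, dtype=np.int8)
        self.nad_mask = np.concatenate(nad) if nad else np.empty(0, dtype=bool)
        self.bonds = (
            np.concatenate(bonds, axis=0) if bonds else np.empty((0, 2), dtype=np.int64)
        )

    @classmethod
    def particles_only(
        cls,
        n_nucleolar: int,
        nucleolar_diameter: float = 0.5,
        confinement_radius: float = 19.7,
    ) -> "GenomeTopology":
        """Chromatin-free topology: nucleolar particles in bare confinement
        (the control condition without the chromatin network)."""
        return cls(
            [],
            n_nucleolar=n_nucleolar,
            nucleolar_diameter=nucleolar_diameter,
            confinement_radius=confinement_radius,
        )

    # -- derived counts ---------------------------------------------------
    @property
    def n_chromatin(self) -> int:
        return int(self.types.size)

    @property
    def n_particles(self) -> int:
        return self.n_chromatin + self.n_nucleolar

    @property
    def nucleolar_indices(self) -> np.ndarray:
        return np.arange(self.n_chromatin, self.n_particles, dtype=np.int64)

    @property
    def is_nucleolar(self) -> np.ndarray:
        mask = np.zeros(self.n_particles, dtype=bool)
        mask[self.n_chromatin :] = True
        return mask

    def codes(self) -> np.ndarray:
        """Engine pair-class codes: chromatin = type + 3*NAD (0..5), nucleolar = 6."""
        codes = np.empty(self.n_particles, dtype=np.int64)
        codes[: self.n_chromatin] = self.types.astype(np.int64) + 3 * self.nad_mask
        codes[self.n_chromatin :] = 6
        return codes

    def with_nad_masks(self, masks: Mapping[str, np.ndarray]) -> "GenomeTopology":
        """Return a copy with NAD masks applied to the haploid chromosomes
        (and therefore mirrored to both homologs)."""
        specs = []
        for spec in self.chromosomes:
            if spec.name in masks:
                mask = np.asarray(masks[spec.name], dtype=bool)
                if mask.size < spec.n_beads:
                    mask = np.concatenate(
                        [mask, np.zeros(spec.n_beads - mask.size, dtype=bool)]
                    )
                elif mask.size > spec.n_beads:
                    raise BinningError(
                        f"NAD mask for {spec.name} has {mask.size} bins, "
                        f"chromosome has {spec.n_beads}"
                    )
                specs.append(replace(spec, nad=mask))
            else:
                specs.append(spec)
        return GenomeTopology(
            specs,
            n_nucleolar=self.n_nucleolar,
            nucleolar_diameter=self.nucleolar_diameter,
            confinement_radius=self.confinement_radius,
            resolution=self.resolution,
            ploidy=self.ploidy,
        )

    # -- text I/O ---------------------------------------------------------
    def to_table(self, path: str | Path) -> None:
        """Write per-bead rows: chromosome, copy, bin, type, NAD flag."""
        names = [self.chromosomes[i].name for i in self.chrom_id]
        df = pd.DataFrame(
            {
                "chrom": names,
                "copy": self.copy_id,
                "bin": self.bin_index,
                "type": [_TYPE_CHARS[t] for t in self.types],
                "nad": self.nad_mask.astype(int),
            }
        )
        with open(path, "w") as fh:
            fh.write(
                f"# nucleodrop topology: n_nucleolar={self.n_nucleolar} "
                f"nucleolar_diameter={self.nucleolar_diameter:g} "
                f"confinement_radius={self.confinement_radius:g} "
                f"resolution={self.resolution}\n"
            )
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_table(cls, path: str | Path) -> "GenomeTopology":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(
                kv.split("=") for kv in header.split(":", 1)[1].split() if "=" in kv
            )
            df = pd.read_csv(fh, sep="\t")
        specs = []
        hap = df[df["copy"] == 0]
        for chrom, grp in hap.groupby("chrom", sort=False):
            grp = grp.sort_values("bin")
            specs.append(
                ChromosomeSpec(
                    name=str(chrom),
                    types=grp["type"].to_numpy(),
                    nad=grp["nad"].to_numpy().astype(bool),
                )
            )
        return cls(
            specs,
            n_nucleolar=int(meta["n_nucleolar"]),
            nucleolar_diameter=float(meta["nucleolar_diameter"]),
            confinement_radius=float(meta["confinement_radius"]),
            resolution=int(meta["resolution"]),
        )


def build_topology(
    chrom_spec: Sequence[ChromosomeSpec],
    n_nucleolar: int = 500,
    confinement_radius: float = 19.7,
    resolution: int = 1_000_000,
    nucleolar_diameter: float = 0.5,
) -> GenomeTopology:
    """Build a diploid topology from a haploid chromosome spec (homologs are
    duplicated) and register ``n_nucleolar`` free nucleolar particles."""
    if len(chrom_spec) == 0:
        raise ValueError(
            "chromosome spec must be non-empty; use GenomeTopology.particles_only "
            "for a chromatin-free system"
        )
    return GenomeTopology(
        chrom_spec,
        n_nucleolar=n_nucleolar,
        nucleolar_diameter=nucleolar_diameter,
        confinement_radius=confinement_radius,
        resolution=resolution,
    )


@dataclass
class SimulationState:
    """Positions and velocities (reduced units) of all beads and particles.

    Chromatin beads come first (in topology order), nucleolar particles last.
    """

    topology: GenomeTopology
    positions: np.ndarray
    velocities: np.ndarray
    seed: int | None = None
    step: int = 0

    def __post_init__(self) -> None:
        n = self.topology.n_particles
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError(f"state arrays must have shape ({n}, 3)")

    def copy(self) -> "SimulationState":
        return SimulationState(
            topology=self.topology,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            seed=self.seed,
            step=self.step,
        )

    @property
    def nucleolar_positions(self) -> np.ndarray:
        return self.positions[self.topology.n_chromatin :]

    def radial_distances(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)

    def assert_confined(self) -> None:
        r = self.radial_distances()
        if not (r < self.topology.confinement_radius).all():
            raise ValueError(
                f"particle outside confinement: max |r| = {r.max():.3f} "
                f">= R_N = {self.topology.confinement_radius:.3f}"
            )


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform points in a sphere: isotropic directions, radii ~ R*u^(1/3)."""
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return direction * r[:, None]


def _confined_walk(
    rng: np.random.Generator,
    n: int,
    radius: float,
    existing: list[np.ndarray],
    bond_length: float,
    min_separation: float,
    territory: tuple[np.ndarray, float] | None = None,
    max_tries: int = 40,
) -> np.ndarray:
    """Self-avoiding confined random walk: each step keeps |r| < radius and
    tries to stay ``min_separation`` away from previously placed beads.

    ``territory`` (center, radius) additionally confines the walk to a
    sub-sphere, producing chromosome-territory-like initial organisation
    instead of fully interpenetrating chains.  After ``max_tries`` rejected
    proposals the best candidate is accepted (the relaxation stage removes
    residual clashes)."""

    def inside(p: np.ndarray) -> bool:
        if np.linalg.norm(p) >= radius:
            return False
        if territory is not None:
            c, rt = territory
            if np.linalg.norm(p - c) >= rt:
                return False
        return True

    pts = np.empty((n, 3))
    others = np.concatenate(existing) if existing else np.empty((0, 3))
    for _ in range(200):
        if territory is not None:
            c, rt = territory
            start = c + _uniform_in_sphere(rng, 1, rt * 0.8)[0]
            if np.linalg.norm(start) >= radius:
                continue
        else:
            start = _uniform_in_sphere(rng, 1, radius * 0.9)[0]
        if others.size == 0 or np.linalg.norm(others - start, axis=1).min() > min_separation:
            break
    pts[0] = start
    for i in range(1, n):
        best, best_d = None, -1.0
        for _ in range(max_tries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = pts[i - 1] + bond_length * u
            if not inside(cand):
                continue
            d = np.linalg.norm(pts[: i - 1] - cand, axis=1).min() if i > 1 else np.inf
            if others.size:
                d = min(d, np.linalg.norm(others - cand, axis=1).min())
            if d > min_separation:
                best = cand
                break
            if d > best_d:
                best, best_d = cand, d
        if best is None:  # every proposal left the region: step back toward it
            target = -pts[i - 1] if territory is None else territory[0] - pts[i - 1]
            nrm = np.linalg.norm(target)
            best = pts[i - 1] + bond_length * (
                target / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
            )
        pts[i] = best
    return pts


def initialize_configuration(
    topology: GenomeTopology,
    chromatin_positions: np.ndarray | None = None,
    seed: int = 0,
    bond_length: float = 1.0,
    min_separation: float = 0.7,
    wall_margin: float = 0.6,
    territory_init: bool = True,
) -> SimulationState:
    """Initial configuration: chromatin as confined self-avoiding random walks
    (or caller-supplied positions), nucleolar particles uniformly random in
    the confinement sphere.  Deterministic under ``seed``.

    With ``territory_init`` each chain is additionally confined to a random
    sub-sphere sized for melt-like local density, giving the
    chromosome-territory organisation that chromosomes keep over the
    timescales simulated (interphase chromosomes do not mix).

    Raises :class:`PackingError` when the total excluded volume of beads and
    particles exceeds the confinement volume.
    """
    rng = np.random.default_rng(seed)
    R = topology.confinement_radius
    bead_vol = topology.n_chromatin * (4.0 / 3.0) * math.pi * 0.5**3
    part_vol = topology.n_nucleolar * (4.0 / 3.0) * math.pi * (
        topology.nucleolar_diameter / 2.0
    ) ** 3
    sphere_vol = (4.0 / 3.0) * math.pi * R**3
    if bead_vol + part_vol > sphere_vol:
        raise PackingError(
            f"total particle volume {bead_vol + part_vol:.1f} exceeds "
            f"confinement volume {sphere_vol:.1f}"
        )

    inner = R - wall_margin
    if chromatin_positions is None:
        n_chains = topology.ploidy * len(topology.chromosomes)
        territories = None
        if territory_init and n_chains > 1:
            # territory radius sized for the chain at melt-like local density
            centers = _uniform_in_sphere(rng, n_chains, 0.55 * inner)
            territories = []
            for copy in range(topology.ploidy):
                for spec in topology.chromosomes:
                    r_t = max(
                        2.5, 1.3 * (3.0 * spec.n_beads / (4.0 * math.pi * 0.6)) ** (1 / 3)
                    )
                    territories.append(r_t)
            territories = [
                (centers[k], territories[k]) for k in range(n_chains)
            ]
        chains: list[np.ndarray] = []
        k = 0
        # walk each chromosome copy independently
        for copy in range(topology.ploidy):
            for spec in topology.chromosomes:
                chains.append(
                    _confined_walk(
                        rng,
                        spec.n_beads,
                        inner,
                        chains,
                        bond_length,
                        min_separation,
                        territory=None if territories is None else territories[k],
                    )
                )
                k += 1
        chromatin = (
            np.concatenate(chains) if chains else np.empty((0, 3))
        )
    else:
        chromatin = np.asarray(chromatin_positions, dtype=np.float64)
        if chromatin.shape != (topology.n_chromatin, 3):
            raise ValueError("chromatin_positions shape mismatch")
        if (np.linalg.norm(chromatin, axis=1) >= R).any():
            raise ValueError("chromatin_positions outside confinement")
    nucleolar = _uniform_in_sphere(rng, topology.n_nucleolar, inner)
    if topology.n_nucleolar:
        # resample particles landing deep inside a chromatin bead or another
        # particle; a uniform redraw preserves the uniform-in-sphere law on
        # the accepted region
        from scipy.spatial import cKDTree

        clearance = 0.4 * (topology.nucleolar_diameter + 1.0)
        self_clearance = 0.8 * topology.nucleolar_diameter
        tree = cKDTree(chromatin) if topology.n_chromatin else None
        for _ in range(200):
            bad = np.zeros(topology.n_nucleolar, dtype=bool)
            if tree is not None:
                d, _idx = tree.query(nucleolar)
                bad |= d < clearance
            if topology.n_nucleolar > 1:
                self_tree = cKDTree(nucleolar)
                dd, _ = self_tree.query(nucleolar, k=2)
                bad |= dd[:, 1] < self_clearance
            if not bad.any():
                break
            nucleolar[bad] = _uniform_in_sphere(rng, int(bad.sum()), inner)
    positions = np.concatenate([chromatin, nucleolar], axis=0)
    state = SimulationState(
        topology=topology,
        positions=positions,
        velocities=np.zeros_like(positions),
        seed=seed,
    )
    state.assert_confined()
    return state


def relax(
    state: SimulationState,
    table=None,
    n_steps: int = 400_000,
    params=None,
    seed: int | None = None,
):
    """Equilibrate a freshly built configuration to remove steric clashes.

    Runs ``n_steps`` of Langevin dynamics with every nucleolar interaction
    epsilon temporarily set to 1.0 k_B*T (so no droplets nucleate during
    equilibration) and returns the final state.  The first stage runs in
    push-off mode (per-step displacement clamped) so the steep repulsion of
    freshly built overlapping configurations anneals instead of diverging.
    ``n_steps == 0`` returns the input unchanged.
    """
    from .engine import IntegratorParams, run
    from .interactions import InteractionTable

    if n_steps == 0:
        return state
    if table is None:
        table = InteractionTable.for_topology(state.topology)
    table = table.relaxed()
    if params is None:
        params = IntegratorParams(record_every=n_steps, seed=seed if seed is not None else 0)
    pushoff = min(4000, max(1, n_steps // 10))
    _, state = run(state, pushoff, params, table, max_displacement=0.05)
    state.velocities[:] = 0.0
    if n_steps > pushoff:
        _, state = run(state, n_steps - pushoff, params, table)
    return state
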