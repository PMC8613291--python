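"""Synthetic presets and fixtures: scaled genomes, NAD signal tracks,
pre-built droplet configurations, and scripted trajectories with known
ground truth for the analytics.

Presets scale the full nucleus setup (diploid genome at 1 Mb, 500 nucleolar
particles, 19.7 sigma confinement) down to desk size while preserving the
nucleolar volume fraction: the particle diameter of each preset solves
sigma_p^3 * N_P / R_N^3 = const, anchored at the full-scale values.  NAD
bins are placed in contiguous runs (nucleolus-associated domains are
domain-like, not scattered single bins).

Every fixture is bit-for-bit reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    ChromosomeSpec,
    GenomeTopology,
    SignalTrack,
    SimulationState,
    annotate_nads,
    build_topology,
    initialize_configuration,
)

__all__ = [
    "Preset",
    "PRESETS",
    "synthetic_nad_track",
    "synthetic_chromosomes",
    "make_topology",
    "two_droplet_fixture",
    "free_particle_state",
    "condensed_positions",
    "scripted_trajectory",
    "fractional_brownian_track",
]

# anchor values of the full-scale setup
_FULL_N = 500
_FULL_RN = 19.7
_FULL_SIGMA_P = 0.5

# approximate human chromosome lengths (chr1-22, X) in Mb
_HUMAN_MB = [
    249, 242, 198, 190, 182, 171, 159, 145, 138, 134, 135, 133,
    114, 107, 102, 90, 83, 80, 59, 64, 47, 51, 156,
]


@dataclass(frozen=True)
class Preset:
    """A scaled study condition: chromosome lengths (haploid, in beads),
    nucleolar count, confinement radius and NAD fraction.

    ``nucleolar_diameter`` preserves the full-scale nucleolar volume
    fraction sigma_p^3 * N_P / R_N^3.
    """

    name: str
    chromosome_lengths: tuple[int, ...]
    n_nucleolar: int
    confinement_radius: float
    nad_fraction: float = 0.3
    resolution: int = 1_000_000

    @property
    def nucleolar_diameter(self) -> float:
        return _FULL_SIGMA_P * (
            (_FULL_N / self.n_nucleolar)
            * (self.confinement_radius / _FULL_RN) ** 3
        ) ** (1.0 / 3.0)

    @property
    def n_bins(self) -> int:
        return int(sum(self.chromosome_lengths))


PRESETS: dict[str, Preset] = {
    "full": Preset(
        name="full",
        chromosome_lengths=tuple(_HUMAN_MB),
        n_nucleolar=500,
        confinement_radius=19.7,
    ),
    "small": Preset(
        name="small",
        chromosome_lengths=(120,) * 8,
        n_nucleolar=150,
        confinement_radius=10.5,
    ),
    "tiny": Preset(
        name="tiny",
        chromosome_lengths=(50,) * 4,
        n_nucleolar=60,
        confinement_radius=7.0,
    ),
}


def _as_preset(preset: str | Preset) -> Preset:
    if isinstance(preset, Preset):
        return preset
    try:
        return PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")


def synthetic_nad_track(
    n_bins: int,
    nad_fraction: float,
    signal_range: tuple[float, float] = (0.0, 30.0),
    seed: int = 0,
    threshold: float = 15.0,
    run_length: int = 5,
    chrom_lengths: dict[str, int] | None = None,
    bin_size: int = 1_000_000,
) -> SignalTrack:
    """Synthetic nucleolar-to-genomic signal track with a known NAD content.

    Exactly ceil(nad_fraction * n_bins) bins carry a signal strictly above
    ``threshold``; they are placed in contiguous runs of ``run_length`` bins
    (the last run may be shorter).  Background bins get values strictly
    below the threshold.  Deterministic under ``seed``.
    """
    if not (0.0 <= nad_fraction <= 1.0):
        raise ValueError("nad_fraction must be in [0, 1]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = signal_range
    if not (lo < threshold < hi):
        raise ValueError("signal_range must bracket the threshold")
    rng = np.random.default_rng(seed)
    k = math.ceil(nad_fraction * n_bins)
    mask = np.zeros(n_bins, dtype=bool)
    remaining = k
    free = np.ones(n_bins, dtype=bool)
    while remaining > 0:
        length = min(run_length, remaining)
        # candidate starts where `length` consecutive bins are free
        ok = np.array(
            [free[s : s + length].all() for s in range(n_bins - length + 1)]
        )
        starts = np.flatnonzero(ok)
        if starts.size == 0:
            length = 1
            starts = np.flatnonzero(free)
            if starts.size == 0:  # spacers used up: any non-NAD bin will do
                starts = np.flatnonzero(~mask)
        s = int(rng.choice(starts))
        mask[s : s + length] = True
        free[s : s + length] = False
        # keep one free spacer so runs stay distinct where possible
        if s + length < n_bins:
            free[s + length] = False
        remaining -= length
    margin = 0.02 * (hi - lo)
    values = rng.uniform(lo, threshold - margin, size=n_bins)
    values[mask] = rng.uniform(threshold + margin, hi, size=int(mask.sum()))

    if chrom_lengths is None:
        chrom_lengths = {"chr1": n_bins}
    if sum(chrom_lengths.values()) != n_bins:
        raise ValueError("chrom_lengths must sum to n_bins")
    rows = []
    offset = 0
    for chrom, nb in chrom_lengths.items():
        for b in range(nb):
            rows.append(
                (chrom, b * bin_size, (b + 1) * bin_size, float(values[offset + b]))
            )
        offset += nb
    return SignalTrack(
        data=pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]),
        bin_size=bin_size,
    )


def synthetic_chromosomes(
    lengths: tuple[int, ...],
    seed: int = 0,
    a_fraction: float = 0.5,
    centromere_fraction: float = 0.06,
    centromere_position: float = 0.5,
    block_mean: int = 5,
) -> list[ChromosomeSpec]:
    """Synthetic haploid chromosome specs with blocky A/B compartments and one
    contiguous centromeric (C) run per chromosome.

    A/B identities alternate in geometric blocks (mean ``block_mean`` bins),
    mimicking the domain-like checkerboard of real compartments; the C run
    sits at fractional position ``centromere_position``.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for ci, n in enumerate(lengths):
        types = np.empty(n, dtype=np.int8)
        pos = 0
        current = 0 if rng.random() < a_fraction else 1
        while pos < n:
            block = 1 + rng.geometric(1.0 / block_mean)
            types[pos : pos + block] = current
            pos += block
            current = 1 - current
        c_len = max(1, round(centromere_fraction * n))
        c_start = int(round(centromere_position * n - c_len / 2))
        c_start = min(max(c_start, 0), n - c_len)
        types[c_start : c_start + c_len] = 2
        specs.append(ChromosomeSpec(name=f"chr{ci + 1}", types=types))
    return specs


def make_topology(
    preset: str | Preset = "tiny",
    seed: int = 0,
    nad_fraction: float | None = None,
    threshold: float = 15.0,
    nad_run_length: int = 20,
    **chromosome_kwargs,
) -> tuple[GenomeTopology, SignalTrack]:
    """Build a preset topology with a synthetic NAD track applied.

    Returns (topology, track); the NAD mask comes from thresholding the
    track, mirrored onto homologs.  NADs are laid out in long contiguous
    blocks (default 20 bins), mirroring the concentration of
    nucleolus-associated domains on a few chromosome arms in vivo, so that
    distinct blocks usually land on distinct chromosomes.  Deterministic
    under ``seed``.
    """
    preset = _as_preset(preset)
    frac = preset.nad_fraction if nad_fraction is None else nad_fraction
    specs = synthetic_chromosomes(preset.chromosome_lengths, seed=seed, **chromosome_kwargs)
    chrom_lengths = {s.name: s.n_beads for s in specs}
    track = synthetic_nad_track(
        preset.n_bins,
        frac,
        seed=seed + 1,
        threshold=threshold,
        run_length=nad_run_length,
        chrom_lengths=chrom_lengths,
        bin_size=preset.resolution,
    )
    topo = build_topology(
        specs,
        n_nucleolar=preset.n_nucleolar,
        confinement_radius=preset.confinement_radius,
        resolution=preset.resolution,
        nucleolar_diameter=preset.nucleolar_diameter,
    )
    masks = annotate_nads(track, threshold=threshold, chrom_bins=chrom_lengths)
    return topo.with_nad_masks(masks), track


def _evict_chromatin(
    positions: np.ndarray,
    n_chromatin: int,
    centers: list[np.ndarray],
    radii: list[float],
    margin: float = 0.6,
    confinement_radius: float | None = None,
) -> None:
    """Move chromatin beads radially out of droplet volumes (in place), so
    no bead starts trapped inside a pre-built particle lattice.  Beads are
    kept inside the confinement sphere when its radius is given; passes
    iterate because leaving one droplet (or the wall region) can land a
    bead inside another."""
    chromatin = positions[:n_chromatin]
    if not n_chromatin:
        return
    for _ in range(10):
        moved = False
        for center, radius in zip(centers, radii):
            center = np.asarray(center, dtype=float)
            d = chromatin - center
            dist = np.linalg.norm(d, axis=1)
            inside = dist < radius + margin
            if inside.any():
                moved = True
                dirs = d[inside]
                norms = np.linalg.norm(dirs, axis=1, keepdims=True)
                norms[norms < 1e-9] = 1.0
                chromatin[inside] = center + dirs / norms * (radius + margin)
        if confinement_radius is not None:
            rr = np.linalg.norm(chromatin, axis=1)
            out = rr >= confinement_radius - 0.6
            if out.any():
                moved = True
                chromatin[out] *= ((confinement_radius - 0.6) / rr[out])[:, None]
        if not moved:
            break


def condensed_positions(
    n: int, spacing: float, center: np.ndarray | None = None
) -> np.ndarray:
    """Compact near-spherical droplet: the ``n`` sites of a cubic lattice with
    the given spacing closest to the center."""
    if n < 1:
        raise ValueError("n must be >= 1")
    side = int(math.ceil((2.0 * n) ** (1.0 / 3.0))) + 2
    ax = (np.arange(side) - (side - 1) / 2.0) * spacing
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    order = np.argsort(np.linalg.norm(grid, axis=1))
    pts = grid[order[:n]]
    pts = pts - pts.mean(axis=0)
    if center is not None:
        pts = pts + np.asarray(center, dtype=float)
    return pts


def free_particle_state(
    n: int,
    nucleolar_diameter: float,
    confinement_radius: float,
    seed: int = 0,
) -> SimulationState:
    """Chromatin-free state: ``n`` nucleolar particles uniformly random in the
    confinement sphere (the no-network control condition)."""
    topo = GenomeTopology.particles_only(
        n, nucleolar_diameter=nucleolar_diameter, confinement_radius=confinement_radius
    )
    return initialize_configuration(topo, seed=seed)


def two_droplet_fixture(
    preset: str | Preset = "tiny",
    separation: float = 4.0,
    seed: int = 0,
    include_chromatin: bool = True,
    relax_steps: int = 3000,
) -> SimulationState:
    """Pre-built two-droplet configuration: two equal compact nucleolar
    spheres at the requested center separation, with chromatin (if included)
    relaxed around the frozen droplets.

    Requires ``separation`` at least the sum of the droplet radii (else the
    droplets would not be distinct) and small enough that both droplets fit
    inside the confinement.
    """
    preset = _as_preset(preset)
    spacing = 2 ** (1.0 / 6.0) * preset.nucleolar_diameter
    n_half = preset.n_nucleolar // 2
    half_a = condensed_positions(n_half, spacing)
    half_b = condensed_positions(preset.n_nucleolar - n_half, spacing)
    r_a = np.linalg.norm(half_a, axis=1).max() + spacing / 2
    r_b = np.linalg.norm(half_b, axis=1).max() + spacing / 2
    if separation < r_a + r_b:
        raise ValueError(
            f"separation {separation:g} below the sum of droplet radii "
            f"{r_a + r_b:.2f}"
        )
    if separation / 2 + max(r_a, r_b) >= preset.confinement_radius:
        raise ValueError("separation places droplets outside the confinement")
    droplets = np.concatenate(
        [
            half_a + np.array([-separation / 2.0, 0.0, 0.0]),
            half_b + np.array([+separation / 2.0, 0.0, 0.0]),
        ]
    )

    if include_chromatin:
        topo, _ = make_topology(preset, seed=seed)
    else:
        topo = GenomeTopology.particles_only(
            preset.n_nucleolar,
            nucleolar_diameter=preset.nucleolar_diameter,
            confinement_radius=preset.confinement_radius,
        )
    state = initialize_configuration(topo, seed=seed)
    state.positions[topo.n_chromatin :] = droplets
    state.velocities[:] = 0.0
    if include_chromatin:
        _evict_chromatin(
            state.positions,
            topo.n_chromatin,
            [np.array([-separation / 2, 0, 0]), np.array([+separation / 2, 0, 0])],
            [r_a, r_b],
            confinement_radius=preset.confinement_radius,
        )
    if include_chromatin and relax_steps > 0:
        from .engine import IntegratorParams, run
        from .interactions import InteractionTable

        table = InteractionTable.for_topology(topo).relaxed()
        frozen = topo.is_nucleolar
        params = IntegratorParams(record_every=relax_steps, seed=seed)
        _, state = run(
            state, relax_steps, params, table, frozen=frozen, max_displacement=0.05
        )
        state.velocities[:] = 0.0
    return state


def seeded_droplet_state(
    preset: str | Preset = "tiny",
    n_droplets: int = 3,
    seed: int = 0,
    include_chromatin: bool = True,
    relax_steps: int = 3000,
) -> SimulationState:
    """Pre-nucleated configuration: the nucleolar particles are split into
    ``n_droplets`` equal compact droplets.

    With chromatin, each droplet is centred on the centroid of one of the
    largest NAD blocks (heterogeneous nucleation happens at
    nucleolus-associated domains), and the chromatin is briefly relaxed
    around the frozen droplets.  Without chromatin, droplets start at
    well-separated positions at half the confinement radius.  Used to study
    coarsening from a common pre-nucleated start, since homogeneous
    nucleation from dilute vapor is far slower than any desk-scale run.
    """
    preset = _as_preset(preset)
    spacing = 2 ** (1.0 / 6.0) * preset.nucleolar_diameter
    n = preset.n_nucleolar
    sizes = [n // n_droplets] * n_droplets
    for k in range(n - sum(sizes)):
        sizes[k] += 1

    if include_chromatin:
        topo, _ = make_topology(preset, seed=seed)
    else:
        topo = GenomeTopology.particles_only(
            n,
            nucleolar_diameter=preset.nucleolar_diameter,
            confinement_radius=preset.confinement_radius,
        )
    state = initialize_configuration(topo, seed=seed)

    if include_chromatin:
        # centroids of the largest contiguous NAD blocks in the walked
        # chromatin configuration (homolog copies are distinct sites)
        flat_nad = topo.nad_mask
        nc = topo.n_chromatin
        runs: list[tuple[int, int]] = []
        i = 0
        while i < nc:
            if flat_nad[i]:
                j = i
                while (
                    j + 1 < nc
                    and flat_nad[j + 1]
                    and topo.chrom_id[j + 1] == topo.chrom_id[i]
                    and topo.copy_id[j + 1] == topo.copy_id[i]
                ):
                    j += 1
                runs.append((i, j + 1))
                i = j + 1
            else:
                i += 1
        runs.sort(key=lambda r: r[0] - r[1])  # longest first
        # among the major NAD blocks, anchor droplets on a maximally spread
        # subset (farthest-point greedy), so distinct droplets sit on
        # distant chromosome territories
        cand = [state.positions[a:b].mean(axis=0) for a, b in runs[: 3 * n_droplets]]
        if len(cand) <= n_droplets:
            centers = cand
        else:
            cand_arr = np.stack(cand)
            chosen = [0]
            while len(chosen) < n_droplets:
                d = np.min(
                    np.linalg.norm(
                        cand_arr[:, None, :] - cand_arr[None, chosen, :], axis=2
                    ),
                    axis=1,
                )
                d[chosen] = -1.0
                chosen.append(int(np.argmax(d)))
            centers = [cand[i] for i in chosen]
        while len(centers) < n_droplets:  # fewer blocks than droplets
            centers.append(
                _uniform_in_sphere(
                    np.random.default_rng(seed + len(centers)),
                    1,
                    0.6 * preset.confinement_radius,
                )[0]
            )
    else:
        # without a network the droplets' coalescence is diffusion limited;
        # they start close enough to meet well before desk-scale Kelvin
        # evaporation (absent at full scale) erodes them
        centers = [
            0.35 * preset.confinement_radius * d
            for d in _spread_directions(n_droplets)
        ]

    placed = []
    radii = []
    final_centers = []
    max_r = preset.confinement_radius - 1.0
    for size, center in zip(sizes, centers):
        center = np.asarray(center, dtype=float)
        r = np.linalg.norm(center)
        if r > max_r - 1.5:
            center = center * (max_r - 1.5) / r
        pts = condensed_positions(size, spacing, center=center)
        placed.append(pts)
        radii.append(np.linalg.norm(pts - center, axis=1).max() + spacing / 2)
        final_centers.append(center)
    state.positions[topo.n_chromatin :] = np.concatenate(placed)
    state.velocities[:] = 0.0
    if include_chromatin:
        _evict_chromatin(
            state.positions,
            topo.n_chromatin,
            final_centers,
            radii,
            confinement_radius=preset.confinement_radius,
        )

    if include_chromatin and relax_steps > 0:
        from .engine import IntegratorParams, run
        from .interactions import InteractionTable

        table = InteractionTable.for_topology(topo).relaxed()
        params = IntegratorParams(record_every=relax_steps, seed=seed)
        _, state = run(
            state,
            relax_steps,
            params,
            table,
            frozen=topo.is_nucleolar,
            max_displacement=0.05,
        )
        state.velocities[:] = 0.0
        # short unfrozen push-off anneals any residual contact
        _, state = run(
            state, 500, IntegratorParams(record_every=500, seed=seed), table,
            max_displacement=0.05,
        )
        state.velocities[:] = 0.0
    return state


def fractional_brownian_track(
    n_steps: int, hurst: float, seed: int = 0, scale: float = 1.0
) -> np.ndarray:
    """3D fractional Brownian motion with Hurst exponent H (MSD ~ t^(2H)),
    generated by Cholesky factorization of the fGn covariance."""
    if not (0.0 < hurst < 1.0):
        raise ValueError("hurst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    k = np.arange(n_steps)
    lag = np.abs(k[:, None] - k[None, :]).astype(float)
    h2 = 2.0 * hurst
    cov = 0.5 * ((lag + 1) ** h2 - 2 * lag**h2 + np.abs(lag - 1) ** h2)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_steps))
    increments = chol @ rng.standard_normal((n_steps, 3))
    track = np.concatenate([np.zeros((1, 3)), np.cumsum(increments, axis=0)])
    return scale * track


def _spread_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (the +/- coordinate axes, cycled)."""
    axes = np.concatenate([np.eye(3), -np.eye(3)])
    if n > 6:
        raise ValueError("at most 6 blobs supported")
    return axes[:n]


def _blob_frames(
    centers: np.ndarray, offsets: list[np.ndarray], jitter: float, rng
) -> np.ndarray:
    """Assemble frames from per-blob center tracks and rigid member offsets."""
    n_frames = centers.shape[1]
    frames = []
    for t in range(n_frames):
        parts = [
            centers[b, t] + offsets[b] + jitter * rng.standard_normal(offsets[b].shape)
            for b in range(len(offsets))
        ]
        frames.append(np.concatenate(parts))
    return np.stack(frames)


def scripted_trajectory(kind: str, seed: int = 0, **params):
    """Deterministic synthetic trajectory with a known embedded ground truth.

    Kinds
    -----
    merge:
        Two droplets drift together and coalesce at ``merge_frame``; the
        intra-droplet spread stays constant (one BMC event).
    evaporate:
        One of two droplets inflates and disperses (one DOR event).
    ballistic:
        Rigid droplets whose centers move at constant velocity (MSD
        exponent 2).
    fbm:
        Droplet centers follow fractional Brownian motion with exponent
        ``alpha`` (default 0.5).

    Returns an engine :class:`~nucleodrop.engine.Trajectory` whose particles
    are all nucleolar; frame times are 1 tau_B apart.
    """
    from .engine import Trajectory

    rng = np.random.default_rng(seed)
    n_per = int(params.pop("n_per", 20))
    n_frames = int(params.pop("n_frames", 60))
    spacing = float(params.pop("spacing", 0.45))
    jitter = float(params.pop("jitter", 0.02))

    if kind == "merge":
        merge_frame = int(params.pop("merge_frame", n_frames // 2))
        sep0 = float(params.pop("initial_separation", 8.0))
        offs = [condensed_positions(n_per, spacing) for _ in range(2)]
        # keep the blobs clearly distinct until the scripted frame, then fuse
        r_blob = max(np.linalg.norm(o, axis=1).max() for o in offs)
        s_contact = 2.0 * r_blob + 1.2
        centers = np.zeros((2, n_frames, 3))
        for t in range(n_frames):
            if t < merge_frame:
                s = s_contact + (sep0 - s_contact) * (1.0 - t / merge_frame)
            else:
                s = 0.4
            centers[0, t, 0] = -s / 2
            centers[1, t, 0] = +s / 2
        frames = _blob_frames(centers, offs, jitter, rng)
    elif kind == "evaporate":
        vanish_frame = int(params.pop("vanish_frame", n_frames // 2))
        sep = float(params.pop("initial_separation", 10.0))
        offs_stable = condensed_positions(n_per, spacing)
        # denser lattice so the inflating blob stays one cluster until it
        # finally disperses
        offs_evap = condensed_positions(n_per, min(spacing, 0.35))
        frames = []
        for t in range(n_frames):
            stable = np.array([-sep / 2, 0.0, 0.0]) + offs_stable
            if t < vanish_frame:
                # mean pairwise distance inflates ~2x before the vanish
                scale = 1.0 + 1.0 * t / vanish_frame
                evap = np.array([+sep / 2, 0.0, 0.0]) + scale * offs_evap
            else:
                # fully evaporated: particles scattered far apart
                evap = np.array([+sep / 2, 0.0, 0.0]) + 20.0 * offs_evap
            frames.append(
                np.concatenate(
                    [
                        stable + jitter * rng.standard_normal(stable.shape),
                        evap + jitter * rng.standard_normal(evap.shape),
                    ]
                )
            )
        frames = np.stack(frames)
    elif kind == "ballistic":
        n_blobs = int(params.pop("n_blobs", 3))
        speed = float(params.pop("speed", 0.1))
        offs = [condensed_positions(n_per, spacing) for _ in range(n_blobs)]
        base = 10.0 * _spread_directions(n_blobs)
        # outward motion so blobs never collide
        vel = speed * _spread_directions(n_blobs)
        t_ax = np.arange(n_frames)
        centers = base[:, None, :] + vel[:, None, :] * t_ax[None, :, None]
        frames = _blob_frames(centers, offs, jitter, rng)
    elif kind == "fbm":
        alpha = float(params.pop("alpha", 0.5))
        n_blobs = int(params.pop("n_blobs", 3))
        scale = float(params.pop("scale", 0.3))
        offs = [condensed_positions(n_per, spacing) for _ in range(n_blobs)]
        base = 10.0 * _spread_directions(n_blobs)
        centers = np.stack(
            [
                base[b]
                + fractional_brownian_track(
                    n_frames - 1, alpha / 2.0, seed=int(rng.integers(2**31)), scale=scale
                )
                for b in range(n_blobs)
            ]
        )
        frames = _blob_frames(centers, offs, jitter, rng)
    else:
        raise ValueError(f"unknown scripted trajectory kind {kind!r}")
    if params:
        raise TypeError(f"unused parameters: {sorted(params)}")

    return Trajectory(
        positions=frames,
        dt=1.0,
        record_every=1,
        is_nucleolar=np.ones(frames.shape[1], dtype=bool),
        seed=seed,
    )
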