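"""Desk-scale study protocols: droplet persistence, coarsening contrast and
droplet-fusion kinetics, with and without the chromatin network.

These drivers freeze the scaled-down study conditions used by the test suite
and document the down-scaling compromises:

* Homogeneous nucleation of nucleolar droplets from dispersed vapor is far
  too rare to observe in desk-scale runs (the particle phase sits close to
  vapor-liquid coexistence), so coarsening studies start from pre-nucleated
  droplets (:func:`nucleodrop.fixtures.seeded_droplet_state` and the
  supersaturated variant here).
* Small droplets (tens of particles) have a strongly elevated vapor pressure
  (Kelvin effect); in the chromatin-free control they eventually evaporate
  outright, an artifact of down-scaling with no full-scale counterpart.
  Comparison horizons are therefore set just after the control finishes
  coalescing and before finite-size evaporation empties it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.stats import linregress

from .clusters import ClusterParams, ClusterTimeSeries, cluster_series, growth_exponent
from .coalescence import NeckProfile, droplet_radius_from_rg, neck_profile
from .engine import IntegratorParams, maxwell_boltzmann_velocities, run
from .fixtures import (
    PRESETS,
    Preset,
    _as_preset,
    _evict_chromatin,
    _spread_directions,
    condensed_positions,
    make_topology,
    seeded_droplet_state,
)
from .genome import GenomeTopology, SimulationState, initialize_configuration
from .interactions import InteractionTable
from .sampling import droplet_rg

__all__ = [
    "PersistenceResult",
    "droplet_persistence_experiment",
    "CoarseningResult",
    "coarsening_contrast_experiment",
    "FusionResult",
    "fusion_experiment",
]


# ---------------------------------------------------------------------------
# droplet persistence: network vs chromatin-free control
# ---------------------------------------------------------------------------


@dataclass
class PersistenceResult:
    """Final droplet counts per seed for one condition."""

    final_counts: list[int]
    series: list[ClusterTimeSeries] = field(repr=False, default_factory=list)

    def majority_at_least(self, n: int) -> bool:
        return sum(c >= n for c in self.final_counts) > len(self.final_counts) / 2

    def majority_equal(self, n: int) -> bool:
        return sum(c == n for c in self.final_counts) > len(self.final_counts) / 2


def droplet_persistence_experiment(
    with_network: bool,
    seeds=range(5),
    preset: str | Preset = "tiny",
    n_droplets: int = 2,
    n_steps: int = 20_000,
    record_every: int = 1_000,
    keep_series: bool = False,
) -> PersistenceResult:
    """Persistence of pre-nucleated droplets over a fixed horizon.

    Both conditions start from ``n_droplets`` equal droplets (on NAD blocks
    with the network, at spread positions without).  The horizon (default
    20,000 steps = 160 tau_B, about ten simulated minutes) is set after the
    chromatin-free system finishes coalescing and before desk-scale Kelvin
    evaporation empties it.  The reported count per seed is the median over
    the last quarter of recorded frames.
    """
    preset = _as_preset(preset)
    finals: list[int] = []
    all_series = []
    for seed in seeds:
        state = seeded_droplet_state(
            preset, n_droplets=n_droplets, seed=seed, include_chromatin=with_network
        )
        table = InteractionTable.for_topology(state.topology)
        params = IntegratorParams(record_every=record_every, seed=seed)
        traj, _ = run(state, n_steps, params, table)
        cp = ClusterParams.for_topology(state.topology)
        series = cluster_series(traj, cp)
        tail = max(3, series.counts.size // 4)
        finals.append(int(np.median(series.counts[-tail:])))
        if keep_series:
            all_series.append(series)
    return PersistenceResult(final_counts=finals, series=all_series)


# ---------------------------------------------------------------------------
# coarsening contrast: growth exponent with vs without the network
# ---------------------------------------------------------------------------


@dataclass
class CoarseningResult:
    betas: list[float]
    series: list[ClusterTimeSeries] = field(repr=False, default_factory=list)

    @property
    def mean_beta(self) -> float:
        return float(np.nanmean(self.betas))


def _supersaturated_seeded_state(
    seed: int,
    with_network: bool,
    n_particles: int,
    diameter: float,
    n_droplets: int,
    droplet_size: int,
    confinement_radius: float,
) -> tuple[SimulationState, GenomeTopology]:
    """Seeded droplets plus free vapor, with or without the tiny chromatin."""
    spacing = 2 ** (1.0 / 6.0) * diameter
    if with_network:
        base, _ = make_topology("tiny", seed=seed)
        topo = GenomeTopology(
            base.chromosomes,
            n_nucleolar=n_particles,
            nucleolar_diameter=diameter,
            confinement_radius=confinement_radius,
            resolution=base.resolution,
        )
    else:
        topo = GenomeTopology.particles_only(
            n_particles,
            nucleolar_diameter=diameter,
            confinement_radius=confinement_radius,
        )
    state = initialize_configuration(topo, seed=seed)
    R = confinement_radius
    if with_network:
        nad = topo.nad_mask
        nc = topo.n_chromatin
        runs = []
        i = 0
        while i < nc:
            if nad[i]:
                j = i
                while (
                    j + 1 < nc
                    and nad[j + 1]
                    and topo.chrom_id[j + 1] == topo.chrom_id[i]
                    and topo.copy_id[j + 1] == topo.copy_id[i]
                ):
                    j += 1
                runs.append((i, j + 1))
                i = j + 1
            else:
                i += 1
        runs.sort(key=lambda r: r[0] - r[1])
        centers = [state.positions[a:b].mean(axis=0) for a, b in runs[:n_droplets]]
    else:
        centers = [0.5 * R * d for d in _spread_directions(n_droplets)]
    placed, radii, fcent = [], [], []
    for c in centers:
        c = np.asarray(c, dtype=float)
        r = np.linalg.norm(c)
        if r > R - 2.5:
            c = c * (R - 2.5) / r
        pts = condensed_positions(droplet_size, spacing, center=c)
        placed.append(pts)
        radii.append(np.linalg.norm(pts - c, axis=1).max() + spacing / 2)
        fcent.append(c)
    drop = np.concatenate(placed)
    state.positions[topo.n_chromatin : topo.n_chromatin + drop.shape[0]] = drop
    # re-draw vapor particles that landed inside a droplet volume or on top
    # of each other (uniform redraws keep the vapor distribution uniform on
    # the allowed region)
    from scipy.spatial import cKDTree

    vap = state.positions[topo.n_chromatin + drop.shape[0] :]
    rng = np.random.default_rng(seed + 7)
    clearance = 0.8 * diameter
    for _ in range(300):
        bad = np.zeros(vap.shape[0], dtype=bool)
        for c, rad in zip(fcent, radii):
            bad |= np.linalg.norm(vap - c, axis=1) < rad + 0.4
        if vap.shape[0] > 1:
            dd, _ = cKDTree(vap).query(vap, k=2)
            bad |= dd[:, 1] < clearance
        if not bad.any():
            break
        u = rng.normal(size=(int(bad.sum()), 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        vap[bad] = u * ((R - 1.0) * rng.random(int(bad.sum())) ** (1 / 3))[:, None]
    table = InteractionTable.for_topology(topo).relaxed()
    if with_network:
        _evict_chromatin(
            state.positions, topo.n_chromatin, fcent, radii,
            confinement_radius=R,
        )
        _, state = run(
            state,
            3000,
            IntegratorParams(record_every=3000, seed=seed),
            table,
            frozen=topo.is_nucleolar,
            max_displacement=0.05,
        )
        state.velocities[:] = 0.0
    # short unfrozen push-off anneals any residual contact before dynamics
    _, state = run(
        state,
        500,
        IntegratorParams(record_every=500, seed=seed),
        table,
        max_displacement=0.05,
    )
    state.velocities[:] = 0.0
    return state, topo


def coarsening_contrast_experiment(
    with_network: bool,
    seeds=range(5),
    n_particles: int = 160,
    diameter: float = 0.4,
    n_droplets: int = 6,
    n_steps: int = 40_000,
    record_every: int = 500,
    confinement_radius: float = 7.0,
    keep_series: bool = False,
) -> CoarseningResult:
    """Coarsening exponent beta from a cascade of pre-nucleated droplets.

    Six droplets are seeded (on NAD anchors with the network, spread without)
    and the dominant droplet size is fitted as size ~ t^beta over the active
    multi-droplet phase (frames with >= 2 droplets).  The size metric is the
    mass-equivalent radius (largest droplet particle count)^(1/3): with only
    a handful of droplets the largest-cluster growth law carries the merge
    cascade cleanly, while mean-size and R_g-based metrics are dominated by
    evaporation and by the ragged shapes of chromatin-wetted clusters.
    """
    droplet_size = n_particles // n_droplets
    betas = []
    all_series = []
    for seed in seeds:
        state, topo = _supersaturated_seeded_state(
            seed,
            with_network,
            n_particles,
            diameter,
            n_droplets,
            droplet_size,
            confinement_radius,
        )
        table = InteractionTable.for_topology(topo)
        params = IntegratorParams(record_every=record_every, seed=seed)
        traj, _ = run(state, n_steps, params, table)
        cp = ClusterParams(
            eps=1.07 * 2 ** (1.0 / 6.0) * diameter, min_samples=4, min_droplet_size=8
        )
        series = cluster_series(traj, cp)
        largest_mass = np.array(
            [
                max(c.size for c in cl) if cl else np.nan
                for cl in series.clusters
            ],
            dtype=float,
        )
        size_metric = largest_mass ** (1.0 / 3.0)
        active = np.flatnonzero(series.counts >= 2)
        try:
            betas.append(growth_exponent(series.times[active], size_metric[active]))
        except ValueError:
            betas.append(float("nan"))
        if keep_series:
            all_series.append(series)
    return CoarseningResult(betas=betas, series=all_series)


# ---------------------------------------------------------------------------
# two-droplet fusion: neck growth kinetics
# ---------------------------------------------------------------------------


@dataclass
class FusionResult:
    times: np.ndarray
    mean_normalized: np.ndarray
    exponent: float | None
    n_fit_points: int
    per_seed_normalized: np.ndarray = field(repr=False, default=None)


def fusion_experiment(
    seeds=range(8),
    n_half: int = 150,
    diameter: float = 0.4,
    confinement_radius: float = 7.5,
    damping_time: float = 0.5,
    n_steps: int = 70_000,
    record_every: int = 8,
    fit_low: float = 0.15,
    smooth: int = 5,
) -> FusionResult:
    """Neck-growth exponent of two fusing droplets (no chromatin).

    Two equilibrium-spaced droplets of ``n_half`` particles start in contact
    with Maxwell-Boltzmann velocities; dynamics are strongly overdamped
    (velocity relaxation far below the fusion timescale) so coalescence is
    controlled by friction against the implicit nucleoplasm, the regime
    where the neck is expected to grow as ~t^(1/2).  The normalized neck
    radius 2R(t)/R_0 (area estimator) is averaged over seeds, median
    smoothed, and fitted on log-log over the rise window
    fit_low < 2R/R_0 < 1 (up to the first crossing of 1).
    """
    spacing = 2 ** (1.0 / 6.0) * diameter
    profs: list[NeckProfile] = []
    for seed in seeds:
        a = condensed_positions(n_half, spacing)
        b = condensed_positions(n_half, spacing)
        r_d = np.linalg.norm(a, axis=1).max() + spacing / 2
        pos = np.concatenate(
            [a + [-(r_d + 0.075), 0.0, 0.0], b + [r_d + 0.075, 0.0, 0.0]]
        )
        topo = GenomeTopology.particles_only(
            2 * n_half,
            nucleolar_diameter=diameter,
            confinement_radius=confinement_radius,
        )
        rng = np.random.default_rng(seed)
        state = SimulationState(
            topo, pos, maxwell_boltzmann_velocities(2 * n_half, 1.0, rng), seed=seed
        )
        table = InteractionTable.for_topology(topo)
        r0 = droplet_radius_from_rg(droplet_rg(a))
        params = IntegratorParams(
            record_every=record_every, seed=seed, damping_time=damping_time
        )
        traj, _ = run(state, n_steps, params, table)
        cf = ClusterParams(eps=1.07 * spacing, min_samples=4, min_droplet_size=10)
        profs.append(
            neck_profile(
                traj.nucleolar_positions,
                traj.times_tau,
                r0=r0,
                cluster_filter=cf,
                estimator="area",
            )
        )
    times = profs[0].times
    stack = np.stack([p.normalized for p in profs])
    mean = np.nanmean(stack, axis=0)
    sm = ndi.median_filter(np.nan_to_num(mean, nan=2.0), size=smooth)
    above = np.flatnonzero(sm >= 1.0)
    end = above[0] + 1 if above.size else sm.size
    idx = np.flatnonzero((sm > fit_low) & (np.arange(sm.size) < end) & (times > 0))
    if idx.size < 8:
        return FusionResult(times, mean, None, int(idx.size), stack)
    slope = float(linregress(np.log(times[idx]), np.log(sm[idx])).slope)
    return FusionResult(times, mean, slope, int(idx.size), stack)
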