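"""Umbrella sampling along the two-droplet radius of gyration, with
temperature replica exchange.

The collective variable is the radius of gyration R_g of the nucleolar
particles belonging to either of the two droplets,

    R_g = sqrt( (1/N) * sum_i |r_i - r_com|^2 ),

which tracks the droplet separation while staying well defined under the
continuous flux of particles between the droplets: membership is identified
once (by density-based clustering) when a window is initialized and kept
fixed afterwards.  A harmonic restraint (K/2)*(R_g - R_c)^2 pins each window
at its center; replica exchange across a ladder of temperatures accelerates
barrier crossing, with neighbor-pair Metropolis swaps on the total potential
energy (bias included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import (
    HarmonicBias,
    IntegratorParams,
    maxwell_boltzmann_velocities,
    run,
    total_potential,
)

__all__ = [
    "droplet_rg",
    "droplet_rg_gradient",
    "UmbrellaWindow",
    "spring_schedule",
    "default_windows",
    "bias_energy",
    "bias_force",
    "ReplicaLadder",
    "swap_acceptance",
    "replica_exchange_sweep",
    "UmbrellaSamples",
    "run_umbrella",
]


def droplet_rg(positions: np.ndarray, members: np.ndarray | None = None) -> float:
    """Radius of gyration of ``members`` (all rows if None): the RMS distance
    to the member centroid.  Translation and rotation invariant."""
    pts = np.asarray(positions, dtype=float)
    if members is not None:
        members = np.asarray(members, dtype=np.int64)
        if members.size == 0:
            raise ValueError("membership must be non-empty")
        pts = pts[members]
    if pts.shape[0] == 0:
        raise ValueError("membership must be non-empty")
    com = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - com) ** 2, axis=1))))


def droplet_rg_gradient(positions: np.ndarray, members: np.ndarray) -> np.ndarray:
    """d(R_g)/d(r_i) for each member: (r_i - r_com) / (N * R_g)."""
    members = np.asarray(members, dtype=np.int64)
    pts = np.asarray(positions, dtype=float)[members]
    com = pts.mean(axis=0)
    rg = droplet_rg(positions, members)
    if rg < 1e-12:
        return np.zeros_like(pts)
    return (pts - com) / (members.size * rg)


def spring_schedule(center: float) -> float:
    """Umbrella spring constant (k_B*T/sigma^2) as a staircase in the window
    center: 100 below 3.5 sigma, 150 in [3.5, 4.0), 200 at and above 4.0."""
    if center < 3.5:
        return 100.0
    if center < 4.0:
        return 150.0
    return 200.0


@dataclass(frozen=True)
class UmbrellaWindow:
    """One umbrella window: restraint center R_c (sigma) and spring K."""

    center: float
    spring: float | None = None

    def __post_init__(self) -> None:
        if self.spring is None:
            object.__setattr__(self, "spring", spring_schedule(self.center))
        if not (self.center > 0 and self.spring >= 0):
            raise ValueError("window center must be positive and spring >= 0")

    def bias(self, members: np.ndarray) -> HarmonicBias:
        return HarmonicBias(members=members, spring=self.spring, center=self.center)


def default_windows() -> list[UmbrellaWindow]:
    """The 16-window layout: centers evenly spaced from 2.5 to 6.0 sigma in
    0.25 sigma increments, plus a first window at 2.0 sigma."""
    centers = [2.0] + [2.5 + 0.25 * k for k in range(15)]
    return [UmbrellaWindow(center=c) for c in centers]


def bias_energy(rg: float, window: UmbrellaWindow) -> float:
    """(K/2)*(R_g - R_c)^2 in k_B*T."""
    return 0.5 * window.spring * (rg - window.center) ** 2


def bias_force(
    positions: np.ndarray, members: np.ndarray, window: UmbrellaWindow
) -> np.ndarray:
    """Bias force on each member via the chain rule through R_g."""
    rg = droplet_rg(positions, members)
    return -window.spring * (rg - window.center) * droplet_rg_gradient(positions, members)


@dataclass(frozen=True)
class ReplicaLadder:
    """Strictly increasing reduced temperatures; swaps attempted every
    ``swap_interval`` steps.  Default: 8 rungs, 1.00 to 1.14 step 0.02."""

    temperatures: tuple[float, ...] = tuple(round(1.0 + 0.02 * k, 2) for k in range(8))
    swap_interval: int = 100

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures)
        if t.size == 0 or not (np.diff(t) > 0).all() or not (t > 0).all():
            raise ValueError("temperatures must be positive and strictly increasing")
        if self.swap_interval < 1:
            raise ValueError("swap_interval must be >= 1")

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)


def swap_acceptance(u_i: float, u_j: float, t_i: float, t_j: float) -> float:
    """Metropolis acceptance for exchanging configurations between two
    temperatures: min{1, exp[(1/T_i - 1/T_j) * (U_i - U_j)]} (k_B = 1)."""
    return min(1.0, math.exp(min(700.0, (1.0 / t_i - 1.0 / t_j) * (u_i - u_j))))


def replica_exchange_sweep(
    energies: np.ndarray,
    ladder: ReplicaLadder,
    rng: np.random.Generator,
    parity: int = 0,
) -> list[tuple[int, int, bool]]:
    """One sweep of neighbor-pair swap attempts over rungs of the given
    ``parity`` (0: pairs (0,1),(2,3),...; 1: pairs (1,2),(3,4),...).

    ``energies[k]`` is the total potential (bias included) of the
    configuration currently at rung k.  Returns (i, j, accepted) per attempt;
    the caller exchanges the configurations of accepted pairs, keeping the
    temperature ladder fixed.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.size != ladder.n_replicas:
        raise ValueError("one energy per ladder rung is required")
    attempts = []
    for i in range(parity % 2, ladder.n_replicas - 1, 2):
        j = i + 1
        p = swap_acceptance(
            energies[i], energies[j], ladder.temperatures[i], ladder.temperatures[j]
        )
        attempts.append((i, j, bool(rng.random() < p)))
    return attempts


@dataclass
class UmbrellaSamples:
    """CV time series per (window, temperature rung).

    ``cv[w][k]`` is the array of R_g samples recorded at rung k of window w;
    ``record_every`` gives their spacing in steps.  ``flagged[w]`` lists
    sample indices where the restrained droplet pair was no longer resolvable
    as two clusters (droplet evaporation), recorded for downstream filtering.
    """

    windows: list[UmbrellaWindow]
    ladder: ReplicaLadder
    record_every: int
    cv: list[list[np.ndarray]]
    potential: list[list[np.ndarray]] = field(default_factory=list)
    flagged: dict[int, list[int]] = field(default_factory=dict)
    swap_accept_rate: float = float("nan")

    def window_samples(self, w: int, rung: int = 0) -> np.ndarray:
        return self.cv[w][rung]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("window\tcenter\tspring\ttemp_index\ttemperature\tsample\trg\n")
            for w, win in enumerate(self.windows):
                for k, temp in enumerate(self.ladder.temperatures):
                    for s, rg in enumerate(self.cv[w][k]):
                        fh.write(
                            f"{w}\t{win.center:g}\t{win.spring:g}\t{k}\t{temp:g}"
                            f"\t{s}\t{rg:.6f}\n"
                        )


def run_umbrella(
    state,
    windows: list[UmbrellaWindow] | None = None,
    ladder: ReplicaLadder | None = None,
    n_steps: int = 100_000,
    params: IntegratorParams | None = None,
    table=None,
    members: np.ndarray | None = None,
    record_every: int = 400,
    seed: int = 0,
    cluster_kwargs: dict | None = None,
    check_evaporation: bool = False,
) -> UmbrellaSamples:
    """Umbrella sampling with temperature replica exchange.

    The droplet membership is identified once from the initial state (the
    union of the two largest density clusters of nucleolar particles, via
    :func:`nucleodrop.clusters.droplet_members`) unless ``members`` is given,
    and stays fixed for every window and replica.  Each window runs
    ``ladder.n_replicas`` replicas; every ``ladder.swap_interval`` steps a
    sweep of neighbor swaps (alternating parity) exchanges configurations.
    R_g is recorded every ``record_every`` steps at every rung.
    """
    from .clusters import dbscan_labels, droplet_members

    if windows is None:
        windows = default_windows()
    if ladder is None:
        ladder = ReplicaLadder()
    if params is None:
        params = IntegratorParams(record_every=max(n_steps, 1))
    if table is None:
        from .interactions import InteractionTable

        table = InteractionTable.for_topology(state.topology)
    if members is None:
        ckw = dict(cluster_kwargs or {})
        ckw.setdefault("n_droplets", 2)
        members = droplet_members(state.nucleolar_positions, **ckw)
        members = state.topology.nucleolar_indices[members]
    members = np.asarray(members, dtype=np.int64)

    rng = np.random.default_rng(seed)
    n_chunks = n_steps // ladder.swap_interval
    rec_per_chunk = ladder.swap_interval / record_every
    cv_all: list[list[np.ndarray]] = []
    pe_all: list[list[np.ndarray]] = []
    flagged: dict[int, list[int]] = {}
    n_attempt = 0
    n_accept = 0
    eps = None
    if check_evaporation and cluster_kwargs:
        eps = cluster_kwargs.get("eps")

    for w, window in enumerate(windows):
        bias = window.bias(members)
        replicas = []
        for k, temp in enumerate(ladder.temperatures):
            rep = state.copy()
            rep.velocities = maxwell_boltzmann_velocities(
                rep.topology.n_particles, temp, rng
            )
            replicas.append(rep)
        cv_series: list[list[float]] = [[] for _ in ladder.temperatures]
        pe_series: list[list[float]] = [[] for _ in ladder.temperatures]
        step_count = 0
        for chunk in range(n_chunks):
            energies = np.empty(ladder.n_replicas)
            for k, temp in enumerate(ladder.temperatures):
                rp = IntegratorParams(
                    dt=params.dt,
                    damping_time=params.damping_time,
                    temperature=temp,
                    seed=int(rng.integers(2**31)),
                    record_every=max(ladder.swap_interval, 1),
                )
                _, replicas[k] = run(
                    replicas[k], ladder.swap_interval, rp, table, bias=bias
                )
                energies[k] = total_potential(replicas[k], table, bias=bias)
            step_count += ladder.swap_interval
            for i, j, accepted in replica_exchange_sweep(energies, ladder, rng, chunk % 2):
                n_attempt += 1
                if accepted:
                    n_accept += 1
                    replicas[i], replicas[j] = replicas[j], replicas[i]
                    # rescale velocities to the destination temperature
                    ti, tj = ladder.temperatures[i], ladder.temperatures[j]
                    replicas[i].velocities *= math.sqrt(ti / tj)
                    replicas[j].velocities *= math.sqrt(tj / ti)
                    energies[i], energies[j] = energies[j], energies[i]
            if step_count % record_every < ladder.swap_interval:
                for k in range(ladder.n_replicas):
                    cv_series[k].append(droplet_rg(replicas[k].positions, members))
                    pe_series[k].append(energies[k])
                if check_evaporation:
                    pos = replicas[0].positions[members]
                    kwargs = dict(cluster_kwargs or {})
                    labels = dbscan_labels(
                        pos,
                        eps=kwargs.get("eps", 0.6),
                        min_samples=kwargs.get("min_samples", 4),
                    )
                    n_cl = len(set(labels[labels >= 0]))
                    if n_cl < 2:
                        flagged.setdefault(w, []).append(len(cv_series[0]) - 1)
        cv_all.append([np.asarray(s) for s in cv_series])
        pe_all.append([np.asarray(s) for s in pe_series])

    return UmbrellaSamples(
        windows=list(windows),
        ladder=ladder,
        record_every=record_every,
        cv=cv_all,
        potential=pe_all,
        flagged=flagged,
        swap_accept_rate=(n_accept / n_attempt) if n_attempt else float("nan"),
    )
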