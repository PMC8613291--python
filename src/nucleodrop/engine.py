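"""Langevin dynamics engine in reduced units.

Integrates the nucleus model with the BAOAB splitting of Langevin dynamics:
all masses are 1, the friction is m/damping_time, and the stochastic kick
amplitude satisfies fluctuation-dissipation at the target temperature.  In
the limit of no friction and no noise the scheme reduces exactly to velocity
Verlet, which is used for energy-conservation checks.

Forces are the sum of

* cut-and-shifted LJ pair interactions (7x7 class matrices from
  :class:`~nucleodrop.interactions.InteractionTable`), evaluated over all
  pairs with directly bonded pairs excluded,
* harmonic bonds between consecutive chromatin beads,
* a purely repulsive shifted-LJ wall acting on the distance to the
  confinement sphere surface,
* optionally a harmonic umbrella bias on the radius of gyration of a fixed
  set of member particles (the chain-rule gradient of R_g distributes the
  bias force over all members).

Same seed implies a bitwise-identical trajectory.  A displacement larger
than 0.5 sigma in a single step, or a non-finite energy, aborts the run with
:class:`SimulationInstabilityError` naming the step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .genome import SimulationState
from .interactions import InteractionTable

__all__ = [
    "IntegratorParams",
    "HarmonicBias",
    "Trajectory",
    "SimulationInstabilityError",
    "run",
    "langevin_step",
    "total_forces",
    "total_potential",
    "maxwell_boltzmann_velocities",
    "kinetic_temperature",
]


class SimulationInstabilityError(RuntimeError):
    def __init__(self, step: int, reason: str = "displacement exceeded 0.5 sigma"):
        super().__init__(f"integration unstable at step {step}: {reason}")
        self.step = step


@dataclass(frozen=True)
class IntegratorParams:
    """Langevin integrator settings (reduced units).

    ``damping_time`` is the velocity relaxation time gamma in tau_B; the
    friction coefficient is m/gamma.  Defaults: dt = 0.008 tau_B,
    gamma = 10 tau_B, T = 1, frames recorded every 2000 steps.
    """

    dt: float = 0.008
    damping_time: float = 10.0
    temperature: float = 1.0
    seed: int = 0
    record_every: int = 2000

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.damping_time > 0:
            raise ValueError("damping_time must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    @property
    def friction_decay(self) -> float:
        """exp(-dt/damping_time); 1.0 for infinite damping time (NVE limit)."""
        if math.isinf(self.damping_time):
            return 1.0
        return math.exp(-self.dt / self.damping_time)

    @property
    def noise_amplitude(self) -> float:
        c1 = self.friction_decay
        return math.sqrt(max(0.0, (1.0 - c1 * c1) * self.temperature))


@dataclass(frozen=True)
class HarmonicBias:
    """Umbrella restraint (spring/2)*(R_g - center)^2 on fixed member indices."""

    members: np.ndarray
    spring: float
    center: float

    def __post_init__(self) -> None:
        members = np.ascontiguousarray(np.asarray(self.members, dtype=np.int64))
        if members.size == 0:
            raise ValueError("bias membership must be non-empty")
        object.__setattr__(self, "members", members)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

_WALL_RC_FACTOR = 2.0 ** (1.0 / 6.0)


@njit(cache=True)
def _build_pairs(pos, codes, rc_max, bonded_next, skin, pair_i, pair_j):
    """Verlet list: all pairs within rc_max + skin, bonded pairs excluded.

    Returns the pair count, or -1 if the preallocated arrays are too small.
    """
    n = pos.shape[0]
    cutoff2 = (rc_max + skin) ** 2
    cnt = 0
    cap = pair_i.shape[0]
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            if j == i + 1 and bonded_next[i]:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cutoff2:
                if cnt >= cap:
                    return -1
                pair_i[cnt] = i
                pair_j[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True)
def _forces_kernel(
    pos,
    codes,
    eps,
    sig,
    rc,
    ecut,
    pair_i,
    pair_j,
    n_pairs,
    bonded_next,
    bond_k,
    bond_r0,
    rn,
    wall_sig,
    wall_eps,
    bias_members,
    bias_k,
    bias_c,
    f,
):
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    pe = 0.0
    # non-bonded pairs from the Verlet list (1-2 bonded pairs excluded)
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        ci = codes[i]
        cj = codes[j]
        rcut = rc[ci, cj]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rcut * rcut:
            continue
        s = sig[ci, cj]
        e = eps[ci, cj]
        sr2 = s * s / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        pe += 4.0 * e * (sr12 - sr6) + ecut[ci, cj]
        fmag = 24.0 * e * (2.0 * sr12 - sr6) / r2
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz
    # harmonic bonds between consecutive beads
    for i in range(n - 1):
        if not bonded_next[i]:
            continue
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0
        pe += 0.5 * bond_k * dr * dr
        if r > 1e-12:
            fmag = -bond_k * dr / r
            f[i, 0] += fmag * dx
            f[i, 1] += fmag * dy
            f[i, 2] += fmag * dz
            f[i + 1, 0] -= fmag * dx
            f[i + 1, 1] -= fmag * dy
            f[i + 1, 2] -= fmag * dz
    # confinement wall: repulsive WCA on the gap d = R_N - |r|
    wall_rc = _WALL_RC_FACTOR * wall_sig
    for i in range(n):
        rr = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        d = rn - rr
        if d < wall_rc:
            if d < 1e-6:
                d = 1e-6
            sr2 = (wall_sig / d) ** 2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            pe += 4.0 * wall_eps * (sr12 - sr6) + wall_eps
            fmag = 24.0 * wall_eps * (2.0 * sr12 - sr6) / d
            if rr > 1e-12:
                inv = 1.0 / rr
                f[i, 0] -= fmag * pos[i, 0] * inv
                f[i, 1] -= fmag * pos[i, 1] * inv
                f[i, 2] -= fmag * pos[i, 2] * inv
    # harmonic bias on the member radius of gyration
    if bias_k > 0.0 and bias_members.shape[0] > 0:
        m = bias_members.shape[0]
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for k in range(m):
            idx = bias_members[k]
            cx += pos[idx, 0]
            cy += pos[idx, 1]
            cz += pos[idx, 2]
        cx /= m
        cy /= m
        cz /= m
        s2 = 0.0
        for k in range(m):
            idx = bias_members[k]
            s2 += (
                (pos[idx, 0] - cx) ** 2
                + (pos[idx, 1] - cy) ** 2
                + (pos[idx, 2] - cz) ** 2
            )
        rg = math.sqrt(s2 / m)
        pe += 0.5 * bias_k * (rg - bias_c) ** 2
        if rg > 1e-12:
            pref = -bias_k * (rg - bias_c) / (m * rg)
            for k in range(m):
                idx = bias_members[k]
                f[idx, 0] += pref * (pos[idx, 0] - cx)
                f[idx, 1] += pref * (pos[idx, 1] - cy)
                f[idx, 2] += pref * (pos[idx, 2] - cz)
    return pe


@njit(cache=True)
def _members_rg(pos, members):
    m = members.shape[0]
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for k in range(m):
        idx = members[k]
        cx += pos[idx, 0]
        cy += pos[idx, 1]
        cz += pos[idx, 2]
    cx /= m
    cy /= m
    cz /= m
    s2 = 0.0
    for k in range(m):
        idx = members[k]
        s2 += (
            (pos[idx, 0] - cx) ** 2 + (pos[idx, 1] - cy) ** 2 + (pos[idx, 2] - cz) ** 2
        )
    return math.sqrt(s2 / m)


@njit(cache=True)
def _integrate_kernel(
    pos,
    vel,
    codes,
    eps,
    sig,
    rc,
    ecut,
    bonded_next,
    bond_k,
    bond_r0,
    rn,
    wall_sig,
    wall_eps,
    frozen,
    bias_members,
    bias_k,
    bias_c,
    n_steps,
    dt,
    c1,
    amp,
    seed,
    record_every,
    frames,
    pe_frames,
    cv_every,
    cv_out,
    limit,
    skin,
    pair_i,
    pair_j,
):
    np.random.seed(seed)
    n = pos.shape[0]
    rc_max = 0.0
    for a in range(rc.shape[0]):
        for b in range(rc.shape[1]):
            if rc[a, b] > rc_max:
                rc_max = rc[a, b]
    n_pairs = _build_pairs(pos, codes, rc_max, bonded_next, skin, pair_i, pair_j)
    if n_pairs < 0:
        return -2
    acc = np.zeros(n)
    f = np.zeros((n, 3))
    pe = _forces_kernel(
        pos, codes, eps, sig, rc, ecut, pair_i, pair_j, n_pairs, bonded_next,
        bond_k, bond_r0, rn, wall_sig, wall_eps, bias_members, bias_k, bias_c, f,
    )
    half = 0.5 * dt
    frame_i = 0
    cv_i = 0
    for step in range(1, n_steps + 1):
        max_disp2 = 0.0
        max_acc = 0.0
        for i in range(n):
            if frozen[i]:
                continue
            dx = 0.0
            dy = 0.0
            dz = 0.0
            # B: half kick
            vel[i, 0] += half * f[i, 0]
            vel[i, 1] += half * f[i, 1]
            vel[i, 2] += half * f[i, 2]
            # A: half drift
            dx += half * vel[i, 0]
            dy += half * vel[i, 1]
            dz += half * vel[i, 2]
            # O: Ornstein-Uhlenbeck
            vel[i, 0] = c1 * vel[i, 0] + amp * np.random.standard_normal()
            vel[i, 1] = c1 * vel[i, 1] + amp * np.random.standard_normal()
            vel[i, 2] = c1 * vel[i, 2] + amp * np.random.standard_normal()
            # A: half drift
            dx += half * vel[i, 0]
            dy += half * vel[i, 1]
            dz += half * vel[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if limit > 0.0 and d2 > limit * limit:
                # push-off mode: clamp the step and kill the velocity so the
                # overlap anneals instead of detonating
                scale = limit / math.sqrt(d2)
                dx *= scale
                dy *= scale
                dz *= scale
                vel[i, 0] = 0.0
                vel[i, 1] = 0.0
                vel[i, 2] = 0.0
                d2 = limit * limit
            pos[i, 0] += dx
            pos[i, 1] += dy
            pos[i, 2] += dz
            if d2 > max_disp2:
                max_disp2 = d2
            acc[i] += math.sqrt(d2)
            if acc[i] > max_acc:
                max_acc = acc[i]
        if limit <= 0.0 and (max_disp2 > 0.25 or not math.isfinite(max_disp2)):
            return step
        if 2.0 * max_acc > skin:
            n_pairs = _build_pairs(pos, codes, rc_max, bonded_next, skin, pair_i, pair_j)
            if n_pairs < 0:
                return -2
            for i in range(n):
                acc[i] = 0.0
        pe = _forces_kernel(
            pos, codes, eps, sig, rc, ecut, pair_i, pair_j, n_pairs, bonded_next,
            bond_k, bond_r0, rn, wall_sig, wall_eps, bias_members, bias_k, bias_c, f,
        )
        if not math.isfinite(pe):
            return step
        for i in range(n):
            if frozen[i]:
                continue
            # B: half kick
            vel[i, 0] += half * f[i, 0]
            vel[i, 1] += half * f[i, 1]
            vel[i, 2] += half * f[i, 2]
        if record_every > 0 and step % record_every == 0 and frame_i < frames.shape[0]:
            for i in range(n):
                frames[frame_i, i, 0] = pos[i, 0]
                frames[frame_i, i, 1] = pos[i, 1]
                frames[frame_i, i, 2] = pos[i, 2]
            pe_frames[frame_i] = pe
            frame_i += 1
        if cv_every > 0 and step % cv_every == 0 and cv_i < cv_out.shape[0]:
            cv_out[cv_i] = _members_rg(pos, bias_members)
            cv_i += 1
    return 0


# ---------------------------------------------------------------------------
# python API
# ---------------------------------------------------------------------------

_EMPTY_MEMBERS = np.empty(0, dtype=np.int64)


def _system_arrays(state: SimulationState, table: InteractionTable):
    topo = state.topology
    codes = topo.codes()
    bonded_next = np.zeros(topo.n_particles, dtype=np.bool_)
    if topo.bonds.size:
        # bonds connect consecutive indices by construction
        bonded_next[topo.bonds[:, 0]] = True
    eps, sig, rc, ecut = table.matrices()
    return codes, bonded_next, eps, sig, rc, ecut


def _bias_args(bias: HarmonicBias | None):
    if bias is None:
        return _EMPTY_MEMBERS, 0.0, 0.0
    return bias.members, float(bias.spring), float(bias.center)


def _all_pairs(state: SimulationState, table: InteractionTable, codes, bonded_next):
    n = state.topology.n_particles
    cap = max(1024, n * (n - 1) // 2)
    pair_i = np.empty(cap, dtype=np.int64)
    pair_j = np.empty(cap, dtype=np.int64)
    n_pairs = _build_pairs(
        state.positions, codes, table.max_cutoff, bonded_next, 0.0, pair_i, pair_j
    )
    return pair_i, pair_j, n_pairs


def _evaluate(state, table, bias):
    codes, bonded_next, eps, sig, rc, ecut = _system_arrays(state, table)
    members, bk, bc = _bias_args(bias)
    pair_i, pair_j, n_pairs = _all_pairs(state, table, codes, bonded_next)
    f = np.zeros_like(state.positions)
    pe = _forces_kernel(
        state.positions, codes, eps, sig, rc, ecut, pair_i, pair_j, n_pairs,
        bonded_next, table.bond_k, table.bond_length,
        state.topology.confinement_radius, table.wall_sigma, table.wall_epsilon,
        members, bk, bc, f,
    )
    return f, float(pe)


def total_forces(
    state: SimulationState, table: InteractionTable, bias: HarmonicBias | None = None
) -> np.ndarray:
    """Forces (negative energy gradient) on every particle, k_B*T/sigma."""
    f, _ = _evaluate(state, table, bias)
    if not np.isfinite(f).all():
        raise SimulationInstabilityError(state.step, "non-finite forces")
    return f


def total_potential(
    state: SimulationState, table: InteractionTable, bias: HarmonicBias | None = None
) -> float:
    """Total potential energy in k_B*T (including any bias)."""
    _, pe = _evaluate(state, table, bias)
    return pe


def maxwell_boltzmann_velocities(
    n: int, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Velocities drawn from the Maxwell-Boltzmann distribution (m = 1)."""
    return rng.normal(0.0, math.sqrt(temperature), size=(n, 3))


def kinetic_temperature(velocities: np.ndarray) -> float:
    """Instantaneous kinetic temperature <v^2>/3 per particle (m = 1)."""
    return float(np.mean(np.sum(velocities**2, axis=1)) / 3.0)


@dataclass
class Trajectory:
    """Recorded frames of a run: positions (n_frames, n_particles, 3) in sigma.

    Frames are uniformly spaced by ``record_every`` steps of size ``dt``; the
    physical frame interval is record_every*dt*time_unit via a UnitSystem.
    """

    positions: np.ndarray
    dt: float
    record_every: int
    is_nucleolar: np.ndarray
    start_step: int = 0
    seed: int | None = None
    potential: np.ndarray | None = None
    topology: object | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def times_tau(self) -> np.ndarray:
        """Time of each frame in tau_B, measured from step 0 of this run."""
        return (
            self.start_step + (np.arange(self.n_frames) + 1) * self.record_every
        ) * self.dt

    def times_seconds(self, units) -> np.ndarray:
        return self.times_tau * units.time_unit

    @property
    def nucleolar_positions(self) -> np.ndarray:
        return self.positions[:, self.is_nucleolar, :]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            positions=self.positions,
            dt=self.dt,
            record_every=self.record_every,
            is_nucleolar=self.is_nucleolar,
            start_step=self.start_step,
            seed=-1 if self.seed is None else self.seed,
            potential=np.empty(0) if self.potential is None else self.potential,
        )

    @classmethod
    def load(cls, path: str | Path) -> "Trajectory":
        data = np.load(path)
        seed = int(data["seed"])
        pot = data["potential"]
        return cls(
            positions=data["positions"],
            dt=float(data["dt"]),
            record_every=int(data["record_every"]),
            is_nucleolar=data["is_nucleolar"],
            start_step=int(data["start_step"]),
            seed=None if seed < 0 else seed,
            potential=None if pot.size == 0 else pot,
        )

    def write_xyz(self, path: str | Path) -> None:
        """Extended-XYZ text output; species P (nucleolar) / C (chromatin)."""
        n = self.positions.shape[1]
        species = np.where(self.is_nucleolar, "P", "C")
        with open(path, "w") as fh:
            for fi in range(self.n_frames):
                fh.write(f"{n}\n")
                fh.write(
                    f'Lattice="1 0 0 0 1 0 0 0 1" Properties=species:S:1:pos:R:3 '
                    f"Time={self.times_tau[fi]:.6f}\n"
                )
                for i in range(n):
                    x, y, z = self.positions[fi, i]
                    fh.write(f"{species[i]} {x:.6f} {y:.6f} {z:.6f}\n")


def _chunk_seed(seed: int, start_step: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, start_step]).generate_state(1)[0] % (2**31))


def run(
    state: SimulationState,
    n_steps: int,
    params: IntegratorParams | None = None,
    table: InteractionTable | None = None,
    bias: HarmonicBias | None = None,
    frozen: np.ndarray | None = None,
    cv_every: int = 0,
    max_displacement: float = 0.0,
    skin: float = 0.3,
) -> tuple[Trajectory, SimulationState]:
    """Integrate ``n_steps`` of Langevin dynamics.

    Returns the recorded :class:`Trajectory` (floor(n_steps/record_every)
    frames) and the final state.  The input state is not modified.  ``frozen``
    marks particles held fixed; ``cv_every`` additionally records the bias
    R_g every that many steps (requires ``bias``).  A positive
    ``max_displacement`` switches to push-off mode: per-step moves are clamped
    to that length instead of aborting, used to anneal steric clashes in
    freshly built configurations.
    """
    if params is None:
        params = IntegratorParams()
    if table is None:
        table = InteractionTable.for_topology(state.topology)
    work = state.copy()
    codes, bonded_next, eps, sig, rc, ecut = _system_arrays(work, table)
    members, bk, bc = _bias_args(bias)
    if cv_every > 0 and bias is None:
        raise ValueError("cv_every requires a bias defining the membership")
    if frozen is None:
        frozen = np.zeros(work.topology.n_particles, dtype=np.bool_)
    else:
        frozen = np.asarray(frozen, dtype=np.bool_)

    n_frames = n_steps // params.record_every
    frames = np.empty((n_frames, work.topology.n_particles, 3))
    pe_frames = np.empty(n_frames)
    n_cv = n_steps // cv_every if cv_every > 0 else 0
    cv_out = np.empty(n_cv)
    n = work.topology.n_particles
    cap = min(max(4096, 160 * n), n * (n - 1) // 2 + 1)
    pair_i = np.empty(cap, dtype=np.int64)
    pair_j = np.empty(cap, dtype=np.int64)

    status = _integrate_kernel(
        work.positions,
        work.velocities,
        codes,
        eps,
        sig,
        rc,
        ecut,
        bonded_next,
        table.bond_k,
        table.bond_length,
        work.topology.confinement_radius,
        table.wall_sigma,
        table.wall_epsilon,
        frozen,
        members,
        bk,
        bc,
        n_steps,
        params.dt,
        params.friction_decay,
        params.noise_amplitude,
        _chunk_seed(params.seed, state.step),
        params.record_every,
        frames,
        pe_frames,
        cv_every,
        cv_out,
        max_displacement,
        skin,
        pair_i,
        pair_j,
    )
    if status == -2:
        raise SimulationInstabilityError(
            state.step, "neighbour-list capacity exceeded; increase pair capacity"
        )
    if status != 0:
        raise SimulationInstabilityError(state.step + status)
    work.step = state.step + n_steps
    work.seed = params.seed
    traj = Trajectory(
        positions=frames,
        dt=params.dt,
        record_every=params.record_every,
        is_nucleolar=work.topology.is_nucleolar,
        start_step=state.step,
        seed=params.seed,
        potential=pe_frames,
        topology=work.topology,
    )
    if cv_every > 0:
        traj.cv_series = cv_out  # type: ignore[attr-defined]
    return traj, work


def langevin_step(
    state: SimulationState,
    params: IntegratorParams | None = None,
    table: InteractionTable | None = None,
    bias: HarmonicBias | None = None,
) -> SimulationState:
    """Advance the state by a single Langevin step (deterministic under seed)."""
    if params is None:
        params = IntegratorParams()
    _, new_state = run(state, 1, params, table, bias=bias)
    return new_state
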