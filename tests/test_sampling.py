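"""Collective variable, umbrella windows and replica exchange."""

import math

import numpy as np
import pytest

from nucleodrop.engine import HarmonicBias, IntegratorParams, run
from nucleodrop.genome import GenomeTopology, SimulationState
from nucleodrop.interactions import InteractionTable, PairPotential
from nucleodrop.sampling import (
    ReplicaLadder,
    UmbrellaWindow,
    bias_energy,
    bias_force,
    default_windows,
    droplet_rg,
    droplet_rg_gradient,
    replica_exchange_sweep,
    run_umbrella,
    spring_schedule,
    swap_acceptance,
)


def rotation_matrix(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestDropletRg:
    def test_coincident_points(self):
        pts = np.ones((5, 3))
        assert droplet_rg(pts) == 0.0

    def test_two_points(self):
        pts = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert droplet_rg(pts) == pytest.approx(1.5)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3))
        com = pts.mean(axis=0)
        direct = math.sqrt(np.sum((pts - com) ** 2) / 50)
        assert droplet_rg(pts) == pytest.approx(direct, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 3))
        base = droplet_rg(pts)
        moved = pts @ rotation_matrix(rng).T + np.array([5.0, -2.0, 1.0])
        assert droplet_rg(moved) == pytest.approx(base, rel=1e-12)

    def test_member_selection(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(20, 3))
        members = np.array([1, 4, 7, 13])
        assert droplet_rg(pts, members) == pytest.approx(droplet_rg(pts[members]))

    def test_empty_membership_rejected(self):
        with pytest.raises(ValueError):
            droplet_rg(np.zeros((4, 3)), np.array([], dtype=int))

    def test_robust_to_particle_flux(self):
        """Moving one particle from one droplet to the other changes R_g by
        under 2% (the reason this CV tolerates membership flux)."""
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.4, (30, 3)) + [-2.0, 0, 0]
        b = rng.normal(0, 0.4, (30, 3)) + [+2.0, 0, 0]
        pts = np.concatenate([a, b])
        before = droplet_rg(pts)
        moved = pts.copy()
        moved[0] = [+2.0, 0.1, 0.0]  # particle hops across
        after = droplet_rg(moved)
        assert abs(after - before) / before < 0.02


class TestWindows:
    def test_sixteen_default_windows(self):
        wins = default_windows()
        assert len(wins) == 16
        centers = [w.center for w in wins]
        assert centers[0] == 2.0
        assert centers[1] == 2.5
        assert centers[-1] == 6.0
        assert np.allclose(np.diff(centers[1:]), 0.25)

    @pytest.mark.parametrize(
        "center,spring",
        [(2.0, 100.0), (3.25, 100.0), (3.5, 150.0), (3.75, 150.0), (4.0, 200.0), (6.0, 200.0)],
    )
    def test_spring_staircase(self, center, spring):
        assert spring_schedule(center) == spring
        assert UmbrellaWindow(center=center).spring == spring

    def test_bias_energy_closed_form(self):
        w = UmbrellaWindow(center=3.0, spring=100.0)
        assert bias_energy(3.0, w) == 0.0
        assert bias_energy(3.1, w) == pytest.approx(0.5)

    def test_bias_force_matches_finite_difference(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 3))
        members = np.arange(8)
        w = UmbrellaWindow(center=1.2, spring=80.0)
        f = bias_force(pts, members, w)
        h = 1e-7
        for i in (0, 3, 7):
            for k in range(3):
                pp = pts.copy()
                pp[i, k] += h
                pm = pts.copy()
                pm[i, k] -= h
                grad = (
                    bias_energy(droplet_rg(pp, members), w)
                    - bias_energy(droplet_rg(pm, members), w)
                ) / (2 * h)
                assert -grad == pytest.approx(f[i - 0, k], rel=1e-5, abs=1e-8)

    def test_gradient_shape_and_sum(self):
        # R_g gradient sums to zero over members (translation invariance)
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        g = droplet_rg_gradient(pts, np.arange(10))
        np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-12)


class TestReplicaExchange:
    def test_default_ladder(self):
        ladder = ReplicaLadder()
        assert ladder.n_replicas == 8
        assert ladder.temperatures[0] == 1.00
        assert ladder.temperatures[-1] == 1.14
        assert np.allclose(np.diff(ladder.temperatures), 0.02)
        assert ladder.swap_interval == 100

    def test_equal_energy_always_swaps(self):
        assert swap_acceptance(5.0, 5.0, 1.0, 1.1) == 1.0

    def test_sweep_parity(self):
        ladder = ReplicaLadder(temperatures=(1.0, 1.1, 1.2, 1.3))
        rng = np.random.default_rng(0)
        even = replica_exchange_sweep(np.zeros(4), ladder, rng, parity=0)
        odd = replica_exchange_sweep(np.zeros(4), ladder, rng, parity=1)
        assert [(i, j) for i, j, _ in even] == [(0, 1), (2, 3)]
        assert [(i, j) for i, j, _ in odd] == [(1, 2)]

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            replica_exchange_sweep(np.zeros(3), ReplicaLadder(), np.random.default_rng(0))

    def test_detailed_balance_two_state_toy(self):
        """Exhaustive stationarity check of the swap move on a 2-configuration,
        2-temperature chain."""
        energies = {"a": 0.0, "b": 1.7}
        t1, t2 = 1.0, 1.4
        states = [("a", "b"), ("b", "a")]  # (config at T1, config at T2)

        def pi(s):
            return math.exp(-energies[s[0]] / t1 - energies[s[1]] / t2)

        for s in states:
            swapped = (s[1], s[0])
            p_fwd = swap_acceptance(energies[s[0]], energies[s[1]], t1, t2)
            p_bwd = swap_acceptance(energies[swapped[0]], energies[swapped[1]], t1, t2)
            assert pi(s) * p_fwd == pytest.approx(pi(swapped) * p_bwd, rel=1e-12)

    def test_harmonic_chain_marginals(self):
        """Metropolis sampling plus swap moves keeps the correct Boltzmann
        marginal at every rung of a two-temperature harmonic oscillator."""
        rng = np.random.default_rng(8)
        ladder = ReplicaLadder(temperatures=(1.0, 2.0), swap_interval=5)
        k_spring = 1.0
        x = np.array([0.0, 0.0])
        samples = [[], []]
        for sweep in range(40_000):
            # local Metropolis move at each rung
            for r, temp in enumerate(ladder.temperatures):
                prop = x[r] + rng.normal(0, 0.8)
                du = 0.5 * k_spring * (prop**2 - x[r] ** 2)
                if rng.random() < math.exp(-du / temp):
                    x[r] = prop
            if sweep % ladder.swap_interval == 0:
                energies = 0.5 * k_spring * x**2
                for i, j, acc in replica_exchange_sweep(energies, ladder, rng, sweep % 2):
                    if acc:
                        x[i], x[j] = x[j], x[i]
            if sweep > 2000:
                samples[0].append(x[0])
                samples[1].append(x[1])
        for r, temp in enumerate(ladder.temperatures):
            var = np.var(samples[r])
            se = temp / k_spring * math.sqrt(2.0 / (len(samples[r]) / 10))
            assert abs(var - temp / k_spring) < 3 * se


@pytest.fixture(scope="module")
def free_octet():
    """Eight non-interacting particles in a wide confinement."""
    topo = GenomeTopology.particles_only(
        8, nucleolar_diameter=0.01, confinement_radius=40.0
    )
    rng = np.random.default_rng(0)
    pos = rng.normal(0, 0.8, (8, 3))
    state = SimulationState(topo, pos, np.zeros_like(pos))
    table = InteractionTable.for_topology(topo)
    return state, table


class TestRunUmbrella:
    def test_zero_steps_gives_empty_series(self, free_octet):
        state, table = free_octet
        out = run_umbrella(
            state,
            windows=[UmbrellaWindow(center=1.5, spring=100.0)],
            ladder=ReplicaLadder(temperatures=(1.0,), swap_interval=100),
            n_steps=0,
            table=table,
            members=np.arange(8),
        )
        assert out.cv[0][0].size == 0

    def test_recording_cadence(self, free_octet):
        state, table = free_octet
        out = run_umbrella(
            state,
            windows=[UmbrellaWindow(center=1.5, spring=100.0)],
            ladder=ReplicaLadder(temperatures=(1.0, 1.05), swap_interval=100),
            n_steps=4000,
            record_every=400,
            table=table,
            members=np.arange(8),
            seed=3,
        )
        assert out.cv[0][0].size == 4000 // 400
        assert len(out.cv[0]) == 2  # one series per rung

    def test_restrained_ideal_gas_matches_mc_oracle(self, free_octet):
        """The engine's biased R_g statistics agree with an independent
        Metropolis sampler of the same restrained ideal gas."""
        state, table = free_octet
        window = UmbrellaWindow(center=1.5, spring=200.0)
        members = np.arange(8)
        out = run_umbrella(
            state,
            windows=[window],
            ladder=ReplicaLadder(temperatures=(1.0,), swap_interval=100),
            n_steps=60_000,
            record_every=100,
            table=table,
            members=members,
            seed=5,
        )
        series = out.cv[0][0][50:]

        # independent MC oracle for the restrained ideal gas
        rng = np.random.default_rng(99)
        pts = state.positions.copy()
        rgs = []
        current = droplet_rg(pts, members)
        for it in range(60_000):
            i = rng.integers(8)
            prop = pts.copy()
            prop[i] += rng.normal(0, 0.3, 3)
            rg_new = droplet_rg(prop, members)
            du = bias_energy(rg_new, window) - bias_energy(current, window)
            if rng.random() < math.exp(-min(du, 700.0)):
                pts = prop
                current = rg_new
            if it > 5000 and it % 10 == 0:
                rgs.append(current)
        rgs = np.asarray(rgs)

        se = math.sqrt(series.var() / (series.size / 20) + rgs.var() / (rgs.size / 20))
        assert abs(series.mean() - rgs.mean()) < 4 * se + 0.01
        # variance of the restrained CV is of order k_BT/K
        assert series.var() == pytest.approx(rgs.var(), rel=0.5)
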