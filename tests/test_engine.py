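"""Pair potential, forces and the Langevin integrator."""

import math

import numpy as np
import pytest

from nucleodrop.engine import (
    HarmonicBias,
    IntegratorParams,
    SimulationInstabilityError,
    kinetic_temperature,
    langevin_step,
    maxwell_boltzmann_velocities,
    run,
    total_forces,
    total_potential,
)
from nucleodrop.genome import GenomeTopology, SimulationState
from nucleodrop.interactions import InteractionTable, PairPotential, pair_energy, pair_force


def particle_state(positions, confinement_radius=50.0, diameter=0.5, velocities=None):
    positions = np.asarray(positions, dtype=float)
    topo = GenomeTopology.particles_only(
        positions.shape[0],
        nucleolar_diameter=diameter,
        confinement_radius=confinement_radius,
    )
    v = np.zeros_like(positions) if velocities is None else np.asarray(velocities, float)
    return SimulationState(topo, positions, v), topo


class TestPairPotential:
    def test_zero_at_and_beyond_cutoff(self):
        pot = PairPotential.attractive(1.8, 0.5, 2.0)
        assert pair_energy(2.0, pot) == 0.0
        assert pair_energy(3.0, pot) == 0.0
        assert pair_force(2.5, pot) == 0.0

    def test_continuity_at_cutoff(self):
        pot = PairPotential.attractive(1.8, 0.5, 2.0)
        assert abs(pair_energy(2.0 - 1e-6, pot)) < 1e-5

    def test_minimum_depth_with_shift(self):
        # at r = 2^(1/6)*sigma_l the well depth is -eps + E_cut
        pot = PairPotential.attractive(1.8, 0.5, 2.0)
        r_min = 2 ** (1 / 6) * 0.5
        expected = -1.8 + pot.e_cut
        assert pair_energy(r_min, pot) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-0.999 * 1.8, rel=1e-3)

    def test_shift_identity_all_classes(self):
        table = InteractionTable.defaults()
        pots = [table.nuc_nuc, table.nuc_nad, table.nuc_nonnad, *table.chromatin.values()]
        for pot in pots:
            sr6 = (pot.sigma / pot.r_cut) ** 6
            assert pot.e_cut == pytest.approx(-4 * pot.epsilon * (sr6**2 - sr6), rel=1e-12)
            assert pot.r_cut > pot.sigma

    def test_invalid_separation(self):
        pot = PairPotential.attractive(1.0, 0.5, 2.0)
        with pytest.raises(ValueError):
            pair_energy(0.0, pot)

    def test_default_class_parameters(self):
        """The three nucleolar interaction classes at the operating point."""
        table = InteractionTable.defaults(nucleolar_diameter=0.5)
        assert (table.nuc_nuc.epsilon, table.nuc_nuc.sigma) == (1.8, 0.5)
        assert (table.nuc_nad.epsilon, table.nuc_nad.sigma) == (1.8, 0.75)
        assert (table.nuc_nonnad.epsilon, table.nuc_nonnad.sigma) == (1.0, 0.75)
        assert table.nuc_nuc.r_cut == 2.0

    def test_relaxed_table_weakens_nucleolar_attraction(self):
        table = InteractionTable.defaults().relaxed()
        assert table.nuc_nuc.epsilon == 1.0
        assert table.nuc_nad.epsilon == 1.0
        assert table.nuc_nonnad.epsilon == 1.0
        # chromatin classes untouched
        assert table.chromatin["BB"].epsilon == 0.3


class TestForces:
    def test_isolated_particle_far_from_wall(self):
        state, _ = particle_state([[0.0, 0.0, 0.0]])
        table = InteractionTable.for_topology(state.topology)
        np.testing.assert_allclose(total_forces(state, table), 0.0, atol=1e-12)

    def test_pair_at_minimum_has_zero_force(self):
        r_min = 2 ** (1 / 6) * 0.5
        state, _ = particle_state([[0, 0, 0], [r_min, 0, 0]])
        table = InteractionTable.for_topology(state.topology)
        np.testing.assert_allclose(total_forces(state, table), 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_central_difference(self, seed):
        """Forces equal the negative numeric gradient of the total energy."""
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-2.5, 2.5, size=(20, 3))
        state, topo = particle_state(pos, confinement_radius=4.5)
        table = InteractionTable.for_topology(topo)
        f = total_forces(state, table)
        h = 1e-6
        for i in range(0, 20, 5):
            for k in range(3):
                sp = state.copy()
                sp.positions[i, k] += h
                sm = state.copy()
                sm.positions[i, k] -= h
                grad = (total_potential(sp, table) - total_potential(sm, table)) / (2 * h)
                assert -grad == pytest.approx(f[i, k], rel=1e-5, abs=1e-4)

    def test_bias_force_matches_central_difference(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(-2, 2, size=(12, 3))
        state, topo = particle_state(pos, confinement_radius=30.0)
        table = InteractionTable.for_topology(topo)
        bias = HarmonicBias(members=np.arange(8), spring=120.0, center=1.5)
        f = total_forces(state, table, bias=bias)
        h = 1e-6
        for i in (0, 5, 7, 11):
            for k in range(3):
                sp = state.copy()
                sp.positions[i, k] += h
                sm = state.copy()
                sm.positions[i, k] -= h
                grad = (
                    total_potential(sp, table, bias=bias)
                    - total_potential(sm, table, bias=bias)
                ) / (2 * h)
                assert -grad == pytest.approx(f[i, k], rel=1e-5, abs=1e-4)


class TestIntegrator:
    def test_seed_repeatability(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-3, 3, (30, 3))
        state, topo = particle_state(pos, confinement_radius=10.0)
        table = InteractionTable.for_topology(topo)
        params = IntegratorParams(seed=42, record_every=100)
        t1, f1 = run(state, 500, params, table)
        t2, f2 = run(state, 500, params, table)
        np.testing.assert_array_equal(f1.positions, f2.positions)
        np.testing.assert_array_equal(t1.positions, t2.positions)

    def test_damped_free_motion_closed_form(self):
        """T = 0, no interactions: exponential velocity decay and the exact
        discrete BAOAB displacement sum."""
        v0 = np.array([[1.3, -0.7, 0.2]])
        state, topo = particle_state([[0.0, 0, 0]], velocities=v0, diameter=0.01)
        table = InteractionTable.for_topology(topo)
        params = IntegratorParams(dt=0.01, damping_time=2.0, temperature=0.0, seed=0)
        n = 200
        _, final = run(state, n, params, table)
        c1 = math.exp(-0.01 / 2.0)
        np.testing.assert_allclose(final.velocities, v0 * c1**n, rtol=1e-10)
        expected_x = v0 * 0.01 * (1 + c1) / 2 * (1 - c1**n) / (1 - c1)
        np.testing.assert_allclose(final.positions, expected_x, rtol=1e-10)

    def test_equipartition_free_particles(self):
        """Long free-particle run: mean kinetic energy 3/2 k_BT within 3 SE."""
        n = 200
        rng = np.random.default_rng(7)
        pos = rng.uniform(-20, 20, (n, 3))
        state, topo = particle_state(pos, confinement_radius=100.0, diameter=1e-3)
        table = InteractionTable.for_topology(topo)
        params = IntegratorParams(seed=3, record_every=4000)
        temps = []
        for _ in range(15):
            _, state = run(state, 1000, params, table)
            temps.append(kinetic_temperature(state.velocities))
        temps = np.array(temps[3:])  # discard equilibration of the OU process
        se = temps.std(ddof=1) / math.sqrt(len(temps))
        assert abs(temps.mean() - 1.0) < 3 * se + 0.02

    def test_nve_limit_conserves_energy(self):
        """No friction, no noise: the scheme reduces to velocity Verlet and
        conserves total energy to high relative accuracy.

        The cluster is bound and slow enough that no pair crosses the cutoff
        (the truncated potential has a force step there, which would cause
        physical, integrator-independent drift).
        """
        rng = np.random.default_rng(1)
        pos = 1.0 * np.stack(
            np.meshgrid(*[np.arange(2)] * 3, indexing="ij"), -1
        ).reshape(-1, 3).astype(float)
        pos += rng.normal(0, 0.005, pos.shape)
        vel = rng.normal(0, 0.05, pos.shape)
        state, topo = particle_state(pos, confinement_radius=50.0, velocities=vel)
        table = InteractionTable.for_topology(topo)
        params = IntegratorParams(
            dt=0.001, damping_time=float("inf"), temperature=0.0, seed=0
        )
        e0 = total_potential(state, table) + 0.5 * np.sum(state.velocities**2)
        _, final = run(state, 10_000, params, table)
        e1 = total_potential(final, table) + 0.5 * np.sum(final.velocities**2)
        assert abs(e1 - e0) / abs(e0) < 1e-4

    def test_harmonic_dimer_bond_statistics(self):
        """Bond-length variance of a bonded dimer matches the Boltzmann
        integral with the r^2 Jacobian within 3 SE."""
        from scipy.integrate import quad

        from nucleodrop.genome import ChromosomeSpec, build_topology

        topo = build_topology(
            [ChromosomeSpec("chr1", types=["A", "A"])], n_nucleolar=0,
            confinement_radius=50.0,
        )
        # diploid: two independent dimers
        pos = np.array(
            [[0, 0, 0], [1.0, 0, 0], [10, 10, 10], [11.0, 10, 10]], dtype=float
        )
        state = SimulationState(topo, pos, np.zeros_like(pos))
        table = InteractionTable.for_topology(topo)

        # exact Boltzmann moments for U(r) = k/2 (r-r0)^2 + WCA, weight r^2
        def boltz(r):
            u = 0.5 * table.bond_k * (r - table.bond_length) ** 2
            return r**2 * math.exp(-min(u, 500.0))

        z, _ = quad(boltz, 0.5, 1.5)
        m1, _ = quad(lambda r: r * boltz(r), 0.5, 1.5)
        m2, _ = quad(lambda r: r**2 * boltz(r), 0.5, 1.5)
        var_exact = m2 / z - (m1 / z) ** 2

        # damping 1 tau_B thermalizes the stiff bond mode quickly, so the
        # 800 tau_B run holds several hundred independent samples
        params = IntegratorParams(dt=0.004, damping_time=1.0, seed=9, record_every=25)
        traj, _ = run(state, 200_000, params, table)
        b = traj.positions[:, topo.bonds[:, 0]] - traj.positions[:, topo.bonds[:, 1]]
        lengths = np.linalg.norm(b, axis=2)[traj.n_frames // 5 :]
        var = lengths.var()
        n_eff = 2 * (0.8 * 200_000 * 0.004) / 4.0  # 2 bonds, tau_corr ~ 2 tau_B
        se = var_exact * math.sqrt(2.0 / n_eff)
        assert abs(var - var_exact) < 3 * se + 0.02 * var_exact

    def test_thermostat_on_interacting_fluid(self):
        """Kinetic temperature within 2% of target for a 100-particle
        repulsive LJ fluid.

        A condensing (attractive) fluid would release latent heat faster
        than the weak friction can drain it, biasing any thermostat check;
        the repulsive fluid equilibrates immediately.
        """
        from dataclasses import replace

        rng = np.random.default_rng(11)
        topo = GenomeTopology.particles_only(
            100, nucleolar_diameter=0.5, confinement_radius=5.0
        )
        from nucleodrop.genome import initialize_configuration

        state = initialize_configuration(topo, seed=2)
        state.velocities = maxwell_boltzmann_velocities(100, 1.0, rng)
        table = InteractionTable.for_topology(topo)
        table = replace(table, nuc_nuc=PairPotential.repulsive(0.5))
        temps = []
        work = state
        for k in range(14):
            _, work = run(
                work, 3_000, IntegratorParams(dt=0.004, seed=100 + k), table
            )
            temps.append(kinetic_temperature(work.velocities))
        assert abs(np.mean(temps[2:]) - 1.0) < 0.02

    def test_confinement_never_violated(self):
        topo = GenomeTopology.particles_only(
            50, nucleolar_diameter=0.5, confinement_radius=4.0
        )
        from nucleodrop.genome import initialize_configuration

        state = initialize_configuration(topo, seed=8)
        table = InteractionTable.for_topology(topo)
        traj, _ = run(state, 20_000, IntegratorParams(seed=1, record_every=200), table)
        r = np.linalg.norm(traj.positions, axis=2)
        assert (r < 4.0).all()

    def test_instability_reports_step(self):
        # two deeply overlapping particles detonate immediately
        state, topo = particle_state([[0, 0, 0], [0.05, 0, 0]])
        table = InteractionTable.for_topology(topo)
        with pytest.raises(SimulationInstabilityError) as exc:
            run(state, 100, IntegratorParams(seed=0), table)
        assert exc.value.step >= 1

    def test_single_step_api(self):
        state, topo = particle_state([[0, 0, 0], [2.5, 0, 0]])
        table = InteractionTable.for_topology(topo)
        out = langevin_step(state, IntegratorParams(seed=4), table)
        assert out.step == 1
        assert out is not state


class TestTrajectory:
    def test_frame_count_and_spacing(self):
        state, topo = particle_state(np.random.default_rng(0).uniform(-2, 2, (10, 3)))
        table = InteractionTable.for_topology(topo)
        traj, _ = run(state, 2000, IntegratorParams(seed=0, record_every=2000), table)
        assert traj.n_frames == 1
        traj, _ = run(state, 9000, IntegratorParams(seed=0, record_every=2000), table)
        assert traj.n_frames == 4
        assert np.allclose(np.diff(traj.times_tau), 2000 * 0.008)

    def test_physical_frame_interval(self):
        from nucleodrop.units import UnitSystem

        state, topo = particle_state([[0, 0, 0]])
        table = InteractionTable.for_topology(topo)
        traj, _ = run(state, 4000, IntegratorParams(seed=0, record_every=2000), table)
        us = UnitSystem.from_nucleus()
        times_s = traj.times_seconds(us)
        assert times_s[1] - times_s[0] == pytest.approx(57.6, abs=0.8)

    def test_save_load_round_trip(self, tmp_path):
        state, topo = particle_state(np.random.default_rng(1).uniform(-2, 2, (6, 3)))
        table = InteractionTable.for_topology(topo)
        traj, _ = run(state, 1000, IntegratorParams(seed=2, record_every=200), table)
        path = tmp_path / "traj.npz"
        traj.save(path)
        from nucleodrop.engine import Trajectory

        loaded = Trajectory.load(path)
        np.testing.assert_array_equal(loaded.positions, traj.positions)
        assert loaded.record_every == traj.record_every

    def test_xyz_output(self, tmp_path):
        state, topo = particle_state([[0, 0, 0], [1, 1, 1]])
        table = InteractionTable.for_topology(topo)
        traj, _ = run(state, 400, IntegratorParams(seed=0, record_every=200), table)
        path = tmp_path / "traj.xyz"
        traj.write_xyz(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "2"
        assert len(lines) == traj.n_frames * 4
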