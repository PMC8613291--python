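"""Droplet identification, tracking, switching events and exponents."""

import numpy as np
import pytest
from helpers import brute_force_dbscan, dbscan_core_mask, same_partition

from nucleodrop.clusters import (
    ClusterParams,
    classify_switch,
    cluster_series,
    dbscan_labels,
    droplet_members,
    growth_exponent,
    msd_exponent,
    time_averaged_msd,
)
from nucleodrop.fixtures import scripted_trajectory

CP = ClusterParams(eps=0.8, min_samples=4, min_droplet_size=10)


class TestDbscan:
    def test_two_separated_groups(self):
        rng = np.random.default_rng(0)
        pts = np.concatenate(
            [rng.normal(0, 0.2, (20, 3)), rng.normal(10, 0.2, (20, 3))]
        )
        labels = dbscan_labels(pts, eps=1.0, min_samples=4)
        assert len(set(labels[labels >= 0])) == 2

    def test_single_dense_group(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 0.1, (15, 3))
        labels = dbscan_labels(pts, eps=1.0, min_samples=4)
        assert set(labels) == {0}

    def test_matches_brute_force_oracle(self):
        """Partition equality with a quadratic reference implementation on
        many random instances (border-point ties checked structurally)."""
        rng = np.random.default_rng(42)
        n_checked = 0
        for trial in range(100):
            n = int(rng.integers(20, 81))
            pts = rng.uniform(0, 6, size=(n, 3))
            eps = float(rng.uniform(0.5, 1.4))
            ms = int(rng.integers(2, 6))
            ours = dbscan_labels(pts, eps, ms)
            ref = brute_force_dbscan(pts, eps, ms)
            core = dbscan_core_mask(pts, eps, ms)
            # noise sets and the partition restricted to core points must match
            assert np.array_equal(ours == -1, ref == -1)
            assert same_partition(ours[core], ref[core])
            # border points must join a cluster owning a core neighbour
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            for i in np.flatnonzero((ours >= 0) & ~core):
                for labels in (ours, ref):
                    mates = np.flatnonzero((labels == labels[i]) & core)
                    assert (d[i, mates] <= eps).any()
            n_checked += 1
        assert n_checked == 100

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 5, (60, 3))
        base = dbscan_labels(pts, 0.9, 4)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = pts @ rot.T + [3.0, -1.0, 2.0]
        assert same_partition(base, dbscan_labels(moved, 0.9, 4))

    def test_droplet_members_two_largest(self):
        rng = np.random.default_rng(4)
        pts = np.concatenate(
            [
                rng.normal(0, 0.15, (25, 3)),
                rng.normal(8, 0.15, (18, 3)),
                rng.normal([0, 8, 0], 0.15, (6, 3)),
            ]
        )
        members = droplet_members(pts, ClusterParams(eps=0.8, min_samples=4))
        assert members.size == 43

    def test_droplet_members_insufficient_clusters(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 0.1, (20, 3))
        with pytest.raises(ValueError):
            droplet_members(pts, ClusterParams(eps=0.8, min_samples=4), n_droplets=2)


class TestClusterSeries:
    def test_static_two_droplets(self):
        rng = np.random.default_rng(0)
        frame = np.concatenate(
            [rng.normal(0, 0.15, (15, 3)), rng.normal(6, 0.15, (15, 3))]
        )
        traj = np.repeat(frame[None], 10, axis=0)
        series = cluster_series(traj, CP)
        assert (series.counts == 2).all()
        assert not series.events
        # persistent identities: same two ids in every frame
        ids = {c.cluster_id for c in series.clusters[0]}
        for cl in series.clusters:
            assert {c.cluster_id for c in cl} == ids

    def test_membership_bookkeeping(self):
        """Droplet members plus noise account for every particle."""
        traj = scripted_trajectory("merge", seed=2)
        series = cluster_series(traj, CP)
        for t, cl in enumerate(series.clusters):
            in_clusters = sum(c.size for c in cl)
            labels = dbscan_labels(traj.nucleolar_positions[t], CP.eps, CP.min_samples)
            small = sum(
                s
                for s in np.unique(labels[labels >= 0], return_counts=True)[1]
                if s < CP.min_droplet_size
            )
            noise = (labels == -1).sum() + small
            assert in_clusters + noise == series.n_particles

    def test_scripted_merge_event(self):
        traj = scripted_trajectory("merge", seed=5, merge_frame=30)
        series = cluster_series(traj, CP)
        assert series.counts[0] == 2
        assert series.counts[-1] == 1
        merges = [e for e in series.events if e.kind == "merge"]
        assert len(merges) == 1
        assert merges[0].frame == 30

    def test_count_rotation_invariance(self):
        traj = scripted_trajectory("merge", seed=1)
        pos = traj.nucleolar_positions
        theta = 1.1
        rot = np.array(
            [
                [np.cos(theta), 0, np.sin(theta)],
                [0, 1, 0],
                [-np.sin(theta), 0, np.cos(theta)],
            ]
        )
        series_a = cluster_series(pos, CP)
        series_b = cluster_series(pos @ rot.T + 2.0, CP)
        np.testing.assert_array_equal(series_a.counts, series_b.counts)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            cluster_series(np.empty((0, 10, 3)), CP)


class TestSwitchClassification:
    def test_merge_is_bmc(self):
        traj = scripted_trajectory("merge", seed=5)
        series = cluster_series(traj, CP)
        (event,) = [e for e in series.events if e.kind == "merge"]
        assert classify_switch(event, series) == "BMC"

    def test_evaporation_is_dor(self):
        traj = scripted_trajectory("evaporate", seed=5, vanish_frame=30)
        series = cluster_series(traj, CP)
        events = [e for e in series.events if e.kind == "vanish"]
        assert events
        assert classify_switch(events[0], series) == "DOR"
        assert events[0].trend > 0.25

    def test_insufficient_history_unclassified(self):
        traj = scripted_trajectory("merge", seed=5, merge_frame=2, n_frames=10)
        series = cluster_series(traj, CP)
        merges = [e for e in series.events if e.kind == "merge"]
        if merges:  # merge within the first 2 frames leaves <3 history points
            assert classify_switch(merges[0], series) is None


class TestGrowthExponent:
    @pytest.mark.parametrize("beta", [0.1, 1.0 / 3.0])
    def test_exact_power_law(self, beta):
        t = np.linspace(2, 300, 60)
        assert growth_exponent(t, t**beta) == pytest.approx(beta, abs=1e-9)

    def test_noisy_power_law_within_ci(self):
        rng = np.random.default_rng(8)
        t = np.linspace(2, 300, 120)
        hits = 0
        for _ in range(20):
            y = t**0.25 * np.exp(rng.normal(0, 0.05, t.size))
            est = growth_exponent(t, y)
            # log-noise sigma = 0.05 -> slope SE ~ 0.05/(sqrt(n)*sd(log t))
            se = 0.05 / (np.sqrt(t.size) * np.log(t).std())
            hits += abs(est - 0.25) < 3 * se
        assert hits >= 18

    def test_fit_window(self):
        t = np.linspace(1, 100, 200)
        y = np.where(t < 50, t**0.5, t**0.0 * 50**0.5)
        assert growth_exponent(t, y, fit_window=(1, 40)) == pytest.approx(0.5, abs=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            growth_exponent(np.arange(1, 10), np.zeros(9))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            growth_exponent(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))


class TestMsd:
    def test_ballistic_exponent(self):
        traj = scripted_trajectory("ballistic", seed=2, n_frames=80)
        series = cluster_series(traj, CP)
        tracks = list(series.center_tracks(traj.nucleolar_positions).values())
        alpha, _ = msd_exponent(tracks)
        assert alpha == pytest.approx(2.0, abs=0.1)

    def test_fractional_noise_exponent(self):
        traj = scripted_trajectory("fbm", seed=1, n_frames=150, alpha=0.5)
        series = cluster_series(traj, CP)
        tracks = list(series.center_tracks(traj.nucleolar_positions).values())
        alpha, _ = msd_exponent(tracks)
        assert alpha == pytest.approx(0.5, abs=0.15)

    def test_free_brownian_particle(self):
        """A single free particle simulated by the engine diffuses normally."""
        from nucleodrop.engine import IntegratorParams, run
        from nucleodrop.genome import GenomeTopology, SimulationState
        from nucleodrop.interactions import InteractionTable

        topo = GenomeTopology.particles_only(
            3, nucleolar_diameter=0.01, confinement_radius=500.0
        )
        pos = np.array([[0.0, 0, 0], [50.0, 0, 0], [0, 50.0, 0]])
        state = SimulationState(topo, pos, np.zeros_like(pos))
        table = InteractionTable.for_topology(topo)
        traj, _ = run(
            state,
            100_000,
            IntegratorParams(seed=12, record_every=500, damping_time=1.0),
            table,
        )
        tracks = [traj.positions[:, i] for i in range(3)]
        alpha, d_eff = msd_exponent(tracks, fit_window=(2, 40))
        assert alpha == pytest.approx(1.0, abs=0.2)
        assert d_eff > 0

    def test_msd_zero_at_zero_lag(self):
        track = np.random.default_rng(0).normal(size=(30, 3))
        msd = time_averaged_msd(track)
        assert msd[0] == 0.0
        assert (msd[1:] >= 0).all()

    def test_short_tracks_rejected(self):
        with pytest.raises(ValueError):
            msd_exponent([np.zeros((5, 3))])
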