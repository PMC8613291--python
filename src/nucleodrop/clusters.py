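"""Droplet identification and coarsening analytics.

Droplets are high-density clusters of nucleolar particles found per frame
with DBSCAN.  Cluster identities are tracked across frames by maximal
shared-particle overlap; a decrease in the cluster count produces a
switching event, classified as

* BMC (Brownian-motion-induced coalescence): two clusters collide and fuse,
  with the intra-cluster mean pairwise distance of the participants staying
  roughly constant beforehand, or
* DOR (diffusion-limited Ostwald ripening): a cluster evaporates, its mean
  pairwise distance inflating significantly before it disappears.

The module also fits the coarsening power law R_g ~ t^beta of the mean
cluster size and the anomalous-diffusion exponent of cluster-center
mean-squared displacements (x^2 ~ D t^alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import linregress
from sklearn.cluster import DBSCAN

__all__ = [
    "NOISE",
    "ClusterParams",
    "dbscan_labels",
    "droplet_members",
    "FrameCluster",
    "SwitchingEvent",
    "ClusterTimeSeries",
    "cluster_series",
    "growth_exponent",
    "classify_switch",
    "msd_exponent",
    "time_averaged_msd",
]

#: DBSCAN noise sentinel.
NOISE = -1


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN neighbourhood radius, core threshold, and the minimum cluster
    size reported as a droplet.

    The default eps (0.6 sigma) is ~7% above the equilibrium pair distance
    2^(1/6)*sigma_p of nucleolar particles with diameter sigma_p = 0.5 sigma,
    and the droplet cut of 10 particles is calibrated for the 500-particle
    system; :meth:`for_topology` rescales both for scaled presets (the cut
    proportionally to the particle count, with a floor of 5).
    """

    eps: float = 0.6
    min_samples: int = 4
    min_droplet_size: int = 10

    def __post_init__(self) -> None:
        if not (self.eps > 0 and self.min_samples >= 1 and self.min_droplet_size >= 1):
            raise ValueError("invalid cluster parameters")

    @classmethod
    def for_topology(cls, topology, **overrides) -> "ClusterParams":
        eps = overrides.pop(
            "eps", 1.07 * 2 ** (1.0 / 6.0) * topology.nucleolar_diameter
        )
        min_size = overrides.pop(
            "min_droplet_size",
            max(5, round(10 * topology.n_nucleolar / 500)),
        )
        return cls(eps=eps, min_droplet_size=min_size, **overrides)


def dbscan_labels(positions: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Standard DBSCAN labels (noise = -1) for one frame of positions."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(positions)


def droplet_members(
    positions: np.ndarray,
    params: ClusterParams | None = None,
    n_droplets: int = 2,
    eps: float | None = None,
    min_samples: int | None = None,
) -> np.ndarray:
    """Indices of the particles in the ``n_droplets`` largest clusters."""
    if params is None:
        params = ClusterParams()
    labels = dbscan_labels(
        positions,
        eps=eps if eps is not None else params.eps,
        min_samples=min_samples if min_samples is not None else params.min_samples,
    )
    ids, sizes = np.unique(labels[labels != NOISE], return_counts=True)
    if ids.size < n_droplets:
        raise ValueError(
            f"found {ids.size} clusters, expected at least {n_droplets}"
        )
    keep = ids[np.argsort(sizes)[::-1][:n_droplets]]
    return np.flatnonzero(np.isin(labels, keep))


@dataclass
class FrameCluster:
    """One droplet in one frame."""

    cluster_id: int
    members: np.ndarray
    rg: float
    mean_pairwise: float

    @property
    def size(self) -> int:
        return int(self.members.size)


@dataclass
class SwitchingEvent:
    """A decrease in the droplet count: a merge (two ids map onto one
    surviving cluster) or a vanishing cluster."""

    frame: int
    kind: Literal["merge", "vanish"]
    involved: tuple[int, ...]
    survivor: int | None
    classification: Literal["BMC", "DOR"] | None = None
    trend: float | None = None


def _frame_clusters(
    positions: np.ndarray, params: ClusterParams
) -> list[tuple[np.ndarray, float, float]]:
    labels = dbscan_labels(positions, params.eps, params.min_samples)
    out = []
    for cid in np.unique(labels[labels != NOISE]):
        members = np.flatnonzero(labels == cid)
        if members.size < params.min_droplet_size:
            continue
        pts = positions[members]
        com = pts.mean(axis=0)
        rg = float(np.sqrt(np.mean(np.sum((pts - com) ** 2, axis=1))))
        mp = float(pdist(pts).mean()) if members.size > 1 else 0.0
        out.append((members, rg, mp))
    return out


@dataclass
class ClusterTimeSeries:
    """Per-frame droplet bookkeeping with persistent identities.

    ``counts[t]`` is the droplet count; ``clusters[t]`` the list of
    :class:`FrameCluster` with persistent ids; ``events`` the switching
    events.  Particles not in any droplet are noise; per frame,
    droplet members + noise = all particles.
    """

    times: np.ndarray
    counts: np.ndarray
    clusters: list[list[FrameCluster]]
    events: list[SwitchingEvent]
    n_particles: int
    params: ClusterParams

    def mean_rg(self) -> np.ndarray:
        """Mean droplet R_g per frame (NaN when no droplet exists)."""
        return np.array(
            [np.mean([c.rg for c in cl]) if cl else np.nan for cl in self.clusters]
        )

    def pairwise_history(self, cluster_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(frame indices, mean pairwise distance) for one persistent id."""
        frames, values = [], []
        for t, cl in enumerate(self.clusters):
            for c in cl:
                if c.cluster_id == cluster_id:
                    frames.append(t)
                    values.append(c.mean_pairwise)
        return np.asarray(frames), np.asarray(values)

    def center_tracks(self, positions: np.ndarray) -> dict[int, np.ndarray]:
        """Center-of-mass track per persistent id, NaN where absent.

        ``positions`` is the (n_frames, n_particles, 3) array the series was
        built from.
        """
        n_frames = len(self.clusters)
        tracks: dict[int, np.ndarray] = {}
        for t, cl in enumerate(self.clusters):
            for c in cl:
                if c.cluster_id not in tracks:
                    tracks[c.cluster_id] = np.full((n_frames, 3), np.nan)
                tracks[c.cluster_id][t] = positions[t, c.members].mean(axis=0)
        return tracks

    def times_minutes(self, units) -> np.ndarray:
        return self.times * units.time_unit / 60.0


def cluster_series(
    traj,
    params: ClusterParams | None = None,
    times: np.ndarray | None = None,
) -> ClusterTimeSeries:
    """Track droplets along a trajectory of nucleolar positions.

    ``traj`` is either an engine :class:`~nucleodrop.engine.Trajectory` (its
    nucleolar positions are used) or a (n_frames, n_particles, 3) array.
    Identities are matched frame-to-frame by maximal member overlap; merge
    and vanish events are recorded whenever the count decreases.
    """
    if hasattr(traj, "nucleolar_positions"):
        positions = traj.nucleolar_positions
        if times is None:
            times = traj.times_tau
    else:
        positions = np.asarray(traj, dtype=float)
    if positions.ndim != 3 or positions.shape[0] == 0:
        raise ValueError("trajectory must be a non-empty (frames, particles, 3) array")
    if times is None:
        times = np.arange(positions.shape[0], dtype=float)
    if params is None:
        params = ClusterParams()

    clusters_out: list[list[FrameCluster]] = []
    events: list[SwitchingEvent] = []
    prev: list[FrameCluster] = []
    next_id = 0
    for t in range(positions.shape[0]):
        raw = _frame_clusters(positions[t], params)
        # match to previous frame by maximal shared-particle overlap
        assigned: list[FrameCluster] = []
        claims: dict[int, list[tuple[int, int]]] = {}  # prev id -> (overlap, new idx)
        overlaps = []
        for k, (members, rg, mp) in enumerate(raw):
            best_id, best_ov = None, 0
            mset = set(members.tolist())
            for pc in prev:
                ov = len(mset.intersection(pc.members.tolist()))
                if ov > best_ov:
                    best_id, best_ov = pc.cluster_id, ov
            overlaps.append((best_id, best_ov))
        # resolve competing claims: the largest overlap keeps the old id
        winner: dict[int, int] = {}
        for k, (pid, ov) in enumerate(overlaps):
            if pid is None:
                continue
            if pid not in winner or overlaps[winner[pid]][1] < ov:
                winner[pid] = k
        for k, (members, rg, mp) in enumerate(raw):
            pid, ov = overlaps[k]
            if pid is not None and winner.get(pid) == k:
                cid = pid
            else:
                cid = next_id
                next_id += 1
            assigned.append(
                FrameCluster(cluster_id=cid, members=members, rg=rg, mean_pairwise=mp)
            )
        # events: previous ids that did not survive
        if prev and len(assigned) < len(prev):
            current_ids = {c.cluster_id for c in assigned}
            merged_targets: dict[int, list[int]] = {}
            for pc in prev:
                if pc.cluster_id in current_ids:
                    continue
                # where did its members go?
                best_k, best_ov = None, 0
                pset = set(pc.members.tolist())
                for k, c in enumerate(assigned):
                    ov = len(pset.intersection(c.members.tolist()))
                    if ov > best_ov:
                        best_k, best_ov = k, ov
                if best_k is not None and best_ov >= max(
                    params.min_samples, pc.size // 4
                ):
                    survivor = assigned[best_k].cluster_id
                    merged_targets.setdefault(survivor, []).append(pc.cluster_id)
                else:
                    events.append(
                        SwitchingEvent(
                            frame=t,
                            kind="vanish",
                            involved=(pc.cluster_id,),
                            survivor=None,
                        )
                    )
            for survivor, gone in merged_targets.items():
                events.append(
                    SwitchingEvent(
                        frame=t,
                        kind="merge",
                        involved=tuple(gone) + (survivor,),
                        survivor=survivor,
                    )
                )
        clusters_out.append(assigned)
        prev = assigned

    counts = np.array([len(cl) for cl in clusters_out])
    return ClusterTimeSeries(
        times=np.asarray(times, dtype=float),
        counts=counts,
        clusters=clusters_out,
        events=events,
        n_particles=positions.shape[1],
        params=params,
    )


def growth_exponent(
    times: np.ndarray,
    sizes: np.ndarray,
    fit_window: tuple[float, float] | None = None,
) -> float:
    """Power-law exponent beta of size ~ t^beta by least squares on log-log.

    ``fit_window`` restricts the fit to times in [t_min, t_max].  Requires at
    least 5 valid (positive, finite) points.
    """
    times = np.asarray(times, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    mask = np.isfinite(times) & np.isfinite(sizes) & (times > 0)
    if fit_window is not None:
        mask &= (times >= fit_window[0]) & (times <= fit_window[1])
    if (sizes[mask] <= 0).any():
        raise ValueError("sizes must be positive inside the fit window")
    if mask.sum() < 5:
        raise ValueError("need at least 5 points in the fit window")
    res = linregress(np.log(times[mask]), np.log(sizes[mask]))
    return float(res.slope)


def classify_switch(
    event: SwitchingEvent,
    series: ClusterTimeSeries,
    threshold: float = 0.25,
    window: int = 20,
) -> Literal["BMC", "DOR"] | None:
    """Classify a switching event by the pre-event trend of the disappearing
    cluster's mean pairwise distance.

    DOR iff the distance rises by more than ``threshold`` (relative) over the
    ``window`` frames before the event; BMC otherwise.  Returns None
    (unclassified) when fewer than 3 pre-event frames of history exist.
    The trend statistic (relative increase) is stored on the event.
    """
    gone = [cid for cid in event.involved if cid != event.survivor]
    best_trend = None
    for cid in gone:
        frames, values = series.pairwise_history(cid)
        mask = (frames < event.frame) & (frames >= event.frame - window)
        vals = values[mask]
        if vals.size < 3 or vals[0] <= 0:
            continue
        start = vals[: max(1, vals.size // 4)].mean()
        end = vals[-max(1, vals.size // 4) :].mean()
        trend = (end - start) / start
        if best_trend is None or trend > best_trend:
            best_trend = trend
    if best_trend is None:
        event.classification = None
        return None
    event.trend = best_trend
    event.classification = "DOR" if best_trend > threshold else "BMC"
    return event.classification


def time_averaged_msd(track: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Time-averaged MSD of one (possibly NaN-padded) 3D track per lag."""
    track = np.asarray(track, dtype=float)
    n = track.shape[0]
    if max_lag is None:
        max_lag = n - 1
    msd = np.full(max_lag + 1, np.nan)
    msd[0] = 0.0
    for lag in range(1, max_lag + 1):
        d = track[lag:] - track[:-lag]
        sq = np.sum(d * d, axis=1)
        valid = np.isfinite(sq)
        if valid.any():
            msd[lag] = np.nanmean(sq[valid])
    return msd


def msd_exponent(
    tracks: Sequence[np.ndarray],
    times: np.ndarray | None = None,
    fit_window: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Anomalous-diffusion exponent alpha and prefactor D from cluster-center
    tracks: fit log(MSD) vs log(t); MSD = 6 D t^alpha.

    ``tracks`` is a sequence of (n_frames, 3) center trajectories (NaN where
    the cluster is absent); the time-averaged MSDs are averaged across tracks
    before fitting.  Requires at least 20 usable frames.
    """
    tracks = [np.asarray(t, dtype=float) for t in tracks]
    if not tracks:
        raise ValueError("need at least one track")
    n = max(t.shape[0] for t in tracks)
    if n < 20:
        raise ValueError("tracks too short: need at least 20 frames")
    if times is None:
        times = np.arange(n, dtype=float)
    max_lag = n - 1
    msds = np.full((len(tracks), max_lag + 1), np.nan)
    for k, tr in enumerate(tracks):
        m = time_averaged_msd(tr, min(max_lag, tr.shape[0] - 1))
        msds[k, : m.size] = m
    mean_msd = np.nanmean(msds, axis=0)
    lags = times[: max_lag + 1] - times[0] if times.size > max_lag else np.arange(
        max_lag + 1, dtype=float
    )
    lo, hi = (1, max(2, max_lag // 4)) if fit_window is None else fit_window
    sel = np.arange(lo, min(hi, max_lag) + 1)
    sel = sel[np.isfinite(mean_msd[sel]) & (mean_msd[sel] > 0) & (lags[sel] > 0)]
    if sel.size < 3:
        raise ValueError("too few valid MSD points in the fit window")
    res = linregress(np.log(lags[sel]), np.log(mean_msd[sel]))
    alpha = float(res.slope)
    d_eff = float(np.exp(res.intercept) / 6.0)
    return alpha, d_eff
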