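"""Coalescence kinetics: committor analysis and neck-radius growth.

The committor of a configuration is the probability that unbiased dynamics
started from it (with velocities redrawn from Maxwell-Boltzmann) relaxes to
the single-droplet state rather than back to the two-droplet state; a
committor of 0.5 identifies a transition state.  During fusion, the thin
bridge (neck) connecting two droplets widens as a power law in time; in the
viscous regime dominated by the outer fluid the exponent is close to 1/2.

The neck is located by projecting the droplet members on the principal axis
of their position covariance, binning an axial density profile, and taking
the interior minimum; the neck radius is the largest distance from the axis
among particles in the minimum's slab.  A unimodal profile means the
droplets have fully fused (sentinel ``None``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import linregress

from .clusters import ClusterParams, dbscan_labels

__all__ = [
    "CommittorResult",
    "committor",
    "committor_md",
    "classify_end_state",
    "neck_radius",
    "NeckProfile",
    "neck_profile",
    "neck_growth_fit",
    "droplet_radius_from_rg",
]


def droplet_radius_from_rg(rg: float) -> float:
    """Radius of a uniform sphere with radius of gyration ``rg``: sqrt(5/3)*rg."""
    return math.sqrt(5.0 / 3.0) * rg


@dataclass
class CommittorResult:
    """Shooting-trajectory outcome counts.

    ``outcomes[c][k]`` is the end state ("single", "two" or "other") of trial
    k from configuration c.  ``fraction_single`` counts unambiguous trials.
    """

    outcomes: list[list[str]]
    n_trials: int

    @property
    def n_single(self) -> int:
        return sum(o.count("single") for o in self.outcomes)

    @property
    def n_two(self) -> int:
        return sum(o.count("two") for o in self.outcomes)

    @property
    def n_other(self) -> int:
        return sum(o.count("other") for o in self.outcomes)

    @property
    def fraction_single(self) -> float:
        decided = self.n_single + self.n_two
        return self.n_single / decided if decided else float("nan")

    def per_config_fraction(self) -> np.ndarray:
        out = []
        for o in self.outcomes:
            decided = o.count("single") + o.count("two")
            out.append(o.count("single") / decided if decided else np.nan)
        return np.asarray(out)


def committor(
    configs: Sequence,
    propagate: Callable,
    classify: Callable[[object], str],
    n_trials: int = 10,
    seed: int = 0,
) -> CommittorResult:
    """Generic shooting estimator of the committor.

    For each configuration, runs ``n_trials`` independent trials:
    ``propagate(config, rng)`` evolves a fresh copy with randomized initial
    conditions, and ``classify`` maps the outcome to "single", "two" or
    "other".  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    outcomes: list[list[str]] = []
    for config in configs:
        row = []
        for _ in range(n_trials):
            end = propagate(config, rng)
            label = classify(end)
            if label not in ("single", "two", "other"):
                raise ValueError(f"classifier returned {label!r}")
            row.append(label)
        outcomes.append(row)
    return CommittorResult(outcomes=outcomes, n_trials=n_trials)


def classify_end_state(positions: np.ndarray, params: ClusterParams) -> str:
    """Droplet-count classification of a frame of nucleolar positions:
    "single" (1 droplet), "two" (2 droplets), "other" (0 or >2)."""
    labels = dbscan_labels(positions, params.eps, params.min_samples)
    ids, sizes = np.unique(labels[labels >= 0], return_counts=True)
    n = int((sizes >= params.min_droplet_size).sum())
    return {1: "single", 2: "two"}.get(n, "other")


def committor_md(
    configs: Sequence,
    n_trials: int = 10,
    trial_steps: int = 200_000,
    params=None,
    table=None,
    cluster_params: ClusterParams | None = None,
    seed: int = 0,
) -> CommittorResult:
    """Committor from molecular-dynamics shooting trajectories.

    Each trial copies the configuration, redraws all velocities from the
    Maxwell-Boltzmann distribution at the run temperature, integrates
    ``trial_steps`` unbiased steps, and classifies the final recorded frame
    by its droplet count.
    """
    from .engine import IntegratorParams, maxwell_boltzmann_velocities, run
    from .interactions import InteractionTable

    if params is None:
        params = IntegratorParams()
    if cluster_params is None:
        cluster_params = ClusterParams.for_topology(configs[0].topology)

    def propagate(state, rng):
        nonlocal table
        if table is None:
            table = InteractionTable.for_topology(state.topology)
        work = state.copy()
        work.velocities = maxwell_boltzmann_velocities(
            work.topology.n_particles, params.temperature, rng
        )
        trial_params = IntegratorParams(
            dt=params.dt,
            damping_time=params.damping_time,
            temperature=params.temperature,
            seed=int(rng.integers(2**31)),
            record_every=max(trial_steps, 1),
        )
        _, final = run(work, trial_steps, trial_params, table)
        return final

    def classify(final):
        return classify_end_state(final.nucleolar_positions, cluster_params)

    return committor(configs, propagate, classify, n_trials=n_trials, seed=seed)


def neck_radius(
    positions: np.ndarray,
    members: np.ndarray | None = None,
    n_bins: int = 20,
    edge_exclude: int = 2,
    estimator: str = "max",
) -> float | None:
    """Neck radius of a dumbbell-shaped droplet pair, or ``None`` once fused.

    Members are projected on the leading principal axis of their position
    covariance; the axial density profile (``n_bins`` bins over the member
    extent) is searched for the minimum BETWEEN the two density peaks
    (sphere caps at the ends are always sparse, so the global minimum is not
    the neck), excluding ``edge_exclude`` bins at each end.  A valley that is
    not clearly below both peaks means the profile is unimodal: the droplets
    have fully fused and ``None`` is returned.

    ``estimator`` selects how the radius is read off the minimum's slab:

    * "max": the maximal distance from the axis among particles in the slab.
      Simple, but an extreme-value statistic, hence noisy for small necks.
    * "area": the radius of the circular cross-section implied by the
      particle count in the slab, sqrt(n_neck / n_peak) * R_peak, with the
      bulk reference taken from the higher peak slab.  Much less sensitive
      to single stray particles; used for neck-growth kinetics.
    """
    pts = np.asarray(positions, dtype=float)
    if members is not None:
        pts = pts[np.asarray(members, dtype=np.int64)]
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 member particles")
    com = pts.mean(axis=0)
    centered = pts - com
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    proj = centered @ axis
    counts, edges = np.histogram(proj, bins=n_bins)
    lo, hi = edge_exclude, n_bins - edge_exclude
    if hi - lo < 3:
        raise ValueError("edge_exclude too large for n_bins")
    interior = counts[lo:hi]
    # the two droplet peaks: the highest bin, and the highest bin at least
    # 3 bins away from it (sphere caps at the ends are always sparse, so the
    # neck is the minimum BETWEEN the peaks, not the global interior minimum)
    i1 = int(np.argmax(interior))
    far = np.abs(np.arange(interior.size) - i1) >= 3
    if not far.any():
        return None
    cand = np.flatnonzero(far)
    i2 = int(cand[np.argmax(interior[cand])])
    a, b = sorted((i1, i2))
    if b - a < 2:
        return None
    between = interior[a + 1 : b]
    m_rel = a + 1 + int(np.argmin(between))
    c_min = interior[m_rel]
    # unimodal (fully fused) when the valley is not clearly below both peaks
    if c_min >= 0.75 * min(interior[i1], interior[i2]):
        return None
    m = lo + m_rel
    in_slab = (proj >= edges[m]) & (proj < edges[m + 1])
    if estimator == "max":
        if not in_slab.any():
            return 0.0
        radial = centered[in_slab] - np.outer(proj[in_slab], axis)
        return float(np.linalg.norm(radial, axis=1).max())
    if estimator == "area":
        m_peak = lo + (a if interior[a] >= interior[b] else b)
        in_peak = (proj >= edges[m_peak]) & (proj < edges[m_peak + 1])
        if not in_peak.any():
            return 0.0
        radial_pk = np.linalg.norm(
            centered[in_peak] - np.outer(proj[in_peak], axis), axis=1
        )
        r_peak = math.sqrt(2.0 * float(np.mean(radial_pk**2)))
        n_neck = max(float(c_min), 0.25)  # resolution floor of ~1/4 particle
        return float(math.sqrt(n_neck / max(interior[m_peak - lo], 1)) * r_peak)
    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass
class NeckProfile:
    """Neck radius versus time during a fusion event.

    ``r0`` is the mean droplet radius before fusion (from per-droplet R_g via
    R = sqrt(5/3)*R_g); ``normalized`` is 2*R(t)/R_0.  ``fused[t]`` marks
    frames where the axial profile was already unimodal.
    """

    times: np.ndarray
    radius: np.ndarray
    r0: float
    exponent: float | None = None

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValueError("r0 must be positive")

    @property
    def normalized(self) -> np.ndarray:
        return 2.0 * self.radius / self.r0

    @property
    def fused(self) -> np.ndarray:
        return ~np.isfinite(self.radius)


def neck_profile(
    positions: np.ndarray,
    times: np.ndarray,
    r0: float,
    members: np.ndarray | None = None,
    n_bins: int = 20,
    cluster_filter: ClusterParams | None = None,
    estimator: str = "max",
) -> NeckProfile:
    """Neck radius per frame of a fusion trajectory (NaN once fused).

    With ``cluster_filter``, each frame keeps only the particles in the (up
    to) two largest density clusters, so vapor-phase particles exchanging
    with the droplets do not contaminate the axial density profile.
    """
    radius = np.empty(positions.shape[0])
    for t in range(positions.shape[0]):
        frame_members = members
        if cluster_filter is not None:
            labels = dbscan_labels(
                positions[t], cluster_filter.eps, cluster_filter.min_samples
            )
            ids, sizes = np.unique(labels[labels >= 0], return_counts=True)
            keep = ids[np.argsort(sizes)[::-1][:2]]
            frame_members = np.flatnonzero(np.isin(labels, keep))
            if members is not None:
                frame_members = np.intersect1d(frame_members, members)
            if frame_members.size < 4:
                radius[t] = np.nan
                continue
        r = neck_radius(
            positions[t], members=frame_members, n_bins=n_bins, estimator=estimator
        )
        radius[t] = np.nan if r is None else r
    return NeckProfile(times=np.asarray(times, dtype=float), radius=radius, r0=r0)


def neck_growth_fit(
    profile: NeckProfile,
    min_points: int = 5,
    min_normalized: float = 0.0,
) -> float:
    """Power-law exponent of normalized neck growth 2R(t)/R_0 ~ t^a.

    Least-squares slope on log-log over the pre-saturation window
    (min_normalized < 2R/R0 < 1, t > 0).  Requires ``min_points`` points.
    The fitted exponent is also stored on the profile.
    """
    t = profile.times
    y = profile.normalized
    mask = np.isfinite(y) & (y > min_normalized) & (y < 1.0) & (t > 0)
    if mask.sum() < min_points:
        raise ValueError(
            f"need at least {min_points} pre-saturation points, got {int(mask.sum())}"
        )
    res = linregress(np.log(t[mask]), np.log(y[mask]))
    profile.exponent = float(res.slope)
    return profile.exponent
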