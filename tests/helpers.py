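"""Shared oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np

from nucleodrop.sampling import UmbrellaWindow


def double_well(x, height=3.0):
    """Analytic double-well free energy h*(x^2-1)^2 in k_BT."""
    return height * (x**2 - 1.0) ** 2


def sample_biased_double_well(
    windows: list[UmbrellaWindow],
    n_samples: int = 20_000,
    burn_in: int = 2_000,
    step: float = 0.12,
    height: float = 3.0,
    temperature: float = 1.0,
    seed: int = 0,
):
    """Metropolis samples of exp(-(F(x) + bias_w(x))/T) for every window.

    All windows are advanced in lock-step with vectorised proposals; the
    sampler only knows the analytic double well, never WHAM, so it serves as
    an independent oracle for free-energy reconstruction.
    """
    rng = np.random.default_rng(seed)
    centers = np.array([w.center for w in windows])
    springs = np.array([w.spring for w in windows])
    x = centers.copy()
    out = np.empty((len(windows), n_samples))

    def energy(xx):
        return double_well(xx, height) + 0.5 * springs * (xx - centers) ** 2

    e = energy(x)
    kept = 0
    it = 0
    while kept < n_samples:
        prop = x + rng.normal(0, step, size=x.shape)
        e_new = energy(prop)
        accept = rng.random(x.shape) < np.exp(-(e_new - e) / temperature)
        x = np.where(accept, prop, x)
        e = np.where(accept, e_new, e)
        it += 1
        if it > burn_in and it % 3 == 0:
            out[:, kept] = x
            kept += 1
    return [out[w] for w in range(len(windows))]


def overdamped_double_well_committor(
    n_trials: int,
    seed: int = 0,
    height: float = 3.0,
    temperature: float = 1.0,
    dt: float = 1e-3,
    max_steps: int = 40_000,
    boundary: float = 0.85,
):
    """Fractions of overdamped-Langevin trajectories from the barrier top
    (x = 0) that commit to the right basin of the symmetric double well.

    Returns a list of end labels understood by the committor estimator
    ("single" for the right basin, "two" for the left).
    """
    rng = np.random.default_rng(seed)
    x = np.zeros(n_trials)
    done = np.zeros(n_trials, dtype=bool)
    label = np.empty(n_trials, dtype=object)
    noise = math.sqrt(2.0 * temperature * dt)
    for _ in range(max_steps):
        force = -4.0 * height * x * (x**2 - 1.0)
        x = x + force * dt + noise * rng.standard_normal(n_trials)
        newly = ~done & (np.abs(x) > boundary)
        label[newly & (x > 0)] = "single"
        label[newly & (x < 0)] = "two"
        done |= newly
        if done.all():
            break
    label[~done] = "other"
    return label.tolist()


def dbscan_core_mask(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    return (d <= eps).sum(axis=1) >= min_samples


def brute_force_dbscan(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Quadratic reference DBSCAN: core points, BFS over the core graph,
    border attachment; noise = -1."""
    n = points.shape[0]
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        queue = [i]
        labels[i] = cid
        while queue:
            j = queue.pop()
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        queue.append(k)
        cid += 1
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Equality of clusterings up to label permutation (noise must match)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    for la, lb in zip(a, b):
        if la == -1:
            continue
        if la in mapping:
            if mapping[la] != lb:
                return False
        else:
            if lb in mapping.values():
                return False
            mapping[la] = lb
    return True
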