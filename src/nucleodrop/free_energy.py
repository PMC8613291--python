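"""Free-energy profiles from umbrella sampling: WHAM, block-averaged errors,
and the finite-difference entropy/energy decomposition.

WHAM (weighted histogram analysis method) combines the biased histograms of
all umbrella windows into one unbiased profile by iterating the
self-consistency equations

    P(b) = sum_w n_w(b) / sum_w N_w exp[(f_w - U_w(b)) / kT]
    f_w  = -kT ln sum_b P(b) exp(-U_w(b) / kT)

until the window free-energy shifts f_w stop changing.  F(b) = -kT ln P(b)
up to an additive constant fixed by the anchor.  Profiles at temperatures a
step dT apart give the entropy along the coordinate by central difference,
S(x) = -[F(x; T+dT) - F(x; T-dT)] / (2 dT), and the energy E = F + T*S, so
the decomposition dF = dE - T*dS holds identically on the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sampling import UmbrellaWindow

__all__ = [
    "CoverageWarning",
    "FreeEnergyProfile",
    "Decomposition",
    "wham",
    "block_errors",
    "entropy_decomposition",
]


class CoverageWarning(UserWarning):
    """Adjacent umbrella windows have non-overlapping sample ranges."""


@dataclass
class FreeEnergyProfile:
    """F on a grid of CV values, in energy units (k_B = 1) at ``temperature``.

    ``f`` is finite on bins with samples and +inf elsewhere; F(anchor) = 0.
    """

    grid: np.ndarray
    f: np.ndarray
    temperature: float
    errors: np.ndarray | None = None
    anchor_index: int | None = None
    window_shifts: np.ndarray | None = field(default=None, repr=False)

    def probability(self) -> np.ndarray:
        """Normalized exp(-F/kT) over the grid (sums to 1 on finite bins)."""
        with np.errstate(over="ignore"):
            p = np.exp(-(self.f - np.nanmin(self.f[np.isfinite(self.f)])) / self.temperature)
        p[~np.isfinite(self.f)] = 0.0
        return p / p.sum()

    def anchored(self, anchor: str | int = "two-droplet") -> "FreeEnergyProfile":
        """Return a copy with F(anchor) = 0.

        ``anchor`` may be a bin index, "global" (global minimum) or
        "two-droplet" (the local minimum at the largest CV value, i.e. the
        separated-droplets basin, so barrier heights read off directly).
        """
        idx = _anchor_index(self.grid, self.f, anchor)
        f = self.f - self.f[idx]
        return FreeEnergyProfile(
            grid=self.grid.copy(),
            f=f,
            temperature=self.temperature,
            errors=None if self.errors is None else self.errors.copy(),
            anchor_index=idx,
            window_shifts=self.window_shifts,
        )


def _anchor_index(grid: np.ndarray, f: np.ndarray, anchor: str | int) -> int:
    finite = np.isfinite(f)
    if isinstance(anchor, (int, np.integer)):
        return int(anchor)
    if anchor == "global":
        return int(np.nanargmin(np.where(finite, f, np.inf)))
    if anchor == "two-droplet":
        # rightmost local minimum of the finite part
        idx = np.flatnonzero(finite)
        sub = f[idx]
        for k in range(len(idx) - 1, -1, -1):
            left = sub[k - 1] if k > 0 else np.inf
            right = sub[k + 1] if k < len(idx) - 1 else np.inf
            if sub[k] <= left and sub[k] <= right:
                return int(idx[k])
        return int(idx[-1])
    raise ValueError(f"unknown anchor {anchor!r}")


def _window_bias(window: UmbrellaWindow, grid: np.ndarray) -> np.ndarray:
    return 0.5 * window.spring * (grid - window.center) ** 2


def _check_coverage(samples, windows) -> None:
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        sa, sb = samples[a], samples[b]
        if len(sa) == 0 or len(sb) == 0:
            continue
        if min(sb) > max(sa) or min(sa) > max(sb):
            warnings.warn(
                f"no histogram overlap between windows centered at "
                f"{windows[a].center:g} and {windows[b].center:g}",
                CoverageWarning,
                stacklevel=3,
            )


def wham(
    samples: list[np.ndarray],
    windows: list[UmbrellaWindow],
    temperature: float = 1.0,
    bin_width: float = 0.05,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    anchor: str | int = "two-droplet",
    grid: np.ndarray | None = None,
) -> FreeEnergyProfile:
    """Self-consistent WHAM estimate of F(CV) from per-window CV samples.

    ``samples[w]`` holds the CV values collected in ``windows[w]``.  Iteration
    stops when the largest change in any window shift f_w drops below ``tol``
    (k_B*T).  Emits :class:`CoverageWarning` when adjacent windows do not
    overlap.  The result is anchored per ``anchor``.
    """
    if len(samples) != len(windows) or len(windows) == 0:
        raise ValueError("need one sample array per window")
    samples = [np.asarray(s, dtype=float) for s in samples]
    counts = np.array([s.size for s in samples], dtype=float)
    if counts.sum() == 0:
        raise ValueError("at least one window must contain samples")
    _check_coverage(samples, windows)

    allsamp = np.concatenate([s for s in samples if s.size])
    if grid is None:
        lo = np.floor(allsamp.min() / bin_width) * bin_width
        hi = np.ceil(allsamp.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
        if edges.size < 2:
            edges = np.array([lo, lo + bin_width])
        grid = 0.5 * (edges[:-1] + edges[1:])
    else:
        grid = np.asarray(grid, dtype=float)
        bin_width = grid[1] - grid[0] if grid.size > 1 else bin_width
        edges = np.concatenate([grid - bin_width / 2, [grid[-1] + bin_width / 2]])

    n_bins = grid.size
    hist = np.zeros((len(windows), n_bins))
    for w, s in enumerate(samples):
        if s.size:
            hist[w], _ = np.histogram(s, bins=edges)
    total_hist = hist.sum(axis=0)

    beta = 1.0 / temperature
    bias = np.stack([_window_bias(w, grid) for w in windows])  # (W, B)
    boltz = np.exp(-beta * bias)
    f_shift = np.zeros(len(windows))
    for _ in range(max_iter):
        # P(b) = sum_w n_w(b) / sum_w N_w exp(beta f_w) exp(-beta U_w(b))
        denom = (counts * np.exp(beta * f_shift)) @ boltz
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total_hist / denom, 0.0)
        z = boltz @ p
        with np.errstate(divide="ignore"):
            new_f = -temperature * np.log(np.where(z > 0, z, np.nan))
        new_f = np.nan_to_num(new_f, nan=0.0)
        new_f -= new_f[0]
        delta = np.max(np.abs(new_f - f_shift))
        f_shift = new_f
        if delta < tol:
            break

    with np.errstate(divide="ignore"):
        f = np.where(p > 0, -temperature * np.log(np.where(p > 0, p, 1.0)), np.inf)
    prof = FreeEnergyProfile(
        grid=grid, f=f, temperature=temperature, window_shifts=f_shift
    )
    return prof.anchored(anchor)


def block_errors(
    samples: list[np.ndarray],
    windows: list[UmbrellaWindow],
    n_blocks: int = 5,
    temperature: float = 1.0,
    anchor: str | int = "two-droplet",
    **wham_kwargs,
) -> FreeEnergyProfile:
    """Block-averaged uncertainty of the WHAM profile.

    Each window's series is split into ``n_blocks`` consecutive equal-length
    blocks; WHAM runs on each block separately (on the full-data grid) and
    the per-bin error is the standard deviation of the block estimates.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    samples = [np.asarray(s, dtype=float) for s in samples]
    for s in samples:
        if s.size and s.size < n_blocks:
            raise ValueError("every sampled window needs at least n_blocks samples")
    full = wham(samples, windows, temperature=temperature, anchor=anchor, **wham_kwargs)
    wham_kwargs = dict(wham_kwargs)
    wham_kwargs.pop("grid", None)
    block_profiles = []
    for b in range(n_blocks):
        block = [
            s[(b * s.size) // n_blocks : ((b + 1) * s.size) // n_blocks] for s in samples
        ]
        block_profiles.append(
            wham(
                block,
                windows,
                temperature=temperature,
                anchor=full.anchor_index,
                grid=full.grid,
                **wham_kwargs,
            )
        )
    stack = np.stack([bp.f for bp in block_profiles])
    finite = np.isfinite(stack).all(axis=0)
    errors = np.full(full.grid.size, np.nan)
    errors[finite] = np.std(stack[:, finite], axis=0, ddof=1)
    return FreeEnergyProfile(
        grid=full.grid,
        f=full.f,
        temperature=full.temperature,
        errors=errors,
        anchor_index=full.anchor_index,
        window_shifts=full.window_shifts,
    )


@dataclass
class Decomposition:
    """Entropic (-T*dS) and energetic (dE) parts of dF along the CV grid,
    relative to the anchor bin; dF = dE - T*dS holds bin-wise exactly."""

    grid: np.ndarray
    delta_f: np.ndarray
    delta_e: np.ndarray
    minus_t_delta_s: np.ndarray
    temperature: float
    delta_t: float


def entropy_decomposition(
    profile_low: FreeEnergyProfile,
    profile_mid: FreeEnergyProfile,
    profile_high: FreeEnergyProfile,
    anchor: str | int = "two-droplet",
) -> Decomposition:
    """Finite-difference decomposition of F(x; T) into energy and entropy.

    The three profiles must share a grid and be at temperatures T - dT, T,
    T + dT.  S(x) = -[F(x; T+dT) - F(x; T-dT)] / (2 dT) (central difference),
    E = F + T*S; both are reported relative to the anchor bin of the middle
    profile.
    """
    grids = [profile_low.grid, profile_mid.grid, profile_high.grid]
    if not all(g.shape == grids[0].shape and np.allclose(g, grids[0]) for g in grids):
        raise ValueError("profiles must share the same CV grid")
    t = profile_mid.temperature
    dt_lo = t - profile_low.temperature
    dt_hi = profile_high.temperature - t
    if not (dt_lo > 0 and dt_hi > 0):
        raise ValueError("temperatures must be ordered low < mid < high")
    if not np.isclose(dt_lo, dt_hi):
        raise ValueError("central difference requires equal temperature steps")

    idx = _anchor_index(profile_mid.grid, profile_mid.f, anchor)
    df = profile_mid.f - profile_mid.f[idx]
    s = -(profile_high.f - profile_low.f) / (dt_lo + dt_hi)
    s_rel = s - s[idx]
    minus_tds = -t * s_rel
    de = df + t * s_rel
    return Decomposition(
        grid=profile_mid.grid.copy(),
        delta_f=df,
        delta_e=de,
        minus_t_delta_s=minus_tds,
        temperature=t,
        delta_t=dt_lo,
    )
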