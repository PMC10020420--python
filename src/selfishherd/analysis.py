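"""Emergent-behaviour statistics of herd trajectories.

Quantifies what a trained herd does: mean squared displacement (motion
regimes), the rotational order parameter and its spatially resolved map
(milling), the median domain of danger (aggregation progress), and the
risk-sharing statistics — cumulative time-averaged DOD per agent, the
ensemble DOD autocorrelation, and the neighbour-persistence probability
p_NN(tau).

All lag statistics use the trajectory's uniform frame spacing Delta-t as the
time unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .environment import HerdFrame
from .geometry import compute_dod
from .trajectory import Trajectory

__all__ = [
    "LagSeries", "msd", "rotational_order", "spatial_rotation_map",
    "median_dod", "cumulative_dod", "cumulative_dod_distribution",
    "dod_acf", "neighbor_persistence", "correlation_time",
    "risk_spread", "msd_saturation_onset",
]


@dataclass
class LagSeries:
    """Values of a statistic on an increasing grid of time lags (units Delta-t).

    ``per_agent`` holds one column per agent when the statistic resolves
    individuals; ``values`` is always the ensemble series.
    """

    lags: np.ndarray                 # (L,) non-negative ints
    values: np.ndarray               # (L,) ensemble values
    per_agent: np.ndarray | None = None   # (L, N) or None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.lags) <= 0) or np.any(self.lags < 0):
            raise ValueError("lags must be non-negative and strictly increasing")


def _lag_grid(t_max: int, max_lags: int | None) -> np.ndarray:
    lags = np.arange(1, t_max)
    if max_lags is not None and lags.size > max_lags:
        lags = np.unique(np.geomspace(1, t_max - 1, max_lags).astype(int))
    return lags


def msd(traj: Trajectory, subtract_com: bool = True, max_lags: int | None = None) -> LagSeries:
    """Mean squared displacement per agent and ensemble-averaged.

    MSD_i(tau) is the time average over t of |x_i(t+tau) - x_i(t)|^2; with
    ``subtract_com`` the per-frame group centroid is removed first, isolating
    intra-group motion from collective drift.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    pos = traj.positions
    if subtract_com:
        pos = pos - pos.mean(axis=1, keepdims=True)
    lags = _lag_grid(traj.n_frames, max_lags)
    per_agent = np.empty((lags.size, traj.n_agents))
    for k, tau in enumerate(lags):
        d = pos[tau:] - pos[:-tau]
        per_agent[k] = (d**2).sum(axis=2).mean(axis=0)
    return LagSeries(lags, per_agent.mean(axis=1), per_agent)


def rotational_order(frame: HerdFrame, per_agent_abs: bool = False) -> float:
    """Rotational order parameter O_R in [0, 1].

    O_R = |(1/N) sum_i (rhat_i x uhat_i) . zhat| with rhat_i the unit vector
    from the group centroid to agent i and uhat_i its heading: 1 for a
    perfect mill, ~1/sqrt(N) for random headings.  ``per_agent_abs`` instead
    averages |rhat_i x uhat_i| per agent (baseline 2/pi for random headings);
    the signed-sum form is the primary definition.  Agents sitting on the
    centroid are excluded.
    """
    if frame.n_agents < 2:
        raise ValueError("need at least 2 agents")
    rel = frame.positions - frame.positions.mean(axis=0)
    r = np.linalg.norm(rel, axis=1)
    keep = r > 1e-9
    if not keep.any():
        raise ValueError("all agents coincide with the centroid: order undefined")
    rhat = rel[keep] / r[keep, None]
    u = np.c_[np.cos(frame.headings[keep]), np.sin(frame.headings[keep])]
    cross = rhat[:, 0] * u[:, 1] - rhat[:, 1] * u[:, 0]
    if per_agent_abs:
        return float(np.abs(cross).mean())
    return float(abs(cross.mean()))


def spatial_rotation_map(
    traj: Trajectory,
    grid_spacing: float = 1.0,
    window: int | None = None,
    min_visits: int = 5,
):
    """Spatially resolved rotational order O*_R(r) on a centroid-centred grid.

    Averages the signed cross product (rhat_i x uhat_i).zhat over all agent
    visits to each square cell during the last ``window`` frames; cells with
    fewer than ``min_visits`` visits are NaN.  Returns (x_centers, y_centers,
    field) with field indexed [iy, ix].
    """
    T = traj.n_frames
    window = T if window is None else int(window)
    if not 1 <= window <= T:
        raise ValueError("window must lie in [1, n_frames]")
    pos = traj.positions[T - window:]
    head = traj.headings[T - window:]
    rel = pos - pos.mean(axis=1, keepdims=True)
    r = np.linalg.norm(rel, axis=2)
    keep = r > 1e-9
    rhat = np.where(keep[..., None], rel / np.maximum(r, 1e-300)[..., None], 0.0)
    cross = rhat[..., 0] * np.sin(head) - rhat[..., 1] * np.cos(head)

    xy = rel[keep]
    cr = cross[keep]
    half = np.max(np.abs(xy)) + 0.5 * grid_spacing
    edges = np.arange(-half, half + grid_spacing, grid_spacing)
    ix = np.digitize(xy[:, 0], edges) - 1
    iy = np.digitize(xy[:, 1], edges) - 1
    nb = edges.size - 1
    counts = np.zeros((nb, nb))
    sums = np.zeros((nb, nb))
    np.add.at(counts, (iy, ix), 1.0)
    np.add.at(sums, (iy, ix), cr)
    with np.errstate(invalid="ignore"):
        field = np.where(counts >= min_visits, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, centers, field


def median_dod(traj: Trajectory):
    """Per-frame median DOD and per-frame mean total reward, as two (T,) arrays."""
    return np.median(traj.areas, axis=1), traj.rewards.mean(axis=1)


def cumulative_dod(traj: Trajectory) -> LagSeries:
    """Cumulative time-averaged DOD per agent, Abar_i(tau) = (1/tau) sum_{t<tau} A_i(t).

    Starts at tau = 1 frame; the ensemble series is the mean over agents.
    As tau grows the per-agent curves converge to a common value when risk is
    shared evenly.
    """
    T = traj.n_frames
    taus = np.arange(1, T + 1)
    per_agent = np.cumsum(traj.areas, axis=0) / taus[:, None]
    return LagSeries(taus, per_agent.mean(axis=1), per_agent)


def cumulative_dod_distribution(traj: Trajectory, bins: int = 40):
    """Histogram of {Abar_i(tau)} over agents at each tau, normalised to sum 1.

    Returns (taus, bin_centers, probs) with probs[k] the distribution at
    taus[k] (rows sum to 1).
    """
    series = cumulative_dod(traj)
    lo = float(series.per_agent.min())
    hi = float(series.per_agent.max())
    edges = np.linspace(lo, hi + 1e-12, bins + 1)
    probs = np.stack([
        np.histogram(row, bins=edges)[0] / row.size for row in series.per_agent
    ])
    return series.lags, 0.5 * (edges[:-1] + edges[1:]), probs


def dod_acf(traj: Trajectory, max_lags: int | None = None) -> LagSeries:
    """Ensemble-averaged autocorrelation of the per-agent DOD time series.

    Each agent's series is mean-removed and normalised by its own variance
    (so ACF(0) = 1), then the ACFs are averaged over agents.  Zero-variance
    agents are excluded with a warning; an all-constant trajectory is an
    error.
    """
    a = traj.areas - traj.areas.mean(axis=0)
    denom = (a**2).sum(axis=0)
    # constant-to-machine-precision series count as zero variance
    floor = (1e-9 * (np.abs(traj.areas).mean(axis=0) + 1.0)) ** 2 * traj.n_frames
    keep = denom > floor
    if not keep.any():
        raise ValueError("all agents have zero DOD variance: ACF undefined")
    if not keep.all():
        warnings.warn("excluding zero-variance agents from ACF", stacklevel=2)
    a = a[:, keep]
    denom = denom[keep]
    T = a.shape[0]
    lags = np.concatenate([[0], _lag_grid(T, max_lags)])
    vals = np.empty(lags.size)
    for k, tau in enumerate(lags):
        vals[k] = ((a[: T - tau] * a[tau:]).sum(axis=0) / denom).mean()
    return LagSeries(lags, vals)


def neighbor_persistence(
    traj: Trajectory, max_lags: int | None = None, stride: int = 1
) -> LagSeries:
    """Probability p_NN(tau) that current Voronoi neighbours are still neighbours
    after lag tau.

    Neighbourhoods are the cutoff-Voronoi adjacency sets recomputed per frame;
    reference times step by ``stride``.  Agents with an empty neighbour set at
    the reference time are excluded there.  p_NN(0) = 1 by construction.
    """
    T = traj.n_frames
    frames_idx = range(0, T, stride)
    neigh = {t: compute_dod(traj.positions[t], traj.delta).neighbor_sets() for t in frames_idx}
    lags = np.concatenate([[0], _lag_grid(T, max_lags)])
    lags = lags[(lags % stride) == 0] if stride > 1 else lags
    vals = np.empty(lags.size)
    for k, tau in enumerate(lags):
        fracs = []
        for t in frames_idx:
            if t + tau >= T or (t + tau) not in neigh:
                continue
            for s0, s1 in zip(neigh[t], neigh[t + tau]):
                if s0:
                    fracs.append(len(s0 & s1) / len(s0))
        vals[k] = np.mean(fracs) if fracs else np.nan
    good = np.isfinite(vals)
    return LagSeries(lags[good], vals[good])


def correlation_time(series: LagSeries, threshold: float = 1.0 / np.e) -> float:
    """Smallest lag at which the series first drops below ``threshold``.

    Returns inf when it never does (e.g. rigid rotation without mixing).
    """
    below = np.flatnonzero(series.values < threshold)
    return float(series.lags[below[0]]) if below.size else float("inf")


def risk_spread(traj: Trajectory) -> LagSeries:
    """Interquartile range of {Abar_i(tau)} over agents divided by the ensemble mean.

    A decaying spread is the quantitative signature of risk sharing: the
    time-averaged predation risks of all individuals converge.
    """
    series = cumulative_dod(traj)
    q1, q3 = np.percentile(series.per_agent, [25, 75], axis=1)
    return LagSeries(series.lags, (q3 - q1) / series.values)


def msd_saturation_onset(series: LagSeries, level: float = 0.95) -> float:
    """Smallest lag reaching ``level`` of the long-lag MSD plateau.

    The plateau is the mean over the last decade of lags.
    """
    lags = np.asarray(series.lags, float)
    plateau = series.values[lags >= lags[-1] / 10.0].mean()
    hit = np.flatnonzero(series.values >= level * plateau)
    return float(lags[hit[0]]) if hit.size else float("inf")
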