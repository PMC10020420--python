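"""The agent's observable: a five-sector vision cone with occlusion.

Each agent perceives a 180-degree cone ahead of it, split into five equal
36-degree sectors ordered left (counter-clockwise) to right.  Every visible
neighbour j adds sigma / |r_ij| to the sector containing the bearing of its
centre, so the observable measures per-sector crowdedness weighted by inverse
distance — a minimal model of animal vision.  With occlusion enabled a
neighbour is invisible when the sight line to its centre passes within half a
body diameter of any nearer agent's centre (finite-size sight blocking).
"""

from __future__ import annotations

import numpy as np

from .environment import HerdFrame

__all__ = ["N_SECTORS", "observe", "observe_all"]

N_SECTORS = 5


def _wrap_pi(angles: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - angles, 2.0 * np.pi)


def _sector_index(bearing: np.ndarray, half_angle: float) -> np.ndarray:
    """Sector of each bearing; ties on a boundary go to the lower (more CCW) index."""
    width = 2.0 * half_angle / N_SECTORS
    # left edge of the cone is +half_angle; sector 0 is leftmost
    idx = np.ceil((half_angle - bearing) / width) - 1
    return np.clip(idx, 0, N_SECTORS - 1).astype(int)


def _visible_mask(rel: np.ndarray, dist: np.ndarray, occlusion: bool) -> np.ndarray:
    """Occlusion filter: neighbour j is hidden if the segment to its centre passes
    within 1/2 sigma of a strictly nearer agent's centre."""
    m = rel.shape[0]
    vis = np.ones(m, dtype=bool)
    if not occlusion or m < 2:
        return vis
    order = np.argsort(dist)
    for rank, j in enumerate(order):
        if rank == 0:
            continue  # nearest neighbour can never be occluded
        blockers = order[:rank]
        nearer = rel[blockers][dist[blockers] < dist[j]]
        if nearer.size == 0:
            continue
        # distance from each nearer centre to segment 0 -> rel[j]
        e = rel[j]
        t = np.clip((nearer @ e) / (e @ e), 0.0, 1.0)
        d = np.linalg.norm(nearer - t[:, None] * e, axis=1)
        if np.any(d < 0.5):
            vis[j] = False
    return vis


def observe(
    frame: HerdFrame,
    agent_index: int,
    occlusion: bool = True,
    half_angle: float = np.pi / 2,
) -> np.ndarray:
    """Five-sector crowdedness observable of one agent.

    Parameters
    ----------
    frame
        Current herd state (must be overlap-free).
    agent_index
        Observer index.
    occlusion
        Apply finite-size sight blocking (on by default).
    half_angle
        Half-opening of the vision cone in radians (default pi/2, i.e. a
        180-degree cone; the cone is closed, so bearings of exactly
        +-half_angle are visible).

    Returns
    -------
    ndarray of shape (5,), non-negative crowdedness per sector, left to right.
    """
    n = frame.n_agents
    if not 0 <= agent_index < n:
        raise IndexError(f"agent index {agent_index} out of range for N={n}")
    rel = np.delete(frame.positions, agent_index, axis=0) - frame.positions[agent_index]
    dist = np.linalg.norm(rel, axis=1)
    if rel.shape[0] and np.min(dist) < 1e-9:
        raise ValueError("coincident agents: observable undefined")
    obs = np.zeros(N_SECTORS)
    if rel.shape[0] == 0:
        return obs
    bearing = _wrap_pi(np.arctan2(rel[:, 1], rel[:, 0]) - frame.headings[agent_index])
    in_cone = np.abs(bearing) <= half_angle + 1e-12
    vis = _visible_mask(rel, dist, occlusion) & in_cone
    if not vis.any():
        return obs
    np.add.at(obs, _sector_index(bearing[vis], half_angle), 1.0 / dist[vis])
    return obs


def observe_all(
    frame: HerdFrame, occlusion: bool = True, half_angle: float = np.pi / 2
) -> np.ndarray:
    """Observables of every agent, shape (N, 5)."""
    return np.stack(
        [observe(frame, i, occlusion=occlusion, half_angle=half_angle) for i in range(frame.n_agents)]
    )
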