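"""Deterministic herd configurations and scripted trajectories for testing.

Named generators — square lattice, tangential ring, rigidly rotating mill,
random gas, and a mirrored two-vortex pair — provide known-answer states for
the analysis statistics (a perfect mill has rotational order 1, a two-vortex
state has opposite-sign lobes in the spatial map, a re-scattered gas has no
neighbour persistence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import HerdFrame
from .geometry import compute_dod
from .reward import RewardParams, reward_total
from .trajectory import Trajectory

__all__ = ["FixtureSpec", "make_fixture", "trajectory_from_frames",
           "lattice_frame", "ring_frame", "mill_trajectory", "gas_trajectory",
           "two_vortex_trajectory"]


def trajectory_from_frames(
    frames: list[HerdFrame],
    rew: RewardParams = RewardParams(),
    actions: np.ndarray | None = None,
) -> Trajectory:
    """Assemble a Trajectory from explicit frames, computing DODs and rewards."""
    T = len(frames)
    n = frames[0].n_agents
    pos = np.stack([f.positions for f in frames])
    head = np.stack([f.headings for f in frames])
    areas = np.empty((T, n))
    nnd = np.empty((T, n))
    for t, f in enumerate(frames):
        dod = compute_dod(f.positions, rew.delta)
        areas[t] = np.minimum(dod.areas, rew.a_max)
        nnd[t] = dod.nn_distance
    br = reward_total(areas.ravel(), nnd.ravel(), rew)
    if actions is None:
        actions = np.full((max(T - 1, 0), n), 3, dtype=int)  # stand still
    return Trajectory(pos, head, areas, nnd,
                      br.r_shh.reshape(T, n), br.r_prox.reshape(T, n),
                      actions, delta=rew.delta)


def lattice_frame(n_side: int = 5, spacing: float = 2.0) -> HerdFrame:
    """Square lattice of n_side^2 agents, all heading +x."""
    g = np.arange(n_side) * spacing
    xx, yy = np.meshgrid(g, g)
    pos = np.c_[xx.ravel(), yy.ravel()]
    return HerdFrame(0, pos, np.zeros(len(pos)))


def ring_frame(
    n: int = 24, radius: float = 5.0, handedness: np.ndarray | int = 1,
    center=(0.0, 0.0),
) -> HerdFrame:
    """Agents on a circle with tangential headings.

    ``handedness`` is +1 (counter-clockwise), -1, or a per-agent array of
    signs — half-and-half gives zero net rotational order.
    """
    phi = 2 * np.pi * np.arange(n) / n
    pos = np.asarray(center) + radius * np.c_[np.cos(phi), np.sin(phi)]
    hand = np.broadcast_to(np.asarray(handedness, float), (n,))
    headings = phi + hand * np.pi / 2
    return HerdFrame(0, pos, headings)


def _mill_frames(
    n_rings: int, per_ring: int, r0: float, omega: float, n_frames: int,
    center=(0.0, 0.0), handedness: int = 1,
) -> list[HerdFrame]:
    frames = []
    radii = r0 * (1 + np.arange(n_rings))
    for t in range(n_frames):
        pos_list, head_list = [], []
        for k, radius in enumerate(radii):
            m = per_ring + 4 * k  # keep spacing roughly even across rings
            phi = 2 * np.pi * np.arange(m) / m + handedness * omega * t + 0.5 * k
            pos_list.append(np.asarray(center) + radius * np.c_[np.cos(phi), np.sin(phi)])
            head_list.append(phi + handedness * np.pi / 2)
        frames.append(HerdFrame(t, np.vstack(pos_list), np.concatenate(head_list)))
    return frames


def mill_trajectory(
    n_rings: int = 3, per_ring: int = 8, r0: float = 1.5, omega: float = 0.05,
    n_frames: int = 50, handedness: int = 1, rew: RewardParams = RewardParams(),
) -> Trajectory:
    """Rigidly rotating concentric-ring mill: tangential headings, fixed topology."""
    return trajectory_from_frames(
        _mill_frames(n_rings, per_ring, r0, omega, n_frames, handedness=handedness), rew
    )


def gas_trajectory(
    n: int = 20, box_side: float = 12.0, n_frames: int = 30,
    rescatter: bool = True, seed: int = 0, rew: RewardParams = RewardParams(),
) -> Trajectory:
    """Random gas; with ``rescatter`` every frame is an independent configuration
    (no neighbour persistence), otherwise the frame is frozen in time."""
    rng = np.random.default_rng(seed)

    def draw():
        from .environment import init_episode
        return init_episode(n, box_side, rng)

    first = draw()
    frames = [
        HerdFrame(t, draw().positions if (rescatter and t) else first.positions.copy(),
                  rng.uniform(0, 2 * np.pi, n))
        for t in range(n_frames)
    ]
    return trajectory_from_frames(frames, rew)


def two_vortex_trajectory(
    per_ring: int = 10, r0: float = 1.5, separation: float = 14.0,
    omega: float = 0.05, n_frames: int = 40, rew: RewardParams = RewardParams(),
) -> Trajectory:
    """Two mirrored mills (opposite handedness) — zero global rotation but
    opposite-sign lobes in the spatial rotation map."""
    half = separation / 2.0
    frames = []
    left = _mill_frames(2, per_ring, r0, omega, n_frames, center=(-half, 0.0), handedness=1)
    right = _mill_frames(2, per_ring, r0, omega, n_frames, center=(half, 0.0), handedness=-1)
    for t, (fl, fr) in enumerate(zip(left, right)):
        frames.append(HerdFrame(
            t,
            np.vstack([fl.positions, fr.positions]),
            np.concatenate([fl.headings, fr.headings]),
        ))
    return trajectory_from_frames(frames, rew)


@dataclass(frozen=True)
class FixtureSpec:
    """Named fixture request: generator name, geometry parameters, seed."""

    name: str                     # lattice | ring | mill | gas | two_vortex
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_fixture(spec: FixtureSpec):
    """Dispatch a FixtureSpec to its generator; deterministic given the seed."""
    p = dict(spec.params)
    if spec.name == "lattice":
        return lattice_frame(**p)
    if spec.name == "ring":
        return ring_frame(**p)
    if spec.name == "mill":
        return mill_trajectory(**p)
    if spec.name == "gas":
        return gas_trajectory(seed=spec.seed, **p)
    if spec.name == "two_vortex":
        return two_vortex_trajectory(**p)
    raise ValueError(f"unknown fixture: {spec.name!r}")
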