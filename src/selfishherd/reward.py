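"""Per-agent reward: linear domain-of-danger term plus proximity penalty.

The selfish-herd term r_SHH rewards a small Voronoi domain of danger A,

    r_SHH(A) = (A_max - A) / (A_max - A_min),

with A_min = pi (sigma/2)^2 the body area of one agent and
A_max = pi delta^2 the area of the full cutoff disk, so r_SHH runs linearly
from 1 (minimal risk) to 0 (isolated agent).  A smooth tanh penalty
discourages nearest-neighbour distances d below the threshold d0,

    r_prox(d) = -c [1 - tanh((d - d0) / w)],

with weight c (default 0.375) and crossover width w (default 2 sigma).  The
total per-agent reward is their sum, bounded in [-2c, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RewardParams", "RewardBreakdown", "reward_shh", "reward_prox", "reward_total"]


@dataclass(frozen=True)
class RewardParams:
    """Reward constants; lengths in sigma.

    ``d0`` controls which collective state emerges: 1.0 sigma gives strongly
    rotating single-vortex groups, 1.5 sigma weakly rotating ones.
    """

    c: float = 0.375
    d0: float = 1.0
    delta: float = 10.0
    sigma: float = 1.0
    width: float = 2.0   # tanh crossover width w

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.delta <= self.d0:
            raise ValueError("delta must exceed d0")
        if self.width <= 0 or self.sigma <= 0:
            raise ValueError("width and sigma must be positive")

    @property
    def a_min(self) -> float:
        return float(np.pi * (self.sigma / 2.0) ** 2)

    @property
    def a_max(self) -> float:
        return float(np.pi * self.delta**2)


@dataclass(frozen=True)
class RewardBreakdown:
    """Per-agent reward components; total = r_shh + r_prox."""

    r_shh: np.ndarray
    r_prox: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.r_shh + self.r_prox


def reward_shh(area, params: RewardParams = RewardParams()):
    """Selfish-herd reward of a DOD area, linear in A and clipped to [0, 1].

    Areas transiently below A_min (possible during overlap resolution) clip
    to 1 so the reward stays bounded.
    """
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0) or np.any(area > params.a_max * (1 + 1e-9)):
        raise ValueError("area must lie in (0, A_max]")
    r = (params.a_max - area) / (params.a_max - params.a_min)
    return np.clip(r, 0.0, 1.0)


def reward_prox(d, params: RewardParams = RewardParams()):
    """Proximity penalty of a nearest-neighbour distance; smooth step of width w."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    return -params.c * (1.0 - np.tanh((d - params.d0) / params.width))


def reward_total(
    areas, nn_distances, params: RewardParams = RewardParams()
) -> RewardBreakdown:
    """Element-wise combined reward for aligned per-agent areas and NN distances."""
    areas = np.asarray(areas, dtype=float)
    nn = np.asarray(nn_distances, dtype=float)
    if areas.shape != nn.shape:
        raise ValueError("areas and nn_distances must be aligned per agent")
    # nn = +inf (single agent) gives tanh -> 1, i.e. zero penalty, as it should
    return RewardBreakdown(reward_shh(areas, params), reward_prox(nn, params))
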