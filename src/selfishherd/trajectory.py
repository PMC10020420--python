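"""In-memory trajectory container: time series of herd frames with rewards and DODs.

A Trajectory is the unit of analysis: T uniformly spaced frames of N agents,
with the per-frame per-agent DOD areas, nearest-neighbour distances, reward
components, and the action chosen in each non-final frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import HerdFrame

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    positions: np.ndarray           # (T, N, 2) sigma
    headings: np.ndarray            # (T, N) radians
    areas: np.ndarray               # (T, N) DOD areas, sigma^2
    nn_dist: np.ndarray             # (T, N) nearest-neighbour distances, sigma
    r_shh: np.ndarray               # (T, N)
    r_prox: np.ndarray              # (T, N)
    actions: np.ndarray             # (T-1, N) int; action taken in frame t
    delta: float = 10.0             # Voronoi cutoff used for the areas
    config: dict = field(default_factory=dict)   # provenance (parameters, seed)

    def __post_init__(self) -> None:
        t, n = self.positions.shape[:2]
        expect = {
            "headings": (t, n), "areas": (t, n), "nn_dist": (t, n),
            "r_shh": (t, n), "r_prox": (t, n), "actions": (max(t - 1, 0), n),
        }
        for name, shape in expect.items():
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, expected {shape}")

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_agents(self) -> int:
        return int(self.positions.shape[1])

    @property
    def rewards(self) -> np.ndarray:
        """Total per-agent reward per frame, (T, N)."""
        return self.r_shh + self.r_prox

    def frame(self, t: int) -> HerdFrame:
        return HerdFrame(t, self.positions[t].copy(), self.headings[t].copy())

    def __len__(self) -> int:
        return self.n_frames
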