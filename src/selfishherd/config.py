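"""Run configuration: every simulation, reward, perception and training knob.

One flat, validated record whose defaults are the study conditions: groups of
100 disk agents, Voronoi cutoff delta = 10 sigma, step 0.25 sigma, turning
radius 0.8 sigma at 18 degrees, 20 % action noise, reward weight c = 0.375
with proximity threshold d0 of 1.0 sigma (strongly rotating groups) or
1.5 sigma (weakly rotating groups), and 30 training episodes of 3000 steps.

Configs load from YAML (unknown keys rejected), round-trip losslessly, and
hash deterministically so every artifact can be traced to its exact
parameters and master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields

import numpy as np
import yaml

from .environment import KinematicsParams
from .marl import TrainingConfig
from .reward import RewardParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # herd and environment
    n_agents: int = 100
    box_side: float = 40.0
    step_length: float = 0.25
    turn_radius: float = 0.8
    turn_angle_deg: float = 18.0
    noise_sd: float = 0.2
    # perception
    occlusion: bool = True
    half_angle_deg: float = 90.0
    # reward
    delta: float = 10.0
    c: float = 0.375
    d0: float = 1.0
    prox_width: float = 2.0
    # training
    steps_per_episode: int = 3000
    n_episodes: int = 30
    gamma: float = 0.99
    learning_rate: float = 1e-3
    entropy_weight: float = 0.01
    hidden: tuple[int, ...] = (64, 64)
    minibatch: int = 8192
    epochs: int = 4
    grad_clip: float = 1.0
    ratio_clip: float = 0.2
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden", tuple(int(h) for h in self.hidden))
        # delegate range validation to the parameter objects themselves
        self.kinematics()
        self.reward()
        self.training()
        if not 0 < self.half_angle_deg <= 180:
            raise ValueError("half_angle_deg must lie in (0, 180]")

    # ---- views onto the module-level parameter objects -------------------
    def kinematics(self) -> KinematicsParams:
        return KinematicsParams(
            self.step_length, self.turn_radius, np.deg2rad(self.turn_angle_deg), self.noise_sd
        )

    def reward(self) -> RewardParams:
        return RewardParams(c=self.c, d0=self.d0, delta=self.delta, width=self.prox_width)

    def training(self) -> TrainingConfig:
        return TrainingConfig(
            n_agents=self.n_agents,
            steps_per_episode=self.steps_per_episode,
            n_episodes=self.n_episodes,
            gamma=self.gamma,
            learning_rate=self.learning_rate,
            entropy_weight=self.entropy_weight,
            hidden=tuple(self.hidden),
            minibatch=self.minibatch,
            epochs=self.epochs,
            grad_clip=self.grad_clip,
            ratio_clip=self.ratio_clip,
            box_side=self.box_side,
            seed=self.seed,
        )

    @property
    def half_angle(self) -> float:
        return float(np.deg2rad(self.half_angle_deg))

    # ---- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden"] = list(d["hidden"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Short deterministic digest identifying this exact configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
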