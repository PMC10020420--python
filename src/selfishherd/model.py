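"""Model/Results interface: fit a selfish-herd policy, then interrogate it.

``SelfishHerd`` bundles a RunConfig the way a statistical model bundles its
data and design; ``fit()`` runs the episodic CTDE training and returns a
``HerdResults`` carrying the trained policy, the training log, and accessors
for steady-state simulation and the emergent-behaviour statistics.

    >>> model = SelfishHerd(RunConfig(n_agents=20, steps_per_episode=200,
    ...                               n_episodes=5))
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    >>> traj = res.simulate(n_steps=500, seed=2)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import analysis
from .config import RunConfig
from .marl import ActorCritic, TrainingLog, rollout, train
from .trajectory import Trajectory

__all__ = ["SelfishHerd", "HerdResults"]


class SelfishHerd:
    """A herd of selfish disk agents minimising their Voronoi domains of danger."""

    def __init__(self, config: RunConfig | None = None, **overrides):
        if config is None:
            config = RunConfig(**overrides)
        elif overrides:
            config = replace(config, **overrides)
        self.config = config

    @classmethod
    def from_yaml(cls, path) -> "SelfishHerd":
        return cls(RunConfig.from_yaml(path))

    def fit(self, seed: int | None = None, callback=None) -> "HerdResults":
        """Train the shared policy; returns a results object."""
        cfg = self.config if seed is None else replace(self.config, seed=int(seed))
        policy, log = train(
            cfg.training(), cfg.kinematics(), cfg.reward(),
            occlusion=cfg.occlusion, half_angle=cfg.half_angle, callback=callback,
        )
        return HerdResults(self, policy, log, cfg)

    def simulate(self, policy, n_steps: int, seed: int = 0, n_agents: int | None = None,
                 start=None) -> Trajectory:
        """Frozen-policy rollout under this model's environment parameters."""
        cfg = self.config
        return rollout(
            policy, n_steps, n_agents or cfg.n_agents, cfg.kinematics(), cfg.reward(),
            seed=seed, box_side=cfg.box_side, occlusion=cfg.occlusion,
            half_angle=cfg.half_angle, start=start,
        )


@dataclass
class HerdResults:
    """Trained policy plus training diagnostics and analysis accessors."""

    model: SelfishHerd
    policy: ActorCritic
    log: TrainingLog
    config: RunConfig

    @property
    def training_table(self) -> pd.DataFrame:
        return self.log.to_frame()

    def simulate(self, n_steps: int, seed: int = 0, **kw) -> Trajectory:
        return self.model.simulate(self.policy, n_steps, seed=seed, **kw)

    def ness_statistics(self, traj: Trajectory, burn_in: int = 0) -> dict:
        """Headline steady-state statistics of a rollout trajectory."""
        if burn_in:
            traj = Trajectory(
                traj.positions[burn_in:], traj.headings[burn_in:], traj.areas[burn_in:],
                traj.nn_dist[burn_in:], traj.r_shh[burn_in:], traj.r_prox[burn_in:],
                traj.actions[burn_in:], delta=traj.delta, config=traj.config,
            )
        order = np.array([
            analysis.rotational_order(traj.frame(t)) for t in range(traj.n_frames)
        ])
        acf = analysis.dod_acf(traj, max_lags=200)
        pnn = analysis.neighbor_persistence(
            traj, max_lags=40, stride=max(1, traj.n_frames // 50)
        )
        spread = analysis.risk_spread(traj)
        return {
            "mean_reward": float(traj.rewards.mean()),
            "median_dod": float(np.median(traj.areas)),
            "rotational_order": float(order.mean()),
            "rotational_order_se": float(order.std() / np.sqrt(len(order))),
            "acf_correlation_time": analysis.correlation_time(acf),
            "pnn_half_lag": analysis.correlation_time(pnn, threshold=0.5),
            "risk_spread_initial": float(spread.values[0]),
            "risk_spread_final": float(spread.values[-1]),
        }

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of a regression results table."""
        cfg = self.config
        df = self.training_table
        lines = [
            "Selfish-herd MARL fit",
            "=" * 58,
            f"agents: {cfg.n_agents:>5d}    episodes: {cfg.n_episodes:>5d}"
            f"    steps/episode: {cfg.steps_per_episode}",
            f"reward: c={cfg.c}, d0={cfg.d0} sigma, delta={cfg.delta} sigma",
            f"kinematics: step {cfg.step_length} sigma, turn {cfg.turn_angle_deg} deg"
            f" @ R={cfg.turn_radius} sigma, noise {cfg.noise_sd:.0%}",
            f"seed: {cfg.seed}    config hash: {cfg.hash()}",
            "-" * 58,
            f"mean reward:  first episode {df.mean_reward.iloc[0]:+.4f}"
            f"   final episode {df.mean_reward.iloc[-1]:+.4f}",
            f"median DOD :  first episode {df.median_dod.iloc[0]:8.2f}"
            f"   final episode {df.median_dod.iloc[-1]:8.2f}  (sigma^2)",
            f"final entropy of policy: {df.entropy.iloc[-1]:.3f} nats",
            "=" * 58,
        ]
        return "\n".join(lines)

    def save_policy(self, path) -> None:
        self.policy.save(path)
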