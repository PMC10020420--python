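"""Multi-agent reinforcement learning with centralized training, decentralized execution.

One shared actor network maps each agent's five-sector observable to a
probability distribution over the four actions; a critic network of the same
shape provides a state-value baseline.  All agents act on their own local
observables (decentralized execution) while a single parameter set is trained
on the experience pooled across the whole group (centralized training) — the
CTDE paradigm.

Training is episodic advantage actor-critic: each episode starts from a fresh
random configuration, runs the observe -> policy -> action -> step -> reward
loop for every agent, then performs one epoch of minibatch Adam updates on
the pooled (observable, action, discounted-return) batch.  Networks and the
optimiser are plain numpy (two 64-unit tanh hidden layers, softmax head),
small enough that a full training run is a single-CPU job.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .environment import (
    N_ACTIONS, Action, HerdFrame, KinematicsParams, init_episode, step,
)
from .geometry import compute_dod
from .perception import N_SECTORS, observe_all
from .reward import RewardParams, reward_total
from .trajectory import Trajectory

__all__ = [
    "MLP", "Adam", "ActorCritic", "TrainingConfig", "TrainingLog",
    "policy_evaluate", "sample_action", "discounted_returns",
    "train", "rollout", "ScriptedPolicy", "random_policy",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# minimal neural-network machinery (numpy)                                    #
# --------------------------------------------------------------------------- #

class MLP:
    """Fully connected tanh network; forward caches activations for backprop."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.W = [
            rng.normal(0.0, np.sqrt(1.0 / sizes[k]), (sizes[k], sizes[k + 1]))
            for k in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[k + 1]) for k in range(len(sizes) - 1)]
        self._acts: list[np.ndarray] = []

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batch forward pass; output layer is linear (logits / value)."""
        self._acts = [x]
        h = x
        last = len(self.W) - 1
        for k, (w, b) in enumerate(zip(self.W, self.b)):
            h = h @ w + b
            if k != last:
                h = np.tanh(h)
            self._acts.append(h)
        return h

    def backward(self, grad_out: np.ndarray) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. params, given dL/d(output)."""
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        g = grad_out
        last = len(self.W) - 1
        for k in range(last, -1, -1):
            if k != last:
                g = g * (1.0 - self._acts[k + 1] ** 2)  # tanh'
            gW[k] = self._acts[k].T @ g
            gb[k] = g.sum(axis=0)
            g = g @ self.W[k].T
        return gW + gb


class Adam:
    """Standard Adam optimiser over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------- #
# actor-critic model                                                          #
# --------------------------------------------------------------------------- #

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class TrainingConfig:
    """Episode schedule and optimisation hyperparameters.

    Defaults reproduce the full study scale: 30 episodes of 3000 steps for 100
    agents, i.e. 9e6 individual actions.
    """

    n_agents: int = 100
    steps_per_episode: int = 3000
    n_episodes: int = 30
    gamma: float = 0.99
    learning_rate: float = 1e-3
    entropy_weight: float = 0.01
    hidden: tuple[int, int] = (64, 64)
    minibatch: int = 8192
    epochs: int = 4          # passes of minibatch updates over each episode's batch
    grad_clip: float = 1.0   # global-norm gradient clip
    ratio_clip: float = 0.2  # proximal clipping of the policy ratio across epochs
    box_side: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if self.n_agents < 2 or self.steps_per_episode < 1 or self.n_episodes < 1:
            raise ValueError("invalid episode schedule")


class ActorCritic:
    """Shared policy (actor) and state-value baseline (critic) with their optimisers."""

    def __init__(self, config: TrainingConfig = TrainingConfig(), rng=None):
        rng = np.random.default_rng(rng if rng is not None else config.seed)
        h = list(config.hidden)
        self.config = config
        self.actor = MLP([N_SECTORS, *h, N_ACTIONS], rng)
        self.critic = MLP([N_SECTORS, *h, 1], rng)
        self.opt_actor = Adam(self.actor.params, lr=config.learning_rate)
        self.opt_critic = Adam(self.critic.params, lr=config.learning_rate)

    # ---- decentralized execution -----------------------------------------
    def action_probs(self, obs: np.ndarray) -> np.ndarray:
        """Policy pi(a|o) for a batch (B, 5) or single (5,) observable."""
        obs = np.asarray(obs, dtype=float)
        if not np.all(np.isfinite(obs)):
            raise ValueError("observable must be finite")
        single = obs.ndim == 1
        probs = _softmax(self.actor.forward(np.atleast_2d(obs)))
        return probs[0] if single else probs

    def value(self, obs: np.ndarray) -> np.ndarray:
        return self.critic.forward(np.atleast_2d(obs))[:, 0]

    # ---- centralized training --------------------------------------------
    def update(
        self,
        obs: np.ndarray,
        actions: np.ndarray,
        returns: np.ndarray,
        old_logp: np.ndarray | None = None,
    ) -> dict:
        """One Adam step of actor and critic on a pooled experience minibatch.

        Advantages (return minus critic baseline) are standardised across the
        minibatch.  When ``old_logp`` (behaviour log-probabilities of the
        chosen actions) is given, the policy gradient uses the proximally
        clipped importance-ratio surrogate so the same batch can safely be
        revisited for several epochs; without it the ratio is one and the
        update is the plain advantage policy gradient.
        """
        obs = np.asarray(obs, float)
        actions = np.asarray(actions, int)
        returns = np.asarray(returns, float)
        B = obs.shape[0]
        rows = np.arange(B)

        values = self.critic.forward(obs)[:, 0]
        adv = returns - values
        adv_n = (adv - adv.mean()) / (adv.std() + 1e-8)

        logits = self.actor.forward(obs)
        probs = _softmax(logits)
        logp = np.log(probs + 1e-12)
        entropy = -(probs * logp).sum(axis=1)

        if old_logp is None:
            ratio = np.ones(B)
            active = np.ones(B, dtype=bool)
        else:
            ratio = np.exp(np.clip(logp[rows, actions] - old_logp, -20, 20))
            eps = self.config.ratio_clip
            active = np.where(adv_n >= 0, ratio < 1 + eps, ratio > 1 - eps)
        # d/dlogits of  -ratio * adv (where unclipped)  - beta * H
        w = np.where(active, ratio * adv_n, 0.0)
        grad = probs * w[:, None]
        grad[rows, actions] -= w
        grad += self.config.entropy_weight * probs * (logp + entropy[:, None])
        actor_grads = self.actor.backward(grad / B)

        self.critic.forward(obs)
        critic_grads = self.critic.backward(((values - returns) / B)[:, None])

        for grads in (actor_grads, critic_grads):
            norm = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if norm > self.config.grad_clip:
                scale = self.config.grad_clip / norm
                for g in grads:
                    g *= scale

        pg_loss = float(-(logp[np.arange(B), actions] * adv_n).mean())
        v_loss = float(0.5 * np.mean((values - returns) ** 2))
        if not (np.isfinite(pg_loss) and np.isfinite(v_loss)):
            raise FloatingPointError("training diverged: non-finite loss")
        self.opt_actor.step(actor_grads)
        self.opt_critic.step(critic_grads)
        return {"pg_loss": pg_loss, "v_loss": v_loss, "entropy": float(entropy.mean())}

    # ---- persistence ------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"actor_{k}": p for k, p in enumerate(self.actor.params)}
        arrays |= {f"critic_{k}": p for k, p in enumerate(self.critic.params)}
        cfg = asdict(self.config)
        cfg["hidden"] = list(cfg["hidden"])
        np.savez(path, __config__=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "ActorCritic":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            cfg["hidden"] = tuple(cfg["hidden"])
            model = cls(TrainingConfig(**cfg))
            for k in range(len(model.actor.params)):
                model.actor.params[k][...] = data[f"actor_{k}"]
            for k in range(len(model.critic.params)):
                model.critic.params[k][...] = data[f"critic_{k}"]
        return model


class ScriptedPolicy:
    """Deterministic or fixed-distribution policy for fixtures and baselines."""

    def __init__(self, probs):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (N_ACTIONS,) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-6:
            raise ValueError("probs must be a length-4 distribution")
        self.probs = probs

    def action_probs(self, obs: np.ndarray) -> np.ndarray:
        obs = np.atleast_2d(np.asarray(obs, float))
        return np.tile(self.probs, (obs.shape[0], 1))


def random_policy() -> ScriptedPolicy:
    """Uniform policy over the four actions (baseline for learning checks)."""
    return ScriptedPolicy(np.full(N_ACTIONS, 0.25))


# --------------------------------------------------------------------------- #
# free functions of the RL loop                                               #
# --------------------------------------------------------------------------- #

def policy_evaluate(model, obs: np.ndarray) -> np.ndarray:
    """Probability 4-vector pi(a|o) of one observable; deterministic."""
    probs = model.action_probs(np.asarray(obs, dtype=float))
    return probs[0] if probs.ndim == 2 and np.asarray(obs).ndim == 1 else probs


def sample_action(dist: np.ndarray, rng: np.random.Generator) -> int:
    """Categorical draw from a validated probability vector."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (N_ACTIONS,) or np.any(dist < -1e-12) or abs(dist.sum() - 1) > 1e-6:
        raise ValueError("invalid action distribution")
    return int(rng.choice(N_ACTIONS, p=dist / dist.sum()))


def discounted_returns(rewards: np.ndarray, gamma: float) -> np.ndarray:
    """G_t = sum_k gamma^k r_{t+k} along the first axis (remaining episode)."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    rewards = np.asarray(rewards, dtype=float)
    out = np.empty_like(rewards)
    acc = np.zeros_like(rewards[-1], dtype=float)
    for t in range(rewards.shape[0] - 1, -1, -1):
        acc = rewards[t] + gamma * acc
        out[t] = acc
    return out


# --------------------------------------------------------------------------- #
# episode runner, training, rollout                                           #
# --------------------------------------------------------------------------- #

def _run_episode(
    policy,
    n_steps: int,
    n_agents: int,
    kin: KinematicsParams,
    rew: RewardParams,
    rng: np.random.Generator,
    box_side: float = 40.0,
    occlusion: bool = True,
    half_angle: float = np.pi / 2,
    start: HerdFrame | None = None,
):
    """Run one frozen-policy episode; returns (Trajectory, obs_history).

    ``obs_history`` has shape (n_steps, N, 5): the observable each agent acted
    on at every non-final frame.
    """
    frame = start if start is not None else init_episode(n_agents, box_side, rng)
    n = frame.n_agents
    T = n_steps + 1
    pos = np.empty((T, n, 2)); head = np.empty((T, n))
    areas = np.empty((T, n)); nnd = np.empty((T, n))
    acts = np.empty((n_steps, n), dtype=int)
    obs_hist = np.empty((n_steps, n, N_SECTORS))

    def record(t, f):
        pos[t] = f.positions
        head[t] = f.headings
        dod = compute_dod(f.positions, rew.delta)
        areas[t] = np.minimum(dod.areas, rew.a_max)
        nnd[t] = dod.nn_distance

    record(0, frame)
    for t in range(n_steps):
        obs = observe_all(frame, occlusion=occlusion, half_angle=half_angle)
        obs_hist[t] = obs
        probs = policy.action_probs(obs)
        # vectorised categorical sampling, one draw per agent
        u = rng.random((n, 1))
        cs = probs.cumsum(axis=1)
        cs[:, -1] = 1.0  # guard against round-off in the last bin
        acts[t] = (cs > u).argmax(axis=1)
        frame = step(frame, acts[t], kin, rng)
        record(t + 1, frame)
    br = reward_total(areas.reshape(-1), nnd.reshape(-1), rew)
    traj = Trajectory(
        pos, head, areas, nnd,
        br.r_shh.reshape(T, n), br.r_prox.reshape(T, n), acts, delta=rew.delta,
    )
    return traj, obs_hist


@dataclass
class TrainingLog:
    """Per-episode summary statistics of a training run."""

    episode: list[int] = field(default_factory=list)
    mean_reward: list[float] = field(default_factory=list)
    median_dod: list[float] = field(default_factory=list)
    pg_loss: list[float] = field(default_factory=list)
    v_loss: list[float] = field(default_factory=list)
    entropy: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(asdict(self))


def train(
    config: TrainingConfig,
    kin: KinematicsParams | None = None,
    rew: RewardParams | None = None,
    occlusion: bool = True,
    half_angle: float = np.pi / 2,
    model: ActorCritic | None = None,
    callback=None,
) -> tuple[ActorCritic, TrainingLog]:
    """Episodic CTDE training of the shared actor.

    Each episode starts from a fresh random configuration, runs the full
    interaction loop, then trains actor and critic for one epoch of minibatch
    Adam updates on the experience pooled over all agents and steps.  The log
    records the per-episode mean total reward and median DOD.
    """
    kin = kin or KinematicsParams()
    rew = rew or RewardParams()
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = ActorCritic(config, rng=rng.integers(2**31))
    log = TrainingLog()

    for ep in range(config.n_episodes):
        traj, obs_hist = _run_episode(
            model, config.steps_per_episode, config.n_agents, kin, rew, rng,
            box_side=config.box_side, occlusion=occlusion, half_angle=half_angle,
        )
        # reward received after acting in frame t is the rating of frame t+1
        rew_seq = traj.rewards[1:]                        # (S, N)
        returns = discounted_returns(rew_seq, config.gamma)
        S, n = rew_seq.shape
        obs_flat = obs_hist.reshape(S * n, N_SECTORS)
        act_flat = traj.actions.reshape(S * n)
        ret_flat = returns.reshape(S * n)

        # behaviour log-probs of the collected actions, for ratio clipping
        beh_probs = model.action_probs(obs_flat)
        old_logp = np.log(beh_probs[np.arange(S * n), act_flat] + 1e-12)

        stats = {"pg_loss": 0.0, "v_loss": 0.0, "entropy": 0.0}
        n_batches = 0
        for _ in range(config.epochs):
            perm = rng.permutation(S * n)
            for lo in range(0, S * n, config.minibatch):
                sel = perm[lo: lo + config.minibatch]
                out = model.update(
                    obs_flat[sel], act_flat[sel], ret_flat[sel], old_logp=old_logp[sel]
                )
                for k in stats:
                    stats[k] += out[k]
                n_batches += 1
        log.episode.append(ep)
        log.mean_reward.append(float(rew_seq.mean()))
        log.median_dod.append(float(np.median(traj.areas[-1])))
        for k in stats:
            getattr(log, k).append(stats[k] / max(n_batches, 1))
        logger.info(
            "episode %d: mean reward %.4f, median DOD %.2f",
            ep, log.mean_reward[-1], log.median_dod[-1],
        )
        if callback is not None:
            callback(ep, model, log)
    return model, log


def rollout(
    policy,
    n_steps: int,
    n_agents: int = 100,
    kin: KinematicsParams | None = None,
    rew: RewardParams | None = None,
    seed: int | np.random.Generator = 0,
    box_side: float = 40.0,
    occlusion: bool = True,
    half_angle: float = np.pi / 2,
    start: HerdFrame | None = None,
) -> Trajectory:
    """Frozen-policy simulation (no learning); emits a full Trajectory."""
    rng = np.random.default_rng(seed)
    traj, _ = _run_episode(
        policy, n_steps, n_agents, kin or KinematicsParams(), rew or RewardParams(),
        rng, box_side=box_side, occlusion=occlusion, half_angle=half_angle, start=start,
    )
    return traj
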