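"""Time-stepping of the herd: action kinematics, motor noise, and collisions.

Agents are disks of diameter sigma (the length unit) on an unbounded plane.
Each time step every agent executes one of four actions — move straight
forward, turn left, turn right, or stand still.  Motile actions translate the
agent by 0.25 sigma; turns follow a circular arc of radius 0.8 sigma through
18 degrees (the chord of that arc is the actual displacement).  Actions carry
multiplicative Gaussian noise (default 20 % of the action magnitude);
standing still is noise-free.

After the synchronous kinematic update, hard-disk overlaps are resolved by
iterative symmetric projection of every overlapping pair back to contact
distance — an overdamped stand-in for a molecular-dynamics collision step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Action",
    "AgentState",
    "HerdFrame",
    "KinematicsParams",
    "InfeasibleDensityError",
    "apply_action",
    "resolve_overlaps",
    "init_episode",
    "step",
]

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


class Action(IntEnum):
    """The four actions available to an agent."""

    FORWARD = 0
    TURN_LEFT = 1
    TURN_RIGHT = 2
    STAND_STILL = 3


N_ACTIONS = 4


class InfeasibleDensityError(RuntimeError):
    """Raised when a non-overlapping random configuration cannot be sampled."""


@dataclass(frozen=True)
class KinematicsParams:
    """Kinematic constants of one action, in units of sigma and radians.

    ``step_length`` is the translation per motile action, ``turn_radius`` the
    radius of curvature of turning arcs, ``turn_angle`` the heading change per
    turn, and ``noise_sd`` the standard deviation of the multiplicative action
    noise as a fraction of the action magnitude.
    """

    step_length: float = 0.25
    turn_radius: float = 0.8
    turn_angle: float = np.deg2rad(18.0)
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if min(self.step_length, self.turn_radius, self.turn_angle) <= 0:
            raise ValueError("kinematic parameters must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        # a turn's arc length should match the straight step length
        if abs(self.turn_radius * self.turn_angle - self.step_length) > 0.01:
            raise ValueError("turn arc length inconsistent with step length")


@dataclass(frozen=True)
class AgentState:
    """Position (sigma) and heading (radians, normalised to [0, 2*pi)) of one agent."""

    position: np.ndarray
    heading: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (2,) or not np.all(np.isfinite(pos)) or not np.isfinite(self.heading):
            raise ValueError("agent state must be finite with a 2-vector position")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "heading", float(self.heading) % TWO_PI)


@dataclass
class HerdFrame:
    """State of all N agents at one time index (vectorised storage)."""

    time_index: int
    positions: np.ndarray   # (N, 2), sigma
    headings: np.ndarray    # (N,), radians in [0, 2*pi)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float) % TWO_PI
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (N, 2)")
        if self.headings.shape != (self.positions.shape[0],):
            raise ValueError("headings must be (N,)")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.headings))):
            raise ValueError("frame must be finite")

    @property
    def n_agents(self) -> int:
        return int(self.positions.shape[0])

    def agent(self, i: int) -> AgentState:
        return AgentState(self.positions[i].copy(), float(self.headings[i]))

    def copy(self) -> "HerdFrame":
        return HerdFrame(self.time_index, self.positions.copy(), self.headings.copy())


def _displacement(action: int, heading: float, params: KinematicsParams, eta1: float, eta2: float):
    """Body-frame kinematics of one action; returns (dx, dy, dheading) in world frame."""
    if action == Action.STAND_STILL:
        return 0.0, 0.0, 0.0
    c, s = np.cos(heading), np.sin(heading)
    if action == Action.FORWARD:
        ell = params.step_length * (1.0 + params.noise_sd * eta1)
        dth = params.noise_sd * params.turn_angle * eta2  # diffusive heading wobble
        return ell * c, ell * s, dth
    if action in (Action.TURN_LEFT, Action.TURN_RIGHT):
        sign = 1.0 if action == Action.TURN_LEFT else -1.0
        theta = sign * params.turn_angle * (1.0 + params.noise_sd * eta2)
        # chord of the circular arc, in the body frame then rotated to world
        bx = params.turn_radius * np.sin(abs(theta))
        by = np.copysign(params.turn_radius * (1.0 - np.cos(theta)), theta)
        return bx * c - by * s, bx * s + by * c, theta
    raise ValueError(f"unknown action id: {action!r}")


def apply_action(
    state: AgentState,
    action: Action | int,
    params: KinematicsParams | None = None,
    noise_draw: tuple[float, float] = (0.0, 0.0),
) -> AgentState:
    """Advance a single agent by one action.

    ``noise_draw`` supplies the two standard-normal variates (translation and
    rotation noise) so that callers control the randomness.
    """
    params = params or KinematicsParams()
    action = Action(action)
    dx, dy, dth = _displacement(action, state.heading, params, *noise_draw)
    return AgentState(state.position + np.array([dx, dy]), state.heading + dth)


def resolve_overlaps(
    frame: HerdFrame,
    overlap_tol: float = 1e-6,
    max_iter: int = 100,
) -> HerdFrame:
    """Project overlapping disk pairs back to contact distance sigma = 1.

    Each sweep pushes every pair with centre distance < 1 apart symmetrically
    along the centre line to distance exactly 1 (corrections from multiple
    pairs accumulate per agent before being applied, so symmetric
    configurations stay symmetric).  Sweeps repeat until no residual overlap
    exceeds ``overlap_tol`` or ``max_iter`` is reached, in which case a
    warning is logged and the best-effort frame returned.
    """
    pos = frame.positions.copy()
    n = pos.shape[0]
    if n < 2:
        return frame.copy()
    for _ in range(max_iter):
        pairs = cKDTree(pos).query_pairs(1.0 - overlap_tol, output_type="ndarray")
        if len(pairs) == 0:
            return HerdFrame(frame.time_index, pos, frame.headings.copy())
        i, j = pairs[:, 0], pairs[:, 1]
        sep = pos[j] - pos[i]
        dist = np.linalg.norm(sep, axis=1)
        # coincident centres: split along an arbitrary fixed direction
        bad = dist < 1e-12
        if bad.any():
            sep[bad] = np.array([1.0, 0.0])
            dist[bad] = 1.0
        push = 0.5 * (1.0 - dist)[:, None] * sep / dist[:, None]
        corr = np.zeros_like(pos)
        np.add.at(corr, j, push)
        np.add.at(corr, i, -push)
        pos += corr
    logger.warning("overlap resolution did not converge in %d sweeps", max_iter)
    warnings.warn("overlap resolution did not fully converge", RuntimeWarning, stacklevel=2)
    return HerdFrame(frame.time_index, pos, frame.headings.copy())


def init_episode(
    n_agents: int,
    box_side: float = 40.0,
    rng: np.random.Generator | int | None = None,
    max_rejections: int = 100_000,
) -> HerdFrame:
    """Random non-overlapping start: positions uniform in a square, headings uniform.

    Positions are rejection-sampled to pairwise distance >= 1 sigma.  Fully
    deterministic for a given seed/generator.
    """
    if n_agents < 2:
        raise ValueError("need at least 2 agents")
    if box_side**2 * 0.3 < n_agents * np.pi / 4:
        raise InfeasibleDensityError("requested packing fraction exceeds 0.3")
    rng = np.random.default_rng(rng)
    placed = np.empty((n_agents, 2))
    count = 0
    rejections = 0
    while count < n_agents:
        cand = rng.uniform(0.0, box_side, size=2)
        if count == 0 or np.min(np.linalg.norm(placed[:count] - cand, axis=1)) >= 1.0:
            placed[count] = cand
            count += 1
        else:
            rejections += 1
            if rejections > max_rejections:
                raise InfeasibleDensityError(
                    f"could not place {n_agents} agents after {max_rejections} rejections"
                )
    headings = rng.uniform(0.0, TWO_PI, size=n_agents)
    return HerdFrame(0, placed, headings)


def step(
    frame: HerdFrame,
    actions: np.ndarray,
    params: KinematicsParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> HerdFrame:
    """Synchronous update: kinematics for all agents, then one overlap resolution.

    ``rng`` supplies the per-agent noise; pass None for deterministic zero-noise
    motion (useful for scripted fixtures).
    """
    params = params or KinematicsParams()
    actions = np.asarray(actions, dtype=int)
    n = frame.n_agents
    if actions.shape != (n,):
        raise ValueError("one action per agent required")
    if np.any((actions < 0) | (actions >= N_ACTIONS)):
        raise ValueError("invalid action id in actions array")
    if rng is None:
        noise = np.zeros((n, 2))
    else:
        noise = np.random.default_rng(rng).standard_normal((n, 2))

    new_pos = frame.positions.copy()
    new_head = frame.headings.copy()
    for a in (Action.FORWARD, Action.TURN_LEFT, Action.TURN_RIGHT):
        idx = np.flatnonzero(actions == a)
        if idx.size == 0:
            continue
        th = frame.headings[idx]
        c, s = np.cos(th), np.sin(th)
        if a == Action.FORWARD:
            ell = params.step_length * (1.0 + params.noise_sd * noise[idx, 0])
            new_pos[idx, 0] += ell * c
            new_pos[idx, 1] += ell * s
            new_head[idx] += params.noise_sd * params.turn_angle * noise[idx, 1]
        else:
            sign = 1.0 if a == Action.TURN_LEFT else -1.0
            theta = sign * params.turn_angle * (1.0 + params.noise_sd * noise[idx, 1])
            bx = params.turn_radius * np.sin(np.abs(theta))
            by = np.copysign(params.turn_radius * (1.0 - np.cos(theta)), theta)
            new_pos[idx, 0] += bx * c - by * s
            new_pos[idx, 1] += bx * s + by * c
            new_head[idx] += theta
    out = HerdFrame(frame.time_index + 1, new_pos, new_head)
    return resolve_overlaps(out)
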