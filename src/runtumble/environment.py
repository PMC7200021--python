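"""Continuous 2-D run-and-tumble chemotaxis world.

The environment models a bacterium-like agent on an unbounded plane with a
single chemical source. The chemical field is radially symmetric and strictly
decreasing with distance from the source, so the *sign* of the spatial
gradient along the agent's heading reduces to a facing test: the gradient is
positive iff the heading points (strictly) towards the source. Only this sign
is ever observed, as a binary observation.

Two actions are available: *run* advances the agent one unit along its
current heading; *tumble* leaves the position unchanged and redraws the
heading uniformly on [0, 2pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "Observation",
    "Action",
    "WorldState",
    "reset",
    "observe",
    "apply_action",
    "distance_to_source",
]

#: forward displacement of a single run step, in length units
STEP_LENGTH = 1.0
#: standard initial distance from the chemical source, in length units
START_DISTANCE = 400.0


class Observation(IntEnum):
    """Binary observation: sign of the local spatial chemical gradient."""

    POS = 0
    NEG = 1

    def onehot(self, n_obs: int = 2) -> np.ndarray:
        v = np.zeros(n_obs)
        v[int(self)] = 1.0
        return v


class Action(IntEnum):
    """The two motor primitives of run-and-tumble locomotion."""

    RUN = 0
    TUMBLE = 1


@dataclass
class WorldState:
    """Hidden ground truth of the environment.

    Attributes
    ----------
    position : ndarray, shape (2,)
        Agent position, in arbitrary length units.
    heading : float
        Agent orientation in radians, normalized to [0, 2pi).
    source : ndarray, shape (2,)
        Position of the chemical source; constant within an episode.
    """

    position: np.ndarray
    heading: float
    source: np.ndarray

    def copy(self) -> "WorldState":
        return replace(self, position=self.position.copy(), source=self.source.copy())


def _wrap_angle(theta: float) -> float:
    return theta % (2.0 * math.pi)


def reset(
    rng: np.random.Generator | int,
    start_distance: float = START_DISTANCE,
    source: np.ndarray | None = None,
) -> WorldState:
    """Place the agent at ``start_distance`` from the source.

    The placement angle and the initial heading are both drawn uniformly on
    [0, 2pi). ``rng`` may be an integer seed or a ``numpy.random.Generator``;
    the same seed yields an identical world state.
    """
    if start_distance <= 0:
        raise ValueError(f"start_distance must be positive, got {start_distance}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    src = np.zeros(2) if source is None else np.asarray(source, dtype=float)
    placement = rng.uniform(0.0, 2.0 * math.pi)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    position = src + start_distance * np.array([math.cos(placement), math.sin(placement)])
    return WorldState(position=position, heading=_wrap_angle(heading), source=src)


def observe(state: WorldState) -> Observation:
    """Sign of the spatial chemical gradient along the current heading.

    Returns :attr:`Observation.POS` iff the heading unit vector has a
    strictly positive dot product with the vector from agent to source.
    A zero dot product (heading exactly tangential, or the agent sitting
    exactly on the source) returns NEG by convention.
    """
    to_source = state.source - state.position
    dot = math.cos(state.heading) * to_source[0] + math.sin(state.heading) * to_source[1]
    return Observation.POS if dot > 0.0 else Observation.NEG


def apply_action(state: WorldState, action: Action, rng: np.random.Generator) -> WorldState:
    """Execute one action in place and return the updated state.

    Run: advance ``STEP_LENGTH`` along the heading, heading unchanged.
    Tumble: position unchanged, heading redrawn uniformly on [0, 2pi).
    """
    if action == Action.RUN:
        state.position[0] += STEP_LENGTH * math.cos(state.heading)
        state.position[1] += STEP_LENGTH * math.sin(state.heading)
    else:
        state.heading = _wrap_angle(rng.uniform(0.0, 2.0 * math.pi))
    return state


def distance_to_source(state: WorldState) -> float:
    """Euclidean distance from the agent to the chemical source."""
    return float(np.hypot(*(state.position - state.source)))
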