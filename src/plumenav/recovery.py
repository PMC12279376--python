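"""Void-state policies: what the agent does when its memory holds no odor.

Turbulent plumes are full of holes, so the void state occurs both inside
and outside the plume and the greedy Q-policy is ill-defined there.  A
separate *recovery strategy* takes over while the agent is in the void:

* ``brownian`` — uniformly random actions.
* ``backtracking`` — retrace the actions played since the last
  detection, in reverse with each action inverted; once the action
  memory is exhausted, fall back to random actions.
* ``circling`` — repeat an action for 1, 2, 3, ... steps, rotating
  through downwind, crosswind-right, upwind, crosswind-left, which
  traces an outward spiral around the point of plume loss.
* ``cast_surge`` — crosswind runs of doubling length (1, 2, 4, ...),
  with a single upwind step and a reversal of cast direction between
  consecutive runs.
* ``learned`` — no hard-wired rule: the void state is split into
  sub-states labeled by the time since entering the void (clamped at
  50), and actions there are learned by the same Q-table as the sensed
  states.  This module only supplies the sub-state index.

All strategies are pure given their internal state and are reset when
the agent receives a detection.
"""

from __future__ import annotations

import random

from .field import Action, INVERSE_ACTION, N_ACTIONS

__all__ = [
    "RecoveryPolicy",
    "BrownianRecovery",
    "BacktrackingRecovery",
    "CirclingRecovery",
    "CastSurgeRecovery",
    "LearnedRecovery",
    "make_recovery",
    "RECOVERY_NAMES",
]

#: Circling rotation order: e1 -> e2 -> -e1 -> -e2 -> e1 (flow frame).
_CIRCLE_ORDER = {
    Action.DOWNWIND: Action.CROSSWIND_RIGHT,
    Action.CROSSWIND_RIGHT: Action.UPWIND,
    Action.UPWIND: Action.CROSSWIND_LEFT,
    Action.CROSSWIND_LEFT: Action.DOWNWIND,
}

RECOVERY_NAMES = ("brownian", "backtracking", "circling", "cast_surge", "learned")


class RecoveryPolicy:
    """Interface shared by the void-state policies."""

    #: True when void actions come from the Q-table (learned recovery).
    uses_qtable = False
    #: True when void actions involve random draws.
    stochastic = False

    def reset(self) -> None:
        """Forget all recovery state (episode start)."""

    def on_detection(self) -> None:
        """Observation above threshold: re-arm the strategy."""

    def record_action(self, action: int) -> None:
        """Inform the strategy of a Q-policy action followed by a blank."""

    def step(self, rng: random.Random) -> int:
        raise NotImplementedError


class BrownianRecovery(RecoveryPolicy):
    """Uniformly random action on every void step."""

    stochastic = True

    def step(self, rng: random.Random) -> int:
        return rng.randrange(N_ACTIONS)


class BacktrackingRecovery(RecoveryPolicy):
    """Retrace the blank-step actions since the last detection.

    The action memory has fixed capacity (set equal to the sensing
    memory); when full, the oldest actions are retained and new ones
    dropped, so an over-long excursion is only partially unwound.  With
    an empty memory a random action is played.
    """

    stochastic = True  # random fallback once the memory is exhausted

    def __init__(self, capacity: int) -> None:
        if capacity < 1:
            raise ValueError("action-memory capacity must be >= 1")
        self.capacity = capacity
        self._stack: list[int] = []

    def reset(self) -> None:
        self._stack.clear()

    def on_detection(self) -> None:
        self._stack.clear()

    def record_action(self, action: int) -> None:
        if len(self._stack) < self.capacity:
            self._stack.append(action)

    @property
    def stored(self) -> list[int]:
        return list(self._stack)

    def step(self, rng: random.Random) -> int:
        if self._stack:
            return INVERSE_ACTION[self._stack.pop()]
        return rng.randrange(N_ACTIONS)


class CirclingRecovery(RecoveryPolicy):
    """Outward spiral: run lengths 1, 2, 3, ... through the 4 directions."""

    def __init__(self) -> None:
        self.reset()

    def reset(self) -> None:
        self.t_void = 0
        self.t_change = 1
        self.a_void = int(Action.DOWNWIND)  # e1

    on_detection = reset

    def step(self, rng: random.Random) -> int:
        action = self.a_void
        self.t_void += 1
        if self.t_void == self.t_change:
            self.t_void = 0
            self.t_change += 1
            self.a_void = int(_CIRCLE_ORDER[self.a_void])
        return action


class CastSurgeRecovery(RecoveryPolicy):
    """Crosswind casts of doubling width with one upwind step between.

    The upwind step replaces the next tick's crosswind action, keeping
    one action per decision.
    """

    def __init__(self) -> None:
        self.reset()

    def reset(self) -> None:
        self.t_void = 0
        self.t_change = 1
        self.a_void = int(Action.CROSSWIND_RIGHT)  # e2
        self._surge_pending = False

    on_detection = reset

    def step(self, rng: random.Random) -> int:
        if self._surge_pending:
            self._surge_pending = False
            return int(Action.UPWIND)
        action = self.a_void
        self.t_void += 1
        if self.t_void == self.t_change:
            self._surge_pending = True
            self.t_change *= 2
            self.a_void = int(INVERSE_ACTION[self.a_void])
            self.t_void = 0
        return action


class LearnedRecovery(RecoveryPolicy):
    """Void sub-states indexed by time since entering the void.

    Action selection is delegated to the Q-table; this class only tracks
    the void counter and maps it to a sub-state in ``1..n_substates``
    (clamped: longer bouts share the last sub-state).
    """

    uses_qtable = True

    def __init__(self, n_substates: int = 50) -> None:
        if n_substates < 1:
            raise ValueError("need at least one void sub-state")
        self.n_substates = n_substates
        self.counter = 0

    def reset(self) -> None:
        self.counter = 0

    on_detection = reset

    def substate(self) -> int:
        """Advance the void counter and return the sub-state in 1..n."""
        self.counter += 1
        return min(self.counter, self.n_substates)

    def step(self, rng: random.Random) -> int:  # pragma: no cover - guarded upstream
        raise RuntimeError("learned recovery selects actions through the Q-table")


def make_recovery(
    name: str, memory: int = 20, n_substates: int = 50
) -> RecoveryPolicy:
    """Build a recovery strategy by config name."""
    if name == "brownian":
        return BrownianRecovery()
    if name == "backtracking":
        return BacktrackingRecovery(capacity=memory)
    if name == "circling":
        return CirclingRecovery()
    if name == "cast_surge":
        return CastSurgeRecovery()
    if name == "learned":
        return LearnedRecovery(n_substates=n_substates)
    raise ValueError(f"unknown recovery strategy {name!r}; expected one of {RECOVERY_NAMES}")
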