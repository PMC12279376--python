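"""Tabular episodic Q-learning for olfactory navigation.

The agent's table maps (olfactory state, action) to an estimate of the
expected discounted return.  The state space is the 15 sensed states,
plus either a single void row (heuristic recoveries; never used for
action selection but kept so that transitions into the void bootstrap a
learned value) or 50 void sub-states (learned recovery, where void
actions are selected greedily from the table like any other state).

Per decision the agent receives a penalty ``-sigma`` away from the
source and ``+1`` on entering the source region, discounted by
``gamma``; exploration and learning rates decay exponentially across
episodes:

    epsilon_k = eta_init  * exp(-eta_decay  * k)
    alpha_k   = alpha_init * exp(-alpha_decay * k)

Defaults reproduce the published training protocol (100,000 episodes,
horizon 5000, gamma 0.9999, sigma 0.001, Q initialized at 0.6).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import (
    EnvironmentSpec,
    GridPosition,
    N_ACTIONS,
    OdorField,
    admissible_starts,
    in_source_region,
    move,
    observe,
)
from .recovery import RecoveryPolicy, make_recovery
from .states import N_SENSED_STATES, VOID, OlfactoryStateMachine

__all__ = [
    "TrainConfig",
    "QTable",
    "EpisodeTranscript",
    "TrainingLog",
    "epsilon_k",
    "alpha_k",
    "select_action",
    "td_update",
    "run_episode",
    "train",
    "derive_seed",
]


def derive_seed(base: int, stream: int) -> int:
    """Deterministically fan one config seed out to component streams."""
    ss = np.random.SeedSequence(entropy=base, spawn_key=(stream,))
    return int(ss.generate_state(1)[0] % (2**31))


def epsilon_k(k: int, eta_init: float = 0.99, eta_decay: float = 1e-4) -> float:
    """Exploration probability at episode ``k``: eta_init * exp(-eta_decay k)."""
    return eta_init * math.exp(-eta_decay * k)


def alpha_k(k: int, alpha_init: float = 0.25, alpha_decay: float = 1e-3) -> float:
    """Learning rate at episode ``k``: alpha_init * exp(-alpha_decay k)."""
    return alpha_init * math.exp(-alpha_decay * k)


@dataclass
class TrainConfig:
    """Hyperparameters of the training protocol (published defaults)."""

    n_episodes: int = 100_000
    horizon: int = 5000
    gamma: float = 0.9999
    sigma: float = 0.001
    success_reward: float = 1.0
    eta_init: float = 0.99
    eta_decay: float = 1e-4
    alpha_init: float = 0.25
    alpha_decay: float = 1e-3
    q_init: float = 0.6
    start_set: str = "admissible"  # or "valid"
    log_every: int = 500
    fixed_tiebreak: bool = False
    #: With a heuristic recovery, also update the single void row using the
    #: action the recovery played (the row is never used for selection,
    #: only as the bootstrap value of entering the void).  When False the
    #: void row stays at ``q_init``, a fixed pessimistic prior for being
    #: lost; useful on static plumes where the void's aliased value is
    #: meaningless.  Ignored by the learned recovery, whose void
    #: sub-states are always learned.
    update_void_row: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0.0 <= self.eta_init <= 1.0:
            raise ValueError("eta_init must lie in [0, 1]")
        if self.alpha_init <= 0.0:
            raise ValueError("alpha_init must be positive")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


class QTable:
    """Dense (state, action) value table over the olfactory states.

    Rows 0..14 are the sensed states; with a heuristic recovery row 15 is
    the single void state, with the learned recovery rows 15..15+n-1 are
    the void sub-states (time since entering the void).
    """

    def __init__(self, n_void_states: int = 1, init_value: float = 0.6) -> None:
        self.n_void_states = n_void_states
        self.init_value = init_value
        self.n_states = N_SENSED_STATES + n_void_states
        self.values: list[list[float]] = [
            [init_value] * N_ACTIONS for _ in range(self.n_states)
        ]

    def void_row(self, substate: int = 1) -> int:
        """Q-table row index of a void (sub-)state, ``substate`` in 1..n."""
        return N_SENSED_STATES + min(substate, self.n_void_states) - 1

    def state_labels(self) -> list[str]:
        """Human-readable row labels (a single void row is just 'void')."""
        from .states import state_label

        labels = [state_label(s) for s in range(N_SENSED_STATES)]
        if self.n_void_states == 1:
            labels.append("void")
        else:
            labels.extend(f"void+{k}" for k in range(1, self.n_void_states + 1))
        return labels

    def greedy_action(self, state: int) -> int:
        row = self.values[state]
        return row.index(max(row))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)

    def copy(self) -> "QTable":
        out = QTable(self.n_void_states, self.init_value)
        out.values = [row[:] for row in self.values]
        return out


def select_action(
    q: QTable,
    state: int,
    epsilon: float,
    rng: random.Random,
    fixed_tiebreak: bool = False,
) -> int:
    """Epsilon-greedy action; argmax ties broken uniformly at random."""
    if epsilon > 0.0 and rng.random() < epsilon:
        return rng.randrange(N_ACTIONS)
    row = q.values[state]
    best = max(row)
    if fixed_tiebreak:
        return row.index(best)
    ties = [a for a in range(N_ACTIONS) if row[a] == best]
    if len(ties) == 1:
        return ties[0]
    return ties[rng.randrange(len(ties))]


def td_update(
    q: QTable,
    state: int,
    action: int,
    reward: float,
    next_state: int | None,
    alpha: float,
    gamma: float,
) -> None:
    """One temporal-difference backup, in place.

    ``next_state`` is a Q-table row index, or None for a terminal
    transition (the bootstrap term is zero).
    """
    bootstrap = 0.0 if next_state is None else max(q.values[next_state])
    row = q.values[state]
    row[action] = (1.0 - alpha) * row[action] + alpha * (reward + gamma * bootstrap)


@dataclass
class EpisodeTranscript:
    """Outcome of one episode (optionally with per-step logs)."""

    start: GridPosition
    start_frame: int
    length: int
    success: bool
    n_void: int
    states: list[int] | None = None  # Q-row index or VOID marker, per step
    actions: list[int] | None = None
    positions: list[GridPosition] | None = None

    @property
    def censored(self) -> bool:
        return not self.success


def run_episode(
    field: OdorField,
    spec: EnvironmentSpec,
    machine: OlfactoryStateMachine,
    recovery: RecoveryPolicy,
    q: QTable,
    config: TrainConfig,
    start: GridPosition,
    start_frame: int,
    rng: random.Random,
    epsilon: float = 0.0,
    alpha: float = 0.0,
    learn: bool = False,
    collect: bool = False,
) -> EpisodeTranscript:
    """Play (and optionally learn from) one episode.

    The sensing buffer is pre-filled with the observations at the start
    cell over the frames preceding ``start_frame``; the intensity history
    starts from that window's average intensity.  The frame index then
    advances by one per decision.  The episode ends on entering the
    source region (reward ``+1``) or after ``config.horizon`` decisions;
    every other decision costs ``-sigma``, also outside the grid.
    """
    speed = spec.speed
    sigma = config.sigma
    gamma = config.gamma
    learned = recovery.uses_qtable
    m0 = machine.buffer_capacity
    machine.initialize(
        observe(field, start, start_frame - m0 + 1 + j) for j in range(m0)
    )
    recovery.reset()

    pos = start
    t = start_frame
    state = machine.state
    n_void = 1 if state == VOID else 0
    log_states = [] if collect else None
    log_actions = [] if collect else None
    log_positions = [pos] if collect else None

    if in_source_region(pos, spec):
        # Already at the target: the simulator relays the reward at once.
        return EpisodeTranscript(start, start_frame, 0, True, 0,
                                 log_states, log_actions, log_positions)

    length = 0
    success = False
    for _ in range(config.horizon):
        # -- select the action for the current state
        if state != VOID:
            q_state = state
            action = select_action(q, state, epsilon, rng, config.fixed_tiebreak)
            from_policy = True
        elif learned:
            q_state = q.void_row(recovery.substate())
            action = select_action(q, q_state, epsilon, rng, config.fixed_tiebreak)
            from_policy = True
        else:
            q_state = q.void_row()
            action = recovery.step(rng)
            from_policy = False

        # -- act, observe, collect reward
        pos = move(pos, action, speed)
        t += 1
        length += 1
        z = observe(field, pos, t)
        terminal = in_source_region(pos, spec)
        reward = config.success_reward if terminal else -sigma
        next_state = machine.update(z)

        # -- recovery bookkeeping keyed on detection vs blank
        if z > machine.s_thr:
            recovery.on_detection()
        elif from_policy and state != VOID:
            recovery.record_action(action)

        if collect:
            log_states.append(q_state if (state != VOID or learned) else VOID)
            log_actions.append(action)
            log_positions.append(pos)

        # -- learning backup at every time step; with a heuristic recovery
        # the void row is (optionally) updated too, with the action the
        # recovery chose, so entering the void bootstraps a learned value
        if learn and (from_policy or config.update_void_row):
            if terminal:
                boot: int | None = None
            elif next_state != VOID:
                boot = next_state
            elif learned:
                boot = q.void_row(min(recovery.counter + 1, recovery.n_substates))
            else:
                boot = q.void_row()
            td_update(q, q_state, action, reward, boot, alpha, gamma)

        if terminal:
            success = True
            break
        if next_state == VOID and state != VOID:
            n_void += 1
        state = next_state

    return EpisodeTranscript(start, start_frame, length, success, n_void,
                             log_states, log_actions, log_positions)


@dataclass
class TrainingLog:
    """Per-block (``log_every`` episodes) rolling averages of performance."""

    episode: list[int] = dc_field(default_factory=list)
    mean_return: list[float] = dc_field(default_factory=list)
    success_rate: list[float] = dc_field(default_factory=list)
    mean_gplus: list[float] = dc_field(default_factory=list)
    mean_ratio: list[float] = dc_field(default_factory=list)
    mean_n_void: list[float] = dc_field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "episode": self.episode,
            "mean_return": self.mean_return,
            "success_rate": self.success_rate,
            "mean_gplus": self.mean_gplus,
            "mean_ratio": self.mean_ratio,
            "mean_n_void": self.mean_n_void,
        })


def train(
    field: OdorField,
    spec: EnvironmentSpec,
    config: TrainConfig | None = None,
    memory: int = 20,
    adaptive_memory: bool = False,
    recovery: str | RecoveryPolicy = "backtracking",
    seed: int = 0,
    machine_kwargs: dict | None = None,
    starts: list[GridPosition] | None = None,
) -> tuple[QTable, TrainingLog]:
    """Run the full training protocol; returns the table and its curves.

    ``starts`` overrides the start set (default: all admissible cells).
    Episodes draw a uniform start cell and a uniform start frame in
    ``[|M_0|, n_frames)`` so the pre-start sensing window can be filled
    from real frames.
    """
    from .evaluation import discounted_return, shortest_path_time

    config = config or TrainConfig()
    machine = OlfactoryStateMachine(
        memory=memory,
        n_thr=spec.noise_level,
        adaptive=adaptive_memory,
        **(machine_kwargs or {}),
    )
    if isinstance(recovery, str):
        recovery = make_recovery(recovery, memory=machine.buffer_capacity)
    q = QTable(
        n_void_states=recovery.n_substates if recovery.uses_qtable else 1,
        init_value=config.q_init,
    )
    if starts is None:
        if config.start_set == "valid":
            from .field import valid_starts

            starts = valid_starts(field, spec, t0=machine.buffer_capacity,
                                  memory=machine.default_memory,
                                  c_thr=machine.c_thr, n_thr=machine.n_thr)
        else:
            starts = admissible_starts(field, spec)
    if not starts:
        raise ValueError("empty start set: no admissible locations in the field")

    rng = random.Random(derive_seed(seed, 0))
    m0 = machine.buffer_capacity
    hi = max(field.n_frames, m0 + 1)
    log = TrainingLog()
    block: list[tuple[int, bool, int, int]] = []  # (tau, success, tau_min, n_void)
    spt_cache: dict[GridPosition, int] = {}

    for k in range(config.n_episodes):
        start = starts[rng.randrange(len(starts))]
        t0 = rng.randrange(m0, hi)
        tr = run_episode(
            field, spec, machine, recovery, q, config,
            start=start, start_frame=t0, rng=rng,
            epsilon=epsilon_k(k, config.eta_init, config.eta_decay),
            alpha=alpha_k(k, config.alpha_init, config.alpha_decay),
            learn=True,
        )
        if start not in spt_cache:
            spt_cache[start] = shortest_path_time(start, spec)
        block.append((tr.length, tr.success, spt_cache[start], tr.n_void))
        if (k + 1) % config.log_every == 0 or k + 1 == config.n_episodes:
            n = len(block)
            returns = [
                discounted_return(tau, ok, config) for tau, ok, _, _ in block
            ]
            succ = [b for b in block if b[1]]
            lam = -math.log(config.gamma)
            log.episode.append(k + 1)
            log.mean_return.append(sum(returns) / n)
            log.success_rate.append(len(succ) / n)
            log.mean_gplus.append(
                sum(math.exp(-lam * tau) for tau, _, _, _ in succ) / len(succ)
                if succ else float("nan")
            )
            log.mean_ratio.append(
                sum((tmin / tau if ok and tau > 0 else tmin / config.horizon)
                    for tau, ok, tmin, _ in block) / n
            )
            log.mean_n_void.append(sum(b[3] for b in block) / n)
            block = []

    return q, log
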