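"""Policy evaluation: trajectories from every start and the four metrics.

A trained policy is scored by running greedy (epsilon = 0) test
trajectories from every start position and summarizing them with

* ``G`` — expected discounted return.  With ``lambda = -ln(gamma)`` and
  arrival time ``tau``, a successful trajectory contributes
  ``exp(-lambda tau) - sigma (1 - exp(-lambda tau)) / (1 - gamma)``; a
  censored one contributes ``G- = -sigma (1 - exp(-lambda H)) / (1 - gamma)``.
* ``f+`` — fraction of trajectories that reach the source region.
* ``g+`` — ``<exp(-lambda tau) | success>``, a discounted speed.
* ``tau_min / tau`` — realized time relative to the shortest possible
  path, 1 for an ideal agent, with failures contributing
  ``tau_min / H``.

The exact decomposition ``G = f+ G+ + (1 - f+) G-`` with
``G+ = g+ - sigma (1 - g+) / (1 - gamma)`` holds on every pooled
trajectory set.  Statistics are computed per start position first, then
averaged (with their spread) across starts.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np

from .field import (
    EnvironmentSpec,
    GridPosition,
    N_ACTIONS,
    OdorField,
    admissible_starts,
    in_source_region,
    valid_starts,
)
from .qlearning import (
    QTable,
    TrainConfig,
    derive_seed,
    run_episode,
    train,
)
from .recovery import RecoveryPolicy, make_recovery
from .states import N_SENSED_STATES, OlfactoryStateMachine

__all__ = [
    "TrajectoryResult",
    "MetricsSummary",
    "OccupancyStats",
    "shortest_path_time",
    "discounted_return",
    "test_policy",
    "metric_G",
    "metric_fplus",
    "metric_gplus",
    "metric_ratio",
    "summarize",
    "occupancy_stats",
    "memory_sweep",
]


def shortest_path_time(start: GridPosition, spec: EnvironmentSpec) -> int | float:
    """Minimum number of speed-sized axis steps from ``start`` to the source region.

    Moves are unconstrained axis steps, so the optimum is the minimal
    Manhattan distance over the cells of the source disc reachable on the
    agent's step lattice (coordinates congruent to the start modulo the
    speed), divided by the speed.  Returns ``math.inf`` when no source
    cell lies on the lattice.
    """
    if in_source_region(start, spec):
        return 0
    v = spec.speed
    sx, sy = spec.source_pos
    r = spec.source_radius
    x0, y0 = start
    best: float = math.inf
    for px in range(math.ceil(sx - r), math.floor(sx + r) + 1):
        if (px - x0) % v:
            continue
        half = math.sqrt(max(0.0, r * r - (px - sx) ** 2))
        for py in range(math.ceil(sy - half), math.floor(sy + half) + 1):
            if (py - y0) % v:
                continue
            steps = (abs(px - x0) + abs(py - y0)) // v
            if steps < best:
                best = steps
    return int(best) if math.isfinite(best) else math.inf


def discounted_return(tau: int, success: bool, config: TrainConfig) -> float:
    """Closed-form discounted return of a trajectory of duration ``tau``.

    Convention: the step penalty is paid on each of the ``tau`` decisions
    and the success reward arrives discounted by ``gamma**tau``; censored
    trajectories pay the penalty over the full horizon and never collect
    the reward.
    """
    gamma, sigma = config.gamma, config.sigma
    if not success:
        tau = config.horizon
    decay = gamma**tau
    penalty = sigma * (1.0 - decay) / (1.0 - gamma)
    return (config.success_reward * decay - penalty) if success else -penalty


@dataclass
class TrajectoryResult:
    """Outcome of one greedy test trajectory."""

    start: GridPosition
    tau: int
    success: bool
    n_void: int
    tau_min: int | float
    states: list[int] | None = None
    actions: list[int] | None = None
    positions: list[GridPosition] | None = None


def test_policy(
    field: OdorField,
    spec: EnvironmentSpec,
    q: QTable,
    recovery: str | RecoveryPolicy = "backtracking",
    memory: int = 20,
    adaptive_memory: bool = False,
    n_reps: int = 10,
    seed: int = 0,
    config: TrainConfig | None = None,
    starts: list[GridPosition] | str = "admissible",
    start_frame: int | None = None,
    collect: bool = False,
    machine_kwargs: dict | None = None,
) -> list[TrajectoryResult]:
    """Run ``n_reps`` greedy trajectories from each start position.

    ``starts`` may be an explicit list, ``"admissible"`` (any cell with
    at least one non-zero observation) or ``"valid"`` (first observation
    above the sensitivity threshold).  The start frame defaults to the
    buffer length so the pre-start window is filled from real frames.
    No learning updates are applied.
    """
    config = config or TrainConfig()
    machine = OlfactoryStateMachine(
        memory=memory,
        n_thr=spec.noise_level,
        adaptive=adaptive_memory,
        **(machine_kwargs or {}),
    )
    if isinstance(recovery, str):
        recovery = make_recovery(recovery, memory=machine.buffer_capacity)
    t0 = machine.buffer_capacity if start_frame is None else start_frame
    if isinstance(starts, str):
        if starts == "valid":
            starts = valid_starts(field, spec, t0, machine.default_memory,
                                  machine.c_thr, machine.n_thr)
        elif starts == "admissible":
            starts = admissible_starts(field, spec)
        else:
            raise ValueError(f"unknown start set {starts!r}")
    rng = random.Random(derive_seed(seed, 1))
    spt_cache: dict[GridPosition, int | float] = {}
    results: list[TrajectoryResult] = []
    for start in starts:
        if start not in spt_cache:
            spt_cache[start] = shortest_path_time(start, spec)
        for _ in range(n_reps):
            tr = run_episode(
                field, spec, machine, recovery, q, config,
                start=start, start_frame=t0, rng=rng,
                epsilon=0.0, learn=False, collect=collect,
            )
            results.append(TrajectoryResult(
                start=start, tau=tr.length, success=tr.success,
                n_void=tr.n_void, tau_min=spt_cache[start],
                states=tr.states, actions=tr.actions, positions=tr.positions,
            ))
    return results


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _traj_G(r: TrajectoryResult, config: TrainConfig) -> float:
    return discounted_return(r.tau, r.success, config)


def metric_G(results: list[TrajectoryResult], config: TrainConfig) -> float:
    """Mean discounted return over all trajectories."""
    if not results:
        raise ValueError("no trajectories")
    return sum(_traj_G(r, config) for r in results) / len(results)


def metric_fplus(results: list[TrajectoryResult]) -> float:
    """Fraction of successful trajectories."""
    if not results:
        raise ValueError("no trajectories")
    return sum(r.success for r in results) / len(results)


def metric_gplus(results: list[TrajectoryResult], config: TrainConfig) -> float:
    """``<exp(-lambda tau) | success>``; NaN if there is no success."""
    lam = -math.log(config.gamma)
    succ = [r for r in results if r.success]
    if not succ:
        return float("nan")
    return sum(math.exp(-lam * r.tau) for r in succ) / len(succ)


def metric_ratio(results: list[TrajectoryResult], config: TrainConfig) -> float:
    """Mean ``tau_min / tau`` (failures contribute ``tau_min / horizon``)."""
    if not results:
        raise ValueError("no trajectories")
    total = 0.0
    for r in results:
        tau = r.tau if (r.success and r.tau > 0) else config.horizon
        total += 0.0 if tau == 0 else r.tau_min / tau
    return total / len(results)


@dataclass
class MetricsSummary:
    """Four performance measures, pooled and per-start."""

    G: float
    f_plus: float
    g_plus: float
    ratio: float
    G_plus: float
    G_minus: float
    lam: float
    mean_n_void: float
    n_starts: int
    n_trajectories: int
    per_start: "object" = None  # pandas DataFrame
    sd_G: float = float("nan")
    sd_f_plus: float = float("nan")
    sd_g_plus: float = float("nan")
    sd_ratio: float = float("nan")

    def to_dict(self) -> dict[str, float]:
        return {
            "G": self.G, "f_plus": self.f_plus, "g_plus": self.g_plus,
            "ratio": self.ratio, "mean_n_void": self.mean_n_void,
        }


def summarize(
    results: list[TrajectoryResult], config: TrainConfig | None = None
) -> MetricsSummary:
    """Per-start means/SDs plus pooled metrics and the G decomposition."""
    import pandas as pd

    config = config or TrainConfig()
    if not results:
        raise ValueError("no trajectories to summarize")
    lam = -math.log(config.gamma)
    gamma, sigma = config.gamma, config.sigma
    g_minus = -sigma * (1.0 - math.exp(-lam * config.horizon)) / (1.0 - gamma)

    by_start: dict[GridPosition, list[TrajectoryResult]] = {}
    for r in results:
        by_start.setdefault(r.start, []).append(r)
    rows = []
    for start, rs in by_start.items():
        succ = [r for r in rs if r.success]
        rows.append({
            "x": start[0], "y": start[1],
            "G": metric_G(rs, config),
            "f_plus": metric_fplus(rs),
            "g_plus": metric_gplus(rs, config),
            "ratio": metric_ratio(rs, config),
            "tau_min": rs[0].tau_min,
            "mean_tau": (sum(r.tau for r in succ) / len(succ)) if succ else float("nan"),
            "mean_n_void": sum(r.n_void for r in rs) / len(rs),
        })
    per_start = pd.DataFrame(rows)

    g_plus_pooled = metric_gplus(results, config)
    f_plus_pooled = metric_fplus(results)
    G_plus = (
        g_plus_pooled - sigma * (1.0 - g_plus_pooled) / (1.0 - gamma)
        if not math.isnan(g_plus_pooled) else float("nan")
    )
    return MetricsSummary(
        G=float(per_start["G"].mean()),
        f_plus=float(per_start["f_plus"].mean()),
        g_plus=float(per_start["g_plus"].mean(skipna=True)),
        ratio=float(per_start["ratio"].mean()),
        G_plus=G_plus,
        G_minus=g_minus,
        lam=lam,
        mean_n_void=float(per_start["mean_n_void"].mean()),
        n_starts=len(by_start),
        n_trajectories=len(results),
        per_start=per_start,
        sd_G=float(per_start["G"].std(ddof=0)),
        sd_f_plus=float(per_start["f_plus"].std(ddof=0)),
        sd_g_plus=float(per_start["g_plus"].std(ddof=0)),
        sd_ratio=float(per_start["ratio"].std(ddof=0)),
    )


# ---------------------------------------------------------------------------
# Occupancy and spatial statistics
# ---------------------------------------------------------------------------


@dataclass
class OccupancyStats:
    """State-visit frequencies and spatial void-probability maps."""

    occupancy: dict[str, float]            # 15 sensed labels + "void"
    action_histogram: np.ndarray           # (16, 4), rows sum to occupancy share
    visit_map: np.ndarray                  # (nx, ny) visit counts
    void_map: np.ndarray                   # (nx, ny) P(void | visited cell)
    nonvoid_map: np.ndarray                # (nx, ny) P(non-void | visited cell)


def occupancy_stats(
    results: list[TrajectoryResult], grid_shape: tuple[int, int]
) -> OccupancyStats:
    """Count olfactory-state visits over all steps of all trajectories.

    Void sub-states (learned recovery) are pooled into a single void
    share.  The spatial maps give, per grid cell, the probability that an
    agent stepping on that cell is in the void state.
    """
    from .states import state_label

    nx, ny = grid_shape
    visits = np.zeros((nx, ny), dtype=np.int64)
    void_visits = np.zeros((nx, ny), dtype=np.int64)
    state_counts = np.zeros(N_SENSED_STATES + 1, dtype=np.int64)  # [.., void]
    action_counts = np.zeros((N_SENSED_STATES + 1, N_ACTIONS), dtype=np.int64)
    for r in results:
        if r.states is None:
            raise ValueError("occupancy needs trajectories collected with collect=True")
        for s, a, pos in zip(r.states, r.actions, r.positions):
            idx = s if 0 <= s < N_SENSED_STATES else N_SENSED_STATES
            state_counts[idx] += 1
            action_counts[idx, a] += 1
            x, y = pos
            if 0 <= x < nx and 0 <= y < ny:
                visits[x, y] += 1
                if idx == N_SENSED_STATES:
                    void_visits[x, y] += 1
    total = state_counts.sum()
    if total == 0:
        raise ValueError("no steps recorded")
    occ = {
        state_label(s): state_counts[s] / total for s in range(N_SENSED_STATES)
    }
    occ["void"] = state_counts[N_SENSED_STATES] / total
    with np.errstate(invalid="ignore", divide="ignore"):
        void_map = np.where(visits > 0, void_visits / np.maximum(visits, 1), np.nan)
    nonvoid_map = np.where(visits > 0, 1.0 - void_map, np.nan)
    return OccupancyStats(
        occupancy=occ,
        action_histogram=action_counts / total,
        visit_map=visits,
        void_map=void_map,
        nonvoid_map=nonvoid_map,
    )


# ---------------------------------------------------------------------------
# Memory sweep
# ---------------------------------------------------------------------------


def memory_sweep(
    field: OdorField,
    spec: EnvironmentSpec,
    memories: list[int],
    config: TrainConfig | None = None,
    recovery: str = "backtracking",
    n_reps: int = 10,
    seed: int = 0,
    starts: list[GridPosition] | str = "admissible",
    include_adaptive: bool = False,
    machine_kwargs: dict | None = None,
) -> dict[object, MetricsSummary]:
    """Train and test one agent per sensing memory ``T`` (shared seeds).

    Returns a mapping ``T -> MetricsSummary``; with ``include_adaptive``
    an extra entry keyed ``"adaptive"`` is added.
    """
    config = config or TrainConfig()
    out: dict[object, MetricsSummary] = {}
    modes: list[tuple[object, int, bool]] = [(T, T, False) for T in memories]
    if include_adaptive:
        modes.append(("adaptive", memories[0] if memories else 20, True))
    for key, memory, adaptive in modes:
        q, _ = train(
            field, spec, config, memory=memory, adaptive_memory=adaptive,
            recovery=recovery, seed=seed, machine_kwargs=machine_kwargs,
            starts=None if isinstance(starts, str) else starts,
        )
        results = test_policy(
            field, spec, q, recovery=recovery, memory=memory,
            adaptive_memory=adaptive, n_reps=n_reps, seed=seed,
            config=config, starts=starts, machine_kwargs=machine_kwargs,
        )
        out[key] = summarize(results, config)
    return out
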