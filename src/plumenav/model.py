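"""Model / results objects tying training and evaluation together.

:class:`PlumeNavigator` is built from an odor field plus an environment
spec and holds the behavioural configuration (sensing memory, recovery
strategy, training hyperparameters).  Its :meth:`~PlumeNavigator.fit`
runs the episodic Q-learning protocol and returns a
:class:`PlumeNavigatorResults` carrying the learned Q-table, the
training curves and a ``summary()`` table; ``evaluate()`` on the results
runs greedy test trajectories and returns an :class:`EvaluationResults`
with the four performance metrics, their per-start spread, and
occupancy statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .field import Action, EnvironmentSpec, OdorField
from .evaluation import (
    MetricsSummary,
    OccupancyStats,
    TrajectoryResult,
    occupancy_stats,
    summarize,
    test_policy,
)
from .qlearning import QTable, TrainConfig, TrainingLog, train
from .recovery import RECOVERY_NAMES

__all__ = ["PlumeNavigator", "PlumeNavigatorResults", "EvaluationResults"]

_ACTION_NAMES = {
    Action.UPWIND: "upwind",
    Action.DOWNWIND: "downwind",
    Action.CROSSWIND_LEFT: "crosswind_left",
    Action.CROSSWIND_RIGHT: "crosswind_right",
}


class PlumeNavigator:
    """An olfactory-search agent to be trained on a snapshot stack.

    Parameters
    ----------
    field : OdorField
        Time-resolved concentration stack, noise floor already applied.
    spec : EnvironmentSpec
        Gridworld geometry (source, speed, horizon, noise level).
    memory : int
        Sensing memory ``T`` (or the adaptive default).
    adaptive_memory : bool
        Track the most recent completed blank instead of a fixed ``T``.
    recovery : str
        One of ``brownian, backtracking, circling, cast_surge, learned``.
    config : TrainConfig, optional
        Training hyperparameters (published defaults when omitted).
    machine_kwargs : dict, optional
        Extra feature-extraction options (percentiles, intermittency
        cuts, ``single_state`` ablation, ``buffer_capacity``).
    """

    def __init__(
        self,
        field: OdorField,
        spec: EnvironmentSpec,
        memory: int = 20,
        adaptive_memory: bool = False,
        recovery: str = "backtracking",
        config: TrainConfig | None = None,
        machine_kwargs: dict | None = None,
    ) -> None:
        if recovery not in RECOVERY_NAMES:
            raise ValueError(
                f"unknown recovery {recovery!r}; expected one of {RECOVERY_NAMES}"
            )
        self.field = field
        self.spec = spec
        self.memory = memory
        self.adaptive_memory = adaptive_memory
        self.recovery = recovery
        self.config = config or TrainConfig()
        self.machine_kwargs = dict(machine_kwargs or {})

    @classmethod
    def from_synthetic(
        cls,
        params=None,
        spec: EnvironmentSpec | None = None,
        **kwargs,
    ) -> "PlumeNavigator":
        """Build a navigator on a generated puff plume.

        The environment spec defaults to the generator's geometry (source
        position and noise level) with speed 1, which suits the compact
        synthetic grids.
        """
        from .synthetic import PuffPlumeParams, generate

        params = params or PuffPlumeParams()
        field = generate(params)
        if spec is None:
            spec = EnvironmentSpec(
                source_pos=params.source_pos,
                source_radius=3.0,
                noise_level=params.noise_level,
                speed=1,
                horizon=kwargs.pop("horizon", 500),
            )
        return cls(field, spec, **kwargs)

    def fit(self, seed: int = 0, n_episodes: int | None = None) -> "PlumeNavigatorResults":
        """Run the episodic training protocol and return the results."""
        config = self.config
        if n_episodes is not None:
            config = replace(config, n_episodes=n_episodes)
        if config.horizon != self.spec.horizon:
            config = replace(config, horizon=self.spec.horizon)
        qtable, log = train(
            self.field,
            self.spec,
            config,
            memory=self.memory,
            adaptive_memory=self.adaptive_memory,
            recovery=self.recovery,
            seed=seed,
            machine_kwargs=self.machine_kwargs,
        )
        return PlumeNavigatorResults(self, qtable, log, seed, config)


@dataclass
class PlumeNavigatorResults:
    """A fitted navigation policy with its training history."""

    model: PlumeNavigator
    qtable: QTable
    training_log: TrainingLog
    seed: int
    config: TrainConfig

    @property
    def params(self) -> np.ndarray:
        """The Q-table as a (n_states, 4) array (the fitted parameters)."""
        return self.qtable.as_array()

    def policy(self) -> dict[str, str]:
        """Greedy action per olfactory state, by label."""
        return {
            label: _ACTION_NAMES[Action(self.qtable.greedy_action(s))]
            for s, label in enumerate(self.qtable.state_labels())
        }

    def evaluate(
        self,
        n_reps: int = 10,
        seed: int | None = None,
        starts="valid",
        collect: bool = False,
        start_frame: int | None = None,
    ) -> "EvaluationResults":
        """Greedy test trajectories from every start; no learning updates."""
        m = self.model
        results = test_policy(
            m.field,
            m.spec,
            self.qtable,
            recovery=m.recovery,
            memory=m.memory,
            adaptive_memory=m.adaptive_memory,
            n_reps=n_reps,
            seed=self.seed if seed is None else seed,
            config=self.config,
            starts=starts,
            start_frame=start_frame,
            collect=collect,
            machine_kwargs=m.machine_kwargs,
        )
        return EvaluationResults(self, results, summarize(results, self.config))

    def summary(self) -> str:
        """Plain-text overview: configuration, training tail, greedy policy."""
        m = self.model
        lines = [
            "Plume navigation Q-learning results",
            "=" * 51,
            f"grid {m.field.grid_shape}, {m.field.n_frames} frames | "
            f"source {m.spec.source_pos} r={m.spec.source_radius:g}",
            f"memory T={'adaptive' if m.adaptive_memory else m.memory} | "
            f"recovery {m.recovery} | seed {self.seed}",
            f"episodes {self.config.n_episodes} | horizon {self.config.horizon} | "
            f"gamma {self.config.gamma} | sigma {self.config.sigma}",
        ]
        if self.training_log.episode:
            lines.append(
                f"final training block: return {self.training_log.mean_return[-1]:.4f}, "
                f"success {self.training_log.success_rate[-1]:.2%}"
            )
        lines.append("-" * 51)
        lines.append("greedy policy (state: action)")
        pol = self.policy()
        for label, action in pol.items():
            lines.append(f"  {label:>8s}: {action}")
        return "\n".join(lines)


@dataclass
class EvaluationResults:
    """Greedy test trajectories and their metric summary."""

    results_for: PlumeNavigatorResults
    trajectories: list[TrajectoryResult]
    metrics: MetricsSummary

    def occupancy(self) -> OccupancyStats:
        """State occupancy and spatial void maps (needs ``collect=True``)."""
        return occupancy_stats(
            self.trajectories, self.results_for.model.field.grid_shape
        )

    def summary(self) -> str:
        s = self.metrics
        return "\n".join([
            "Greedy policy evaluation",
            "=" * 44,
            f"starts {s.n_starts} | trajectories {s.n_trajectories}",
            f"G       {s.G: .4f}  (sd across starts {s.sd_G:.4f})",
            f"f+      {s.f_plus: .4f}  (sd {s.sd_f_plus:.4f})",
            f"g+      {s.g_plus: .4f}  (sd {s.sd_g_plus:.4f})",
            f"tmin/t  {s.ratio: .4f}  (sd {s.sd_ratio:.4f})",
            f"<N_void> {s.mean_n_void: .3f}",
        ])
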