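"""Shared fixtures: generated plumes and trained agents (no stored data)."""

from __future__ import annotations

import numpy as np
import pytest

import plumenav as pn


def make_cone_field(nx: int = 50, ny: int = 20) -> pn.OdorField:
    """Static blank-free cone: concentration halves every 10 cells downwind,
    support half-width min(3, 0.5*(x-2)) around the centerline y=10."""
    frame = np.zeros((nx, ny))
    for x in range(2, nx):
        w = min(3.0, 0.5 * (x - 2))
        band = min((x - 2) // 10, 4)
        for y in range(ny):
            if abs(y - 10) <= w:
                frame[x, y] = 2.0 ** (-band)
    return pn.OdorField(frame[None, :, :])


CONE_SPEC = dict(source_pos=(5, 10), source_radius=5.0, noise_level=1e-8,
                 speed=1, horizon=400)
#: Fixed intensity bin edges separating the cone's five concentration plateaus.
CONE_BIN_EDGES = (0.09, 0.18, 0.35, 0.7)


@pytest.fixture(scope="session")
def cone_env():
    return make_cone_field(), pn.EnvironmentSpec(**CONE_SPEC)


@pytest.fixture(scope="session")
def default_plume():
    """The package-default synthetic puff plume and its environment."""
    params = pn.PuffPlumeParams()
    field = pn.generate(params)
    spec = pn.EnvironmentSpec(
        source_pos=params.source_pos, source_radius=3.0,
        noise_level=params.noise_level, speed=1, horizon=1000,
    )
    return params, field, spec


@pytest.fixture(scope="session")
def trained_cone_agent(cone_env):
    """A converged agent on the static cone (shared across tests)."""
    field, spec = cone_env
    config = pn.TrainConfig(
        n_episodes=6000, horizon=400, gamma=0.995,
        eta_decay=7e-4, alpha_decay=5e-4, log_every=1000,
        update_void_row=False,
    )
    machine_kwargs = dict(intensity_bin_edges=CONE_BIN_EDGES)
    q, log = pn.train(field, spec, config, memory=2, recovery="backtracking",
                      seed=2, machine_kwargs=machine_kwargs)
    return q, log, config, machine_kwargs


SWEEP_MEMORIES = (1, 2, 4, 8, 16, 32)
SWEEP_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def memory_sweep_results(default_plume):
    """Seed-averaged optimal-memory sweep plus an adaptive-memory agent.

    2000-episode trainings per memory (decay constants scaled to the episode
    count), greedy tests from a fixed random sample of 250 admissible starts
    with 2 repetitions, averaged over 3 training seeds.
    """
    import random

    _, field, spec = default_plume
    config = pn.TrainConfig(n_episodes=2000, horizon=1000,
                            eta_decay=2.5e-3, alpha_decay=2e-3, log_every=2000)
    starts = random.Random(7).sample(pn.admissible_starts(field, spec), 250)
    out: dict[object, dict[str, float]] = {}
    for key, memory, adaptive in (
        [(T, T, False) for T in SWEEP_MEMORIES] + [("adaptive", 8, True)]
    ):
        G, n_void, f_plus = [], [], []
        for seed in SWEEP_SEEDS:
            q, _ = pn.train(field, spec, config, memory=memory,
                            adaptive_memory=adaptive, recovery="backtracking",
                            seed=seed)
            res = pn.test_policy(field, spec, q, recovery="backtracking",
                                 memory=memory, adaptive_memory=adaptive,
                                 n_reps=2, seed=seed, config=config,
                                 starts=starts)
            summary = pn.summarize(res, config)
            G.append(summary.G)
            n_void.append(summary.mean_n_void)
            f_plus.append(summary.f_plus)
        out[key] = {
            "G": float(np.mean(G)), "G_seeds": G,
            "n_void": float(np.mean(n_void)),
            "f_plus": float(np.mean(f_plus)),
        }
    return out
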