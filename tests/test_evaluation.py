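"""Shortest paths, the four performance metrics, occupancy and sweeps."""

import math
import random
from collections import deque

import pytest

import plumenav as pn
from plumenav.evaluation import TrajectoryResult, discounted_return
from plumenav.qlearning import TrainConfig


def bfs_steps(start, spec, bound=80):
    """Brute-force breadth-first search over the speed-step lattice."""
    if pn.in_source_region(start, spec):
        return 0
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        pos, d = queue.popleft()
        for action in range(4):
            nxt = pn.move(pos, action, spec.speed)
            if nxt in seen or abs(nxt[0]) > bound or abs(nxt[1]) > bound:
                continue
            if pn.in_source_region(nxt, spec):
                return d + 1
            seen.add(nxt)
            queue.append((nxt, d + 1))
    return math.inf


class TestShortestPathTime:
    def test_straight_downwind_divisible(self):
        spec = pn.EnvironmentSpec(source_pos=(10, 20), source_radius=5,
                                  speed=10)
        # 30 cells downwind of the region edge: (45,20) -> edge at (15,20)
        assert pn.shortest_path_time((45, 20), spec) == 3

    def test_one_step_away(self):
        spec = pn.EnvironmentSpec(source_pos=(10, 20), source_radius=5, speed=1)
        assert pn.shortest_path_time((16, 20), spec) == 1

    def test_inside_region_is_zero(self):
        spec = pn.EnvironmentSpec(source_pos=(10, 20), source_radius=5, speed=1)
        assert pn.shortest_path_time((12, 21), spec) == 0

    @pytest.mark.parametrize("speed", [1, 2, 3])
    def test_matches_bfs_enumeration(self, speed):
        spec = pn.EnvironmentSpec(source_pos=(8, 9), source_radius=3.0,
                                  speed=speed)
        rng = random.Random(0)
        for _ in range(40):
            start = (rng.randrange(0, 25), rng.randrange(0, 25))
            assert pn.shortest_path_time(start, spec) == bfs_steps(start, spec)


def random_results(seed, n_starts=12, n_reps=4, horizon=5000):
    """Arbitrary synthetic trajectory sets for metric identity checks."""
    rng = random.Random(seed)
    results = []
    for i in range(n_starts):
        start = (rng.randrange(100), rng.randrange(100))
        tau_min = rng.randrange(1, 60)
        for _ in range(n_reps):
            success = rng.random() < 0.8
            tau = rng.randrange(tau_min, horizon) if success else horizon
            results.append(TrajectoryResult(
                start=start, tau=tau, success=success,
                n_void=rng.randrange(10), tau_min=tau_min))
    return results


class TestMetricG:
    def test_tau_zero_contributes_one(self):
        config = TrainConfig()
        r = TrajectoryResult(start=(0, 0), tau=0, success=True, n_void=0,
                             tau_min=0)
        assert pn.metric_G([r], config) == pytest.approx(1.0)

    def test_closed_form_without_penalty(self):
        config = TrainConfig(sigma=0.0)
        lam = -math.log(config.gamma)
        rs = [TrajectoryResult((0, 0), 100, True, 0, 50) for _ in range(3)]
        assert pn.metric_G(rs, config) == pytest.approx(math.exp(-lam * 100))

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_literal_discounted_reward_sum(self, seed):
        """G equals the step-by-step discounted sum of the reward stream."""
        config = TrainConfig()
        gamma, sigma = config.gamma, config.sigma
        for r in random_results(seed, n_starts=4, n_reps=2, horizon=800):
            tau = r.tau if r.success else config.horizon
            # literal stream: -sigma on each of tau steps, +1 on success
            total = 0.0
            for t in range(tau):
                total += (gamma**t) * (-sigma)
            if r.success:
                total += gamma**tau * 1.0
            assert discounted_return(r.tau, r.success, config) == \
                pytest.approx(total, abs=1e-10)


class TestMetricIdentities:
    @pytest.mark.parametrize("seed", range(8))
    def test_decomposition_exact(self, seed):
        """G = f+ G+ + (1 - f+) G- to 1e-10 on arbitrary result sets."""
        config = TrainConfig()
        results = random_results(seed)
        summary = pn.summarize(results, config)
        assert summary.G == pytest.approx(
            summary.f_plus * summary.G_plus
            + (1 - summary.f_plus) * summary.G_minus,
            abs=1e-10,
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_bounds(self, seed):
        # successes faster than ~900 steps keep G+ positive at the
        # published gamma/sigma (G+ = g+ - sigma (1-g+)/(1-gamma))
        config = TrainConfig(horizon=600)
        results = random_results(seed, horizon=600)
        s = pn.summarize(results, config)
        assert 0.0 <= s.f_plus <= 1.0
        assert 0.0 <= s.g_plus <= 1.0
        assert 0.0 <= s.ratio <= 1.0
        assert s.G <= 1.0
        assert s.G_minus < 0.0 < s.G_plus

    def test_all_success_fplus_one(self):
        config = TrainConfig()
        rs = [TrajectoryResult((0, 0), 10, True, 0, 10) for _ in range(5)]
        assert pn.metric_fplus(rs) == 1.0
        assert pn.metric_ratio(rs, config) == pytest.approx(1.0)

    def test_gplus_undefined_without_success_is_flagged(self):
        config = TrainConfig()
        rs = [TrajectoryResult((0, 0), config.horizon, False, 0, 10)]
        assert math.isnan(pn.metric_gplus(rs, config))

    def test_failures_use_horizon_conventions(self):
        config = TrainConfig(horizon=100)
        rs = [TrajectoryResult((0, 0), 100, False, 0, 20)]
        lam = -math.log(config.gamma)
        g_minus = -config.sigma * (1 - math.exp(-lam * 100)) / (1 - config.gamma)
        assert pn.metric_G(rs, config) == pytest.approx(g_minus)
        assert pn.metric_ratio(rs, config) == pytest.approx(20 / 100)


class TestTestPolicy:
    def test_result_count_bookkeeping(self, cone_env, trained_cone_agent):
        field, spec = cone_env
        q, _, config, mk = trained_cone_agent
        starts = pn.admissible_starts(field, spec)[:7]
        res = pn.test_policy(field, spec, q, recovery="backtracking",
                             memory=2, n_reps=3, seed=0, config=config,
                             starts=starts, machine_kwargs=mk)
        assert len(res) == 7 * 3

    def test_deterministic_strategy_repeats_identically(self, cone_env,
                                                        trained_cone_agent):
        """With no random components, the n_reps trajectories coincide."""
        field, spec = cone_env
        q, _, config, mk = trained_cone_agent
        starts = pn.admissible_starts(field, spec)[:10]
        res = pn.test_policy(field, spec, q, recovery="circling", memory=2,
                             n_reps=3, seed=5, config=config, starts=starts,
                             machine_kwargs=mk, collect=True)
        by_start = {}
        for r in res:
            by_start.setdefault(r.start, []).append(r)
        for rs in by_start.values():
            assert len({r.tau for r in rs}) == 1
            assert all(r.positions == rs[0].positions for r in rs)


class TestOccupancy:
    def test_frequencies_match_counting_oracle(self, cone_env,
                                               trained_cone_agent):
        field, spec = cone_env
        q, _, config, mk = trained_cone_agent
        starts = pn.admissible_starts(field, spec)[::9]
        res = pn.test_policy(field, spec, q, recovery="backtracking",
                             memory=2, n_reps=1, seed=1, config=config,
                             starts=starts, machine_kwargs=mk, collect=True)
        occ = pn.occupancy_stats(res, field.grid_shape)
        total_steps = sum(r.tau for r in res)
        assert sum(occ.occupancy.values()) == pytest.approx(1.0)
        # brute-force recount of one state's share
        flat = [s for r in res for s in r.states]
        for code in {s for s in flat if 0 <= s < 15}:
            share = sum(1 for s in flat if s == code) / len(flat)
            assert occ.occupancy[pn.state_label(code)] == pytest.approx(share)
        assert occ.action_histogram.sum() == pytest.approx(1.0)
        assert occ.visit_map.sum() <= total_steps + len(res)

    def test_all_void_trajectory(self):
        r = TrajectoryResult((0, 0), 3, False, 1, 5,
                             states=[-1, -1, -1], actions=[0, 1, 2],
                             positions=[(0, 0), (0, 1), (0, 2), (0, 3)])
        occ = pn.occupancy_stats([r], (5, 5))
        assert occ.occupancy["void"] == 1.0

    def test_requires_collected_logs(self):
        r = TrajectoryResult((0, 0), 3, False, 1, 5)
        with pytest.raises(ValueError, match="collect"):
            pn.occupancy_stats([r], (5, 5))


class TestMemorySweep:
    def test_single_memory_reduces_to_train_plus_test(self, cone_env):
        field, spec = cone_env
        config = TrainConfig(n_episodes=100, horizon=60, eta_decay=0.02,
                             alpha_decay=0.01, log_every=100)
        starts = pn.admissible_starts(field, spec)[:12]
        out = pn.memory_sweep(field, spec, [3], config=config,
                              recovery="backtracking", n_reps=2, seed=4,
                              starts=starts)
        assert list(out.keys()) == [3]
        q, _ = pn.train(field, spec, config, memory=3,
                        recovery="backtracking", seed=4)
        res = pn.test_policy(field, spec, q, recovery="backtracking",
                             memory=3, n_reps=2, seed=4, config=config,
                             starts=starts)
        direct = pn.summarize(res, config)
        assert out[3].G == pytest.approx(direct.G)
        assert out[3].mean_n_void == pytest.approx(direct.mean_n_void)
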