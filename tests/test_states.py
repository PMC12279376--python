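"""Olfactory features, discretization and the online state machine."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from plumenav.states import (
    VOID,
    OlfactoryStateMachine,
    discretize_intensity,
    discretize_intermittency,
    features,
    filtered_memory,
    nearest_rank_percentile,
    sensitivity_threshold,
    state_label,
)

concentrations = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)


class TestSensitivityThreshold:
    def test_noise_floor_dominates_for_zero_window(self):
        assert sensitivity_threshold([0.0] * 4, 0.5, 3e-6) == 3e-6

    def test_single_observation_scaled_by_c_thr(self):
        assert sensitivity_threshold([2e-3], 0.5, 0.0) == pytest.approx(1e-3)

    def test_window_mean_scaling(self):
        assert sensitivity_threshold([1, 1, 1, 1], 0.5, 0.0) == pytest.approx(0.5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_threshold([], 0.5, 0.0)


class TestFilteredMemory:
    def test_keeps_order_and_strict_threshold(self):
        assert filtered_memory([0, 0.4, 0.1, 0.9], 0.3) == [0.4, 0.9]
        assert filtered_memory([0.1, 0.2], 0.3) == []
        assert filtered_memory([0.3], 0.3) == []  # strictly greater

    @given(st.lists(concentrations, min_size=1, max_size=30),
           st.floats(min_value=0, max_value=5, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_brute_force_oracle(self, window, thr):
        out = filtered_memory(window, thr)
        assert out == [z for z in window if z > thr]
        assert all(z > thr for z in out)


class TestFeatures:
    def test_all_blank_window(self):
        assert features([0, 0, 0, 0], 0.1) == (0.0, 0.0)

    def test_conditional_mean_and_fraction(self):
        c, i = features([0, 0.4, 0.1, 0.9], 0.3)
        assert c == pytest.approx(0.65)
        assert i == pytest.approx(0.5)

    def test_intermittency_bound_attained(self):
        _, i = features([1.0, 2.0], 0.5)
        assert i == 1.0

    @given(st.lists(concentrations, min_size=1, max_size=30),
           st.floats(min_value=0, max_value=5, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_bounds(self, window, thr):
        c, i = features(window, thr)
        assert 0.0 <= i <= 1.0
        assert c >= 0.0
        assert (i == 0.0) == (c == 0.0)


class TestDiscretizeIntermittency:
    @pytest.mark.parametrize("i,expected", [
        (0.2, 0), (0.33, 0), (0.34, 1), (0.66, 1), (0.67, 2), (0.9, 2),
        (0.0, 0), (1.0, 2),
    ])
    def test_bin_edges(self, i, expected):
        assert discretize_intermittency(i) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            discretize_intermittency(1.5)


class TestDiscretizeIntensity:
    def test_nearest_rank_on_1_to_100(self):
        X = list(range(1, 101))
        # nearest-rank percentiles of 1..100 are exactly 25, 50, 80, 99
        assert nearest_rank_percentile(X, 25) == 25
        assert nearest_rank_percentile(X, 99) == 99
        assert discretize_intensity(60, X) == 2
        assert discretize_intensity(25, X) == 0
        assert discretize_intensity(99.5, X) == 4

    def test_extremes(self):
        X = [1.0, 2.0, 3.0]
        assert discretize_intensity(0.5, X) == 0
        assert discretize_intensity(10.0, X) == 4

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            discretize_intensity(1.0, [])

    @given(st.lists(concentrations, min_size=1, max_size=50), concentrations)
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_c_for_fixed_history(self, history, c):
        X = sorted(history)
        assert discretize_intensity(c, X) <= discretize_intensity(c + 0.5, X)


def brute_force_state(buffer, history_sorted, c_thr, n_thr):
    """Independent step-by-step re-implementation of the state rule."""
    T = len(buffer)
    s_thr = max(c_thr * sum(buffer) / T, n_thr)
    above = [z for z in buffer if z > s_thr]
    if not above:
        return VOID
    c = sum(above) / len(above)
    i = len(above) / T
    i_bin = 0 if i <= 0.33 else (1 if i <= 0.66 else 2)
    c_bin = 4
    for b, q in enumerate((25, 50, 80, 99)):
        n = len(history_sorted)
        rank = max(1, math.ceil(q / 100 * n))
        if c <= history_sorted[rank - 1]:
            c_bin = b
            break
    return i_bin * 5 + c_bin


class TestStateMachine:
    def test_scripted_sequence_matches_independent_replay(self):
        rng = random.Random(42)
        machine = OlfactoryStateMachine(memory=4, n_thr=1e-3)
        z0 = [rng.random() for _ in range(4)]
        machine.initialize(z0)
        buf = list(z0)
        # independent oracle state, including the X bookkeeping
        T = 4
        s_thr = max(0.5 * sum(buf) / T, 1e-3)
        above = [z for z in buf if z > s_thr]
        X = sorted([sum(above) / len(above) if above else 0.0])
        for step in range(30):
            z = rng.random() if rng.random() > 0.4 else 0.0
            got = machine.update(z)
            buf = (buf + [z])[-4:]
            s_thr = max(0.5 * sum(buf) / 4, 1e-3)
            above = [v for v in buf if v > s_thr]
            c = sum(above) / len(above) if above else 0.0
            X = sorted(X + [c])
            assert got == brute_force_state(buf, X, 0.5, 1e-3), f"step {step}"

    def test_void_after_detections_leave_window(self):
        machine = OlfactoryStateMachine(memory=3, n_thr=1e-6)
        machine.initialize([1.0, 1.0, 1.0])
        assert machine.state != VOID
        states = [machine.update(0.0) for _ in range(5)]
        assert states[-1] == VOID
        assert machine.i == 0.0

    def test_constant_signal_saturates_intermittency(self):
        machine = OlfactoryStateMachine(memory=5, n_thr=1e-6)
        machine.initialize([0.5] * 5)
        for _ in range(10):
            state = machine.update(0.5)
        assert machine.i == 1.0
        assert state // 5 == 2  # top intermittency bin
        # stationary under a constant noise-free signal
        assert machine.update(0.5) == state

    def test_void_iff_filtered_empty_iff_zero_intermittency(self):
        rng = random.Random(1)
        machine = OlfactoryStateMachine(memory=4, n_thr=1e-3)
        machine.initialize([rng.random() for _ in range(4)])
        for _ in range(200):
            state = machine.update(rng.random() if rng.random() > 0.5 else 0.0)
            above = [z for z in machine.window if z > machine.s_thr]
            assert (state == VOID) == (len(above) == 0) == (machine.i == 0.0)

    def test_online_binning_with_frozen_history_equals_offline(self):
        # once X is frozen, the online rule is plain offline binning on X
        rng = random.Random(9)
        X = sorted(rng.random() for _ in range(57))
        for c in [rng.random() for _ in range(100)]:
            online = discretize_intensity(c, X)
            offline = 4
            for b, q in enumerate((25, 50, 80, 99)):
                if c <= X[max(1, math.ceil(q / 100 * 57)) - 1]:
                    offline = b
                    break
            assert online == offline

    def test_global_bin_edges_mode(self):
        machine = OlfactoryStateMachine(
            memory=1, n_thr=1e-6, intensity_bin_edges=(0.1, 0.2, 0.4, 0.8))
        machine.initialize([0.3])
        assert machine.state % 5 == 2
        machine.update(0.05)
        assert machine.state % 5 == 0
        machine.update(0.9)
        assert machine.state % 5 == 4

    def test_single_state_ablation(self):
        machine = OlfactoryStateMachine(memory=2, n_thr=1e-6, single_state=True)
        machine.initialize([1.0, 1.0])
        assert machine.state == 0
        machine.update(0.0)
        machine.update(0.0)
        assert machine.state == VOID


class TestAdaptiveMemory:
    def test_tracks_last_completed_blank(self):
        machine = OlfactoryStateMachine(memory=6, n_thr=1e-6, adaptive=True,
                                        buffer_capacity=10)
        machine.initialize([1.0] * 6)
        assert machine.T == 6  # no blank yet -> default
        for _ in range(3):
            machine.update(0.0)  # 3-step blank
        machine.update(1.0)  # detection completes the blank
        assert machine.last_blank == 3
        machine.update(1.0)
        assert machine.T == 3

    def test_clamped_at_buffer_capacity(self):
        machine = OlfactoryStateMachine(memory=4, n_thr=1e-6, adaptive=True,
                                        buffer_capacity=5)
        machine.initialize([1.0] * 4)
        for _ in range(200):
            machine.update(0.0)
        machine.update(1.0)
        assert machine.last_blank == 200
        assert machine.adaptive_memory() == 5

    def test_no_blank_yet_returns_default(self):
        machine = OlfactoryStateMachine(memory=7, adaptive=True)
        machine.initialize([1.0] * 3)
        assert machine.adaptive_memory() == 7


def test_state_labels():
    assert state_label(VOID) == "void"
    assert state_label(0) == "i0c0"
    assert state_label(14) == "i2c4"
    assert state_label(15) == "void+1"
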