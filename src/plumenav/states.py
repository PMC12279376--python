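"""Temporal odor features and discrete olfactory states.

An agent carries a rolling window ``M`` of its last ``T`` odor
observations (the *sensing memory*).  From the window it computes an
adaptive sensitivity threshold

    s_thr = max( C_thr / T * sum(M), n_thr ),

keeps only the observations strictly above it (the *filtered memory*),
and summarizes them by two features:

* average intensity ``c`` — mean of the above-threshold observations
  (0 if there are none), and
* intermittency ``i`` — their fraction of the window, in [0, 1].

Intermittency is cut at 0.33 / 0.66 into 3 bins; intensity is cut at the
25 / 50 / 80 / 99th percentiles of the intensities collected so far along
the agent's own path (dataset ``X``), into 5 bins, giving 15 sensed
states.  A window with no above-threshold observation is the *void*
state.  Percentiles are nearest-rank, so the online binning is exact on
small histories.

Adaptive memory sets ``T`` equal to the duration of the most recent
completed blank (a maximal run of observations at or below threshold),
clamped to a buffer capacity ``T_b``; until a blank has completed the
default memory is used.
"""

from __future__ import annotations

import math
from bisect import insort

__all__ = [
    "VOID",
    "N_SENSED_STATES",
    "state_code",
    "state_label",
    "sensitivity_threshold",
    "filtered_memory",
    "features",
    "discretize_intermittency",
    "discretize_intensity",
    "nearest_rank_percentile",
    "OlfactoryStateMachine",
]

#: Number of sensed (non-void) olfactory states: 3 intermittency x 5 intensity.
N_SENSED_STATES = 15

#: Code for the void state (no above-threshold detection in the window).
VOID = -1

_I_CUTS = (0.33, 0.66)
_C_PERCENTILES = (25.0, 50.0, 80.0, 99.0)


def state_code(i_bin: int, c_bin: int) -> int:
    """Pack (intermittency bin, intensity bin) into a code in 0..14."""
    return i_bin * 5 + c_bin


def state_label(code: int) -> str:
    if code == VOID:
        return "void"
    if 0 <= code < N_SENSED_STATES:
        return f"i{code // 5}c{code % 5}"
    return f"void+{code - N_SENSED_STATES + 1}"  # void sub-state (time since entry)


def sensitivity_threshold(window, c_thr: float, n_thr: float) -> float:
    """``max(c_thr * mean(window), n_thr)`` over a non-empty window."""
    n = len(window)
    if n == 0:
        raise ValueError("sensitivity threshold needs at least one observation")
    return max(c_thr * sum(window) / n, n_thr)


def filtered_memory(window, s_thr: float) -> list[float]:
    """Observations strictly above the sensitivity threshold, in order."""
    return [z for z in window if z > s_thr]


def features(window, s_thr: float) -> tuple[float, float]:
    """Average intensity ``c`` and intermittency ``i`` of a window.

    ``c`` is the mean over above-threshold observations only (0 if none);
    ``i`` is their fraction of the full window.
    """
    n = len(window)
    if n == 0:
        raise ValueError("features need at least one observation")
    total = 0.0
    count = 0
    for z in window:
        if z > s_thr:
            total += z
            count += 1
    c = total / count if count else 0.0
    return c, count / n


def discretize_intermittency(i: float, cuts: tuple[float, float] = _I_CUTS) -> int:
    """3-bin intermittency: 0 if i <= 0.33, 1 if <= 0.66, else 2."""
    if i < 0.0 or i > 1.0:
        raise ValueError(f"intermittency must lie in [0, 1], got {i}")
    lo, hi = cuts
    if i <= lo:
        return 0
    if i <= hi:
        return 1
    return 2


def nearest_rank_percentile(sorted_values, q: float) -> float:
    """Nearest-rank percentile of an ascending sequence (inverse ECDF)."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("percentile of an empty dataset")
    rank = max(1, math.ceil(q / 100.0 * n))
    return sorted_values[min(rank, n) - 1]


def discretize_intensity(
    c: float,
    sorted_history,
    percentiles: tuple[float, float, float, float] = _C_PERCENTILES,
) -> int:
    """5-bin intensity by comparing ``c`` to running percentiles of ``X``.

    Bin 0: c <= p25, 1: <= p50, 2: <= p80, 3: <= p99, 4: above p99, where
    the percentiles are nearest-rank over the agent's intensity history.
    """
    for b, q in enumerate(percentiles):
        if c <= nearest_rank_percentile(sorted_history, q):
            return b
    return len(percentiles)


class OlfactoryStateMachine:
    """Online computation of the olfactory state along an agent's path.

    Parameters
    ----------
    memory : int
        Sensing memory ``T`` (fixed mode), or the default used in adaptive
        mode until the first blank completes.
    c_thr : float
        Scaling constant of the sensitivity threshold (default 0.5).
    n_thr : float
        Hard floor of the sensitivity threshold; set it to the environment
        noise level.
    adaptive : bool
        If True, ``T`` tracks the most recent completed blank, clamped to
        ``1..buffer_capacity``.
    buffer_capacity : int
        Raw-observation buffer size ``T_b`` in adaptive mode (default 50).
    single_state : bool
        Ablation collapsing the 15 sensed states into one.
    intensity_bin_edges : tuple of 4 floats, optional
        Global binning: fixed ascending cut points for the intensity bins
        instead of the online percentiles.  Requires prior knowledge of
        the concentration scale, so it is off by default; the intensity
        history ``X`` is still collected.
    """

    __slots__ = (
        "default_memory", "c_thr", "n_thr", "adaptive", "buffer_capacity",
        "single_state", "i_cuts", "percentiles", "bin_edges", "_buf", "_X",
        "_blank_len", "_last_blank", "state", "c", "i", "s_thr", "T",
    )

    def __init__(
        self,
        memory: int = 20,
        c_thr: float = 0.5,
        n_thr: float = 3e-6,
        adaptive: bool = False,
        buffer_capacity: int = 50,
        single_state: bool = False,
        i_cuts: tuple[float, float] = _I_CUTS,
        percentiles: tuple[float, float, float, float] = _C_PERCENTILES,
        intensity_bin_edges: tuple[float, float, float, float] | None = None,
    ) -> None:
        if memory < 1:
            raise ValueError("memory must be >= 1")
        if buffer_capacity < 1:
            raise ValueError("buffer_capacity must be >= 1")
        self.default_memory = memory
        self.c_thr = c_thr
        self.n_thr = n_thr
        self.adaptive = adaptive
        self.buffer_capacity = buffer_capacity if adaptive else max(memory, 1)
        self.single_state = single_state
        self.i_cuts = i_cuts
        self.percentiles = percentiles
        if intensity_bin_edges is not None:
            intensity_bin_edges = tuple(intensity_bin_edges)
            if list(intensity_bin_edges) != sorted(intensity_bin_edges):
                raise ValueError("intensity_bin_edges must be ascending")
        self.bin_edges = intensity_bin_edges
        self.reset()

    # -- episode lifecycle -------------------------------------------------

    def reset(self) -> None:
        """Forget everything (start of an episode)."""
        self._buf: list[float] = []
        self._X: list[float] = []  # ascending intensity history
        self._blank_len = 0
        self._last_blank: int | None = None
        self.state = VOID
        self.c = 0.0
        self.i = 0.0
        self.s_thr = self.n_thr
        self.T = self.default_memory

    def initialize(self, prior_observations) -> int:
        """Fill the buffer with the pre-start observations and seed ``X``.

        The intensity history starts as ``{c(M_0)}``; the blank tracker
        starts clean (no blank completed yet).
        """
        self.reset()
        for z in prior_observations:
            self._buf.append(float(z))
            if len(self._buf) > self.buffer_capacity:
                self._buf.pop(0)
        if not self._buf:
            raise ValueError("initialize needs at least one prior observation")
        self._recompute_features()
        insort(self._X, self.c)
        self._classify()
        return self.state

    # -- online update -----------------------------------------------------

    def update(self, z: float) -> int:
        """Push one observation; return the new olfactory state code.

        Order of operations: the adaptive window length is set from the
        blank completed *before* this observation; the new threshold is
        computed on the updated window; then the blank tracker compares
        ``z`` against that threshold.
        """
        self._buf.append(float(z))
        if len(self._buf) > self.buffer_capacity:
            self._buf.pop(0)
        self._recompute_features()
        # blank tracking against the current threshold
        if z > self.s_thr:
            if self._blank_len > 0:
                self._last_blank = self._blank_len
            self._blank_len = 0
        else:
            self._blank_len += 1
        insort(self._X, self.c)  # X grows before the state is discretized
        self._classify()
        return self.state

    def _recompute_features(self) -> None:
        if self.adaptive:
            if self._last_blank is not None:
                self.T = min(max(self._last_blank, 1), self.buffer_capacity)
            else:
                self.T = self.default_memory
        else:
            self.T = self.default_memory
        window = self._buf[-self.T:] if len(self._buf) > self.T else self._buf
        n = len(window)
        total = 0.0
        for v in window:
            total += v
        s_thr = self.c_thr * total / n
        if s_thr < self.n_thr:
            s_thr = self.n_thr
        self.s_thr = s_thr
        above_total = 0.0
        above = 0
        for v in window:
            if v > s_thr:
                above_total += v
                above += 1
        if above == 0:
            self.c = 0.0
            self.i = 0.0
        else:
            self.c = above_total / above
            self.i = above / n

    def _classify(self) -> None:
        if self.i == 0.0:
            self.state = VOID
            return
        if self.single_state:
            self.state = 0
            return
        i_bin = 0 if self.i <= self.i_cuts[0] else (1 if self.i <= self.i_cuts[1] else 2)
        if self.bin_edges is not None:
            c_bin = 4
            for b, edge in enumerate(self.bin_edges):
                if self.c <= edge:
                    c_bin = b
                    break
        else:
            c_bin = discretize_intensity(self.c, self._X, self.percentiles)
        self.state = i_bin * 5 + c_bin

    # -- introspection -----------------------------------------------------

    @property
    def window(self) -> list[float]:
        """The trailing ``T`` observations the features were computed on."""
        return list(self._buf[-self.T:] if len(self._buf) > self.T else self._buf)

    @property
    def intensity_history(self) -> list[float]:
        """Ascending copy of the intensity dataset ``X``."""
        return list(self._X)

    @property
    def last_blank(self) -> int | None:
        """Duration of the most recent completed blank, if any."""
        return self._last_blank

    @property
    def current_blank_length(self) -> int:
        return self._blank_len

    def adaptive_memory(self) -> int:
        """Window length the adaptive rule would use right now."""
        if self._last_blank is None:
            return self.default_memory
        return min(max(self._last_blank, 1), self.buffer_capacity)
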