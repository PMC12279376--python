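# Methods

## Model

Navigation is a discrete Markov decision process on an integer lattice.
The agent's position is hidden; its observation is the odor
concentration `z(s(t), t)` read from a time-resolved snapshot stack at
its current cell, with the frame index advancing by one per decision and
wrapping modulo the number of stored frames. Positions outside the
stored grid are legal and read zero (the gridworld is infinite). One
action per time stamp displaces the agent `speed` cells along one of the
four wind-relative axes; the episode ends with reward +1 on entering the
circular source region, otherwise each decision costs σ, and searches
are cut off at the horizon `H`.

### Olfactory states

The sensing buffer holds the last `T` observations (the *sensing
memory*). Features are computed per update:

1. sensitivity threshold `s_thr = max(C_thr/T · Σ M_i, n_thr)`;
2. filtered memory `Δᴹ`: the observations strictly above `s_thr`;
3. intensity `c` (mean of `Δᴹ`, 0 if empty) and intermittency
   `i = |Δᴹ|/|M|`.

`i` is discretized at 0.33/0.66 (lower-closed) and `c` at the
25/50/80/99th percentiles of the intensity history `X` accumulated along
the agent's own path, nearest-rank convention, with the current `c`
inserted into `X` *before* discretization. `X` resets at each episode
start and is seeded with `c(M₀)`, where `M₀` is pre-filled with the
observations at the start cell over the frames preceding the start
frame. An empty `Δᴹ` is the void state.

Two documented variants exist, both off by default: `single_state`
collapses the 15 sensed states into one (an ablation that degrades
performance), and `intensity_bin_edges` replaces the online percentiles
with fixed global cut points. The online rule needs no prior knowledge
of the concentration scale but makes state identity path-dependent; the
global rule is the converse. With a frozen history the two coincide (a
property the tests check).

### Update order within one decision

Select action (Q-policy in sensed states, recovery in the void) → move →
advance the frame → observe `z` → terminal check → recompute features
and state → blank-tracker update (`z` vs the new `s_thr`) → recovery
bookkeeping (detection clears/re-arms strategies; a blank step after a
policy action is recorded for backtracking) → TD backup. In adaptive
mode the window length for this decision uses the blank completed
*before* the current observation, which breaks the circularity between
the threshold (needs `T`) and the blank tracker (needs the threshold).

### Adaptive memory

`T = clamp(τ_b⁻, 1, T_b)` where `τ_b⁻` is the most recent completed
blank — a maximal run of observations ≤ `s_thr` terminated by a
detection — and `T_b` (default 50) is the raw-observation buffer
capacity. Until a first blank completes, the configured default memory
is used. Blanks are measured with the same threshold that empties the
filtered memory, so "blank ends" and "state leaves void" agree.

### Recovery strategies

Brownian (uniform random), backtracking (LIFO inversion of the actions
recorded on blank steps since the last detection; random fallback when
exhausted; capacity equal to the sensing buffer, oldest actions retained
on overflow so over-long excursions unwind partially), circling (run
lengths 1, 2, 3, … rotating downwind → crosswind-right → upwind →
crosswind-left), cast-and-surge (crosswind runs doubling 1, 2, 4, …,
direction alternating, one upwind step *in place of* the tick after each
run — one action per decision), and learned (void split into 50
sub-states labeled by time since entry, clamped at 50, counter reset on
detection; actions learned by the same table). Backtracking records only
Q-policy actions: recording the recovery's own inverse steps would
corrupt the stored path. Circling and cast-and-surge re-arm on any
observation above `s_thr`.

### Q-learning

Dense table over 15 sensed states plus either one void row (heuristic
recoveries) or 50 void sub-state rows (learned recovery), initialized at
`q_init = 0.6`. Published protocol: 100,000 episodes, horizon 5000,
γ = 0.9999, σ = 0.001, ε and α schedules `0.99·e^(−10⁻⁴k)` and
`0.25·e^(−10⁻³k)`. Terminal transitions zero the bootstrap term. Argmax
ties break uniformly at random (a fixed-order tie-break is available).
Episode starts draw uniformly from the admissible cells and a uniform
start frame in `[|M₀|, n_frames)`. Training is bit-reproducible given
(dataset, config, seed); one config seed fans out to the training and
test streams through independent `SeedSequence` children.

The single void row of a heuristic recovery is never used for action
selection; it only supplies the bootstrap value of transitions *into*
the void. By default it is updated each void step with the action the
recovery played. `TrainConfig(update_void_row=False)` freezes it at
`q_init` instead — a fixed prior for the value of being lost (note
0.6 ≈ γ^H for the published γ and H, the value of succeeding right at
the horizon). The frozen variant matters on *deterministic* plumes:
there the single void row is aliased across the whole domain, and
max-bootstrap feedback can lend it fictitious value that attracts
distant states into closed greedy cycles which a static environment
never breaks. Stochastic plumes disrupt such cycles, and the learned
updates help there, so updating is the default.

## Evaluation

Greedy (ε = 0) trajectories, `n_reps` per start (default 10), no
learning. Start sets: *admissible* (any cell with at least one non-zero
observation, source region excluded) or *valid* (observation at the
start frame above the initialized buffer's threshold); the start frame
defaults to the buffer length so pre-start windows are filled from real
frames. Metrics, with λ = −ln γ (Δt = 1):

- `G`: per trajectory `e^{−λτ} − σ(1−e^{−λτ})/(1−γ)`; censored runs
  contribute `G⁻ = −σ(1−e^{−λH})/(1−γ)`. The success term `e^{−λτ}`
  corresponds to the +1 arriving at discount γ^τ with the penalty paid
  on all τ steps; the test-suite oracle reconstructs reward streams
  under exactly this convention, making the closed form equal the
  literal discounted sum to 10⁻¹⁰.
- `f⁺`: success fraction; `g⁺ = ⟨e^{−λτ}|success⟩` (flagged NaN with no
  successes); `⟨τ_min/τ⟩` with failures contributing `τ_min/H`.
- Statistics are computed per start first, then mean and SD across
  starts; the decomposition `G = f⁺G⁺ + (1−f⁺)G⁻` is exact on pooled
  trajectories. Note `G⁺ = g⁺ − σ(1−g⁺)/(1−γ)` is positive only when
  successes are faster than ≈ 950 steps at the published γ and σ.

`τ_min` is computed in closed form: moves are unconstrained axis steps,
so the optimum is the minimal Manhattan distance over source-region
cells congruent to the start modulo the speed, divided by the speed
(breadth-first search over the step lattice is the independent oracle in
the tests). Occupancy statistics count per-step state visits (void
sub-states pooled), action histograms weighted by occupancy, and
per-cell void probabilities.

## Synthetic plume generator

A stochastic puff model stands in for the DNS snapshot data: Poisson
emissions at the source (`puff_rate` per frame), advection by a mean
wind, independent crosswind Gaussian random walks (`meander_sd`), and
Gaussian blobs of conserved mass whose squared radius grows linearly
with age (`puff_growth`), summed per cell and clipped by a hard noise
floor. A spin-up phase (2·nx/wind frames) precedes frame 0 so the
recorded stack is statistically steady.

Defaults — 128×64 grid, source (12, 32), 2000 frames, wind 1 cell/frame,
rate 0.8, meander 1.2, growth 0.02, floor 10⁻⁴ — were chosen once to
match the Eulerian regime of the boundary-layer data the method was
developed on: pooled mean blank ≈ 10 frames with a heavy tail (SD ≈ 3×
the mean), whiffs of comparable scale, and per-cell intermittency
spanning a nearly saturated thin core to a few percent at the edges.
What the generator does *not* emulate: spatially correlated meandering
(puffs wander independently, so signal correlations between neighboring
cells are too weak), realistic turbulent spectra and concentration PDFs,
Reynolds-number scaling. Passing tests on it therefore show that the
algorithm handles *intermittency with the right duration statistics*,
not that performance numbers transfer to any particular real flow.

Eulerian whiff/blank statistics segment each cell's above-threshold
binary series into maximal runs; runs touching the series boundary are
censored and dropped; never-detecting cells are flagged NaN and excluded
from pooling.

## Scaled-down study conditions

The published protocol (10⁵ episodes on a 1225×280 DNS stack) is hours
of CPU; the test suite and the acceptance script run the same code at
reduced scale, with schedule decay constants scaled inversely to the
episode count so the schedules traverse the same range:

- **Optimal-memory sweep**: stock plume, speed 1, horizon 1000 (≈9× the
  longest shortest-path; the published horizon is ≈40×, but lost agents
  need room to cycle through recovery for the void-encounter statistics
  to be meaningful), T ∈ {1, 2, 4, 8, 16, 32}, 2000 episodes, 3 training
  seeds averaged, 250 sampled starts × 2 repetitions.
- **Cone oracle**: 50×20 static blank-free cone with five concentration
  plateaus (halving every 10 cells), fixed intensity bin edges between
  the plateaus so the olfactory states partition space compatibly,
  T = 2, backtracking, 6000 episodes, horizon 400, γ = 0.995 (discount
  matched to the fixture's timescale the same way the published γ pairs
  with its horizon), frozen void row. Under these conditions training
  converges to exact shortest paths from every start, verified against
  breadth-first search.

## Numerical choices and edge cases

- Nearest-rank percentiles (inverse ECDF): exact on small histories, no
  interpolation ambiguity.
- Strict inequality (`>`) for detection everywhere: filtered memory,
  valid starts, blank tracking, recovery re-arming.
- An agent starting inside the source region terminates immediately with
  τ = 0 (metric contribution e⁰ = 1).
- Empty intensity history, empty sensing window, and empty start sets
  raise; out-of-grid positions and t beyond the stack do not (defined
  cases: zero signal, wrapped time).
- Q-values are provably confined to [−σ/(1−γ), 1] for rewards in
  {−σ, +1}; the tests assert it after training.
- `n_thr` is set to the environment noise level; the two symbols are
  used interchangeably by the data preprocessing and the threshold
  formula, and nothing in the package distinguishes them.

## Known limitations

- Tabular only: no function approximation or recurrent policies.
- The online percentile binning makes olfactory states path-dependent;
  analyses that need a spatially stable state map should use the global
  binning mode.
- The adaptive-memory buffer `T_b = 50` is a convention; performance is
  insensitive to it until blanks routinely exceed it.
- Recovery strategies are pure and mutually exclusive; no mixtures or
  switching policies.
- The simulator is 2D and snapshot-driven; no within-frame motion,
  no 3D plumes, no flow simulation.
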