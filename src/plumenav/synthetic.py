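"""Synthetic intermittent plumes and Eulerian whiff/blank statistics.

The generator is a stochastic puff model: puffs are emitted at the
source with Poisson counts per frame, advected downwind by a mean wind,
meander crosswind by independent Gaussian random walks, and spread as
radially symmetric Gaussian blobs whose squared radius grows linearly
with age while total mass is conserved.  A hard noise floor zeroes the
faint tails.  The result reproduces the statistical traits the
navigation method depends on — a conical time-averaged plume,
concentration decaying downwind, and on/off (whiff/blank) signals whose
durations broaden with distance from the source — with five
interpretable knobs, without attempting to match any particular
turbulent spectrum.

:func:`blank_statistics` measures the fixed-point (Eulerian) whiff and
blank durations of any snapshot stack: per cell, the binary
above-threshold series is segmented into maximal runs, and below-runs
strictly between two above-runs are blanks (runs touching the series
boundary are censored and dropped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .field import GridPosition, OdorField, apply_noise_floor

__all__ = ["PuffPlumeParams", "generate", "BlankStats", "blank_statistics"]


@dataclass
class PuffPlumeParams:
    """Knobs of the puff-plume generator.

    Defaults give a genuinely intermittent plume on a 128 x 64 grid:
    small puffs (squared radius 0.02 cells^2 per frame of age) emitted
    roughly every 1-2 frames, drifting one cell per frame downwind while
    meandering crosswind faster than they grow, so that a fixed point
    inside the plume sees the signal switch on and off.  The resulting
    fixed-point (Eulerian) statistics — pooled mean blank near 10 frames
    with a heavy tail, intermittency ranging from a near-saturated thin
    core to a few percent at the edges — mirror the boundary-layer
    snapshot data this generator stands in for.
    """

    grid_shape: tuple[int, int] = (128, 64)
    source_pos: GridPosition = (12, 32)
    n_frames: int = 2000
    mean_wind: float = 1.0          # cells advected per frame, +x
    puff_rate: float = 0.8          # expected emissions per frame
    puff_growth: float = 0.02       # squared-radius growth per frame, cells^2
    meander_sd: float = 1.2         # crosswind random-walk step SD, cells
    emission_mass: float = 1.0
    noise_level: float = 1e-4
    seed: int = 0
    warmup: int | None = None   # spin-up frames before t=0; None -> automatic

    def __post_init__(self) -> None:
        if self.puff_rate < 0:
            raise ValueError("puff_rate must be >= 0")
        if self.puff_growth <= 0:
            raise ValueError("puff_growth must be > 0")
        if self.meander_sd < 0:
            raise ValueError("meander_sd must be >= 0")
        if self.emission_mass <= 0:
            raise ValueError("emission_mass must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


def generate(params: PuffPlumeParams) -> OdorField:
    """Simulate a puff plume; bit-reproducible for identical params+seed.

    Each live puff of age ``a`` deposits
    ``mass / (2 pi s2) * exp(-d^2 / (2 s2))`` with
    ``s2 = puff_growth * (a + 1)``; the frame is the sum over puffs, then
    the noise floor is applied.  Puffs whose 4-sigma support has left the
    grid downwind are retired.
    """
    rng = np.random.default_rng(params.seed)
    nx, ny = params.grid_shape
    sx, sy = params.source_pos
    frames = np.zeros((params.n_frames, nx, ny), dtype=np.float64)

    puff_x: list[float] = []
    puff_y: list[float] = []
    puff_age: list[int] = []

    # spin up to a statistically steady puff population before recording,
    # long enough for emissions to cross the whole domain
    if params.warmup is None:
        warmup = int(2 * nx / params.mean_wind) if params.mean_wind > 0 else nx
    else:
        warmup = params.warmup

    for t in range(-warmup, params.n_frames):
        # advect and meander existing puffs, then emit new ones at the source
        n_live = len(puff_x)
        if n_live:
            steps = rng.normal(0.0, params.meander_sd, size=n_live) \
                if params.meander_sd > 0 else np.zeros(n_live)
            for i in range(n_live):
                puff_x[i] += params.mean_wind
                puff_y[i] += steps[i]
                puff_age[i] += 1
        for _ in range(rng.poisson(params.puff_rate)):
            puff_x.append(float(sx))
            puff_y.append(float(sy))
            puff_age.append(0)

        # retire puffs gone past the downwind edge
        keep = [
            i for i in range(len(puff_x))
            if puff_x[i] - 4.0 * math.sqrt(params.puff_growth * (puff_age[i] + 1)) < nx
        ]
        if len(keep) != len(puff_x):
            puff_x = [puff_x[i] for i in keep]
            puff_y = [puff_y[i] for i in keep]
            puff_age = [puff_age[i] for i in keep]

        if t < 0:
            continue  # spin-up: evolve puffs without rendering
        frame = frames[t]
        for cx, cy, age in zip(puff_x, puff_y, puff_age):
            s2 = params.puff_growth * (age + 1)
            radius = 4.0 * math.sqrt(s2)
            x_lo = max(0, int(math.floor(cx - radius)))
            x_hi = min(nx, int(math.ceil(cx + radius)) + 1)
            y_lo = max(0, int(math.floor(cy - radius)))
            y_hi = min(ny, int(math.ceil(cy + radius)) + 1)
            if x_lo >= x_hi or y_lo >= y_hi:
                continue
            xs = np.arange(x_lo, x_hi, dtype=np.float64) - cx
            ys = np.arange(y_lo, y_hi, dtype=np.float64) - cy
            d2 = xs[:, None] ** 2 + ys[None, :] ** 2
            frame[x_lo:x_hi, y_lo:y_hi] += (
                params.emission_mass / (2.0 * math.pi * s2)
            ) * np.exp(-d2 / (2.0 * s2))

    return apply_noise_floor(OdorField(frames), params.noise_level)


# ---------------------------------------------------------------------------
# Eulerian run-length statistics
# ---------------------------------------------------------------------------


@dataclass
class BlankStats:
    """Per-cell and pooled whiff/blank durations (frames).

    Cells never above threshold (or with no interior run) carry NaN in
    the per-cell maps and are excluded from pooling.
    """

    mean_blank: np.ndarray
    sd_blank: np.ndarray
    mean_whiff: np.ndarray
    pooled_mean_blank: float
    pooled_sd_blank: float
    pooled_mean_whiff: float
    pooled_sd_whiff: float
    n_blanks: int
    n_whiffs: int

    def to_dataframe(self):
        """Long-format table: cell x, cell y, mean_blank, sd_blank, mean_whiff."""
        import pandas as pd

        nx, ny = self.mean_blank.shape
        xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return pd.DataFrame({
            "x": xs.ravel(), "y": ys.ravel(),
            "mean_blank": self.mean_blank.ravel(),
            "sd_blank": self.sd_blank.ravel(),
            "mean_whiff": self.mean_whiff.ravel(),
        })


def _interior_runs(binary: np.ndarray) -> tuple[list[int], list[int]]:
    """Durations of interior below-runs (blanks) and above-runs (whiffs).

    Runs touching either end of the series are censored and dropped.
    """
    n = binary.size
    change = np.flatnonzero(np.diff(binary)) + 1
    bounds = np.concatenate(([0], change, [n]))
    blanks: list[int] = []
    whiffs: list[int] = []
    n_runs = bounds.size - 1
    for i in range(n_runs):
        if i == 0 or i == n_runs - 1:
            continue  # censored at the series boundary
        dur = int(bounds[i + 1] - bounds[i])
        if binary[bounds[i]]:
            whiffs.append(dur)
        else:
            blanks.append(dur)
    return blanks, whiffs


def blank_statistics(field: OdorField, threshold: float) -> BlankStats:
    """Eulerian whiff/blank statistics of a snapshot stack.

    For each grid cell the series ``concentration > threshold`` is
    segmented into maximal runs; blank durations are lengths of
    below-threshold runs strictly between two above-threshold runs.
    """
    if field.n_frames < 2:
        raise ValueError("blank statistics need at least 2 frames")
    nx, ny = field.grid_shape
    mean_blank = np.full((nx, ny), np.nan)
    sd_blank = np.full((nx, ny), np.nan)
    mean_whiff = np.full((nx, ny), np.nan)
    all_blanks: list[int] = []
    all_whiffs: list[int] = []
    ever = (field.frames > threshold).any(axis=0)
    for x, y in zip(*np.nonzero(ever)):
        binary = (field.frames[:, x, y] > threshold).astype(np.int8)
        blanks, whiffs = _interior_runs(binary)
        if blanks:
            mean_blank[x, y] = float(np.mean(blanks))
            sd_blank[x, y] = float(np.std(blanks))
            all_blanks.extend(blanks)
        if whiffs:
            mean_whiff[x, y] = float(np.mean(whiffs))
            all_whiffs.extend(whiffs)
    return BlankStats(
        mean_blank=mean_blank,
        sd_blank=sd_blank,
        mean_whiff=mean_whiff,
        pooled_mean_blank=float(np.mean(all_blanks)) if all_blanks else float("nan"),
        pooled_sd_blank=float(np.std(all_blanks)) if all_blanks else float("nan"),
        pooled_mean_whiff=float(np.mean(all_whiffs)) if all_whiffs else float("nan"),
        pooled_sd_whiff=float(np.std(all_whiffs)) if all_whiffs else float("nan"),
        n_blanks=len(all_blanks),
        n_whiffs=len(all_whiffs),
    )
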