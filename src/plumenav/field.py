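"""Odor snapshot stacks served as a gridworld environment.

The environment is a time-ordered stack of 2D concentration grids
("frames").  An agent occupies integer grid coordinates ``(x, y)`` with
``x`` increasing downwind (the mean flow blows toward larger ``x``) and
moves one axis-aligned step of ``speed`` cells per decision.  The
gridworld is infinite: positions outside the stored grid are legal and
simply read zero concentration.  Time is periodic — frame indices are
taken modulo the number of stored frames.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import IntEnum
import numpy as np

__all__ = [
    "Action",
    "ACTION_VECTORS",
    "INVERSE_ACTION",
    "GridPosition",
    "OdorField",
    "EnvironmentSpec",
    "load_field",
    "save_field",
    "apply_noise_floor",
    "observe",
    "move",
    "in_source_region",
    "admissible_starts",
    "valid_starts",
]

#: A grid position is a plain ``(x, y)`` tuple of (possibly negative) ints.
GridPosition = tuple[int, int]


class Action(IntEnum):
    """The four moves, labeled relative to the mean flow (+x downwind)."""

    UPWIND = 0  # -e1
    DOWNWIND = 1  # +e1
    CROSSWIND_LEFT = 2  # -e2
    CROSSWIND_RIGHT = 3  # +e2


#: Unit displacement of each action, before scaling by speed.
ACTION_VECTORS: dict[int, tuple[int, int]] = {
    Action.UPWIND: (-1, 0),
    Action.DOWNWIND: (1, 0),
    Action.CROSSWIND_LEFT: (0, -1),
    Action.CROSSWIND_RIGHT: (0, 1),
}

#: Action that exactly undoes each action.
INVERSE_ACTION: dict[int, int] = {
    Action.UPWIND: Action.DOWNWIND,
    Action.DOWNWIND: Action.UPWIND,
    Action.CROSSWIND_LEFT: Action.CROSSWIND_RIGHT,
    Action.CROSSWIND_RIGHT: Action.CROSSWIND_LEFT,
}

N_ACTIONS = 4


@dataclass
class OdorField:
    """Time-ordered stack of 2D odor-concentration grids.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, nx, ny)
        Non-negative concentrations in arbitrary units (relative to the
        concentration at the source).  Axis 0 is time, axis 1 streamwise,
        axis 2 spanwise.
    frame_index_wraps : bool
        If True (default) the stack loops in time: frame ``t`` reads
        ``frames[t % n_frames]``.
    """

    frames: np.ndarray
    frame_index_wraps: bool = True

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a 3D (time, x, y) array, got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def frame(self, t: int) -> np.ndarray:
        return self.frames[t % self.n_frames]


@dataclass
class EnvironmentSpec:
    """Gridworld geometry and episode bookkeeping.

    Defaults follow the native boundary-layer dataset: source at (20, 142)
    with a circular source region of radius 10, noise level 3e-6 relative
    to the source concentration, agent speed 10 grid points per decision,
    one decision per time stamp and a 5000-step horizon.
    """

    source_pos: GridPosition = (20, 142)
    source_radius: float = 10.0
    noise_level: float = 3e-6
    speed: int = 10
    decisions_per_stamp: int = 1
    horizon: int = 5000

    def __post_init__(self) -> None:
        if self.source_radius < 0:
            raise ValueError("source_radius must be >= 0")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.speed < 1:
            raise ValueError("speed must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


# ---------------------------------------------------------------------------
# I/O: three supported container dialects
# ---------------------------------------------------------------------------

_LAYOUTS = ("hdf5", "npz", "frames_dir")


def _infer_layout(path: str) -> str:
    if os.path.isdir(path):
        return "frames_dir"
    suffix = os.path.splitext(path)[1].lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if suffix == ".npz":
        return "npz"
    raise ValueError(
        f"cannot infer dataset layout for {path!r}; pass layout explicitly "
        f"(one of {_LAYOUTS})"
    )


def load_field(path: str, layout: str | None = None) -> OdorField:
    """Read a snapshot stack from one of the supported container dialects.

    Supported layouts: ``hdf5`` (one 3D time-major dataset, named
    ``frames`` or the only 3D dataset in the file), ``npz`` (array
    ``frames`` or the only array), and ``frames_dir`` (a directory of
    per-frame 2D text matrices with sortable zero-padded names).
    """
    if layout is None:
        layout = _infer_layout(path)
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {_LAYOUTS}")
    if layout == "frames_dir":
        if not os.path.isdir(path):
            raise FileNotFoundError(path)
        names = sorted(
            n for n in os.listdir(path)
            if os.path.splitext(n)[1].lower() in (".txt", ".csv", ".dat")
        )
        if not names:
            raise ValueError(f"no per-frame matrices found in {path!r}")
        mats = [np.atleast_2d(np.loadtxt(os.path.join(path, n))) for n in names]
        shapes = {m.shape for m in mats}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes in {path!r}: {sorted(shapes)}")
        return OdorField(np.stack(mats, axis=0))
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if layout == "npz":
        with np.load(path) as archive:
            if "frames" in archive:
                data = archive["frames"]
            elif len(archive.files) == 1:
                data = archive[archive.files[0]]
            else:
                raise ValueError(
                    f"{path!r} holds {archive.files}; expected a single array "
                    "or one named 'frames'"
                )
            return OdorField(np.asarray(data))
    # hdf5
    import h5py

    with h5py.File(path, "r") as handle:
        if "frames" in handle:
            data = handle["frames"][...]
        else:
            candidates = [
                k for k, v in handle.items()
                if isinstance(v, h5py.Dataset) and v.ndim == 3
            ]
            if len(candidates) != 1:
                raise ValueError(
                    f"{path!r} must hold one 3D dataset (or one named 'frames'); "
                    f"found {candidates}"
                )
            data = handle[candidates[0]][...]
        return OdorField(np.asarray(data))


def save_field(field: OdorField, path: str, layout: str | None = None) -> None:
    """Write a snapshot stack in one of the supported container dialects."""
    if layout is None:
        layout = _infer_layout(path)
    if layout == "hdf5":
        import h5py

        with h5py.File(path, "w") as handle:
            handle.create_dataset("frames", data=field.frames)
    elif layout == "npz":
        np.savez_compressed(path, frames=field.frames)
    elif layout == "frames_dir":
        os.makedirs(path, exist_ok=True)
        width = max(4, len(str(field.n_frames)))
        for t in range(field.n_frames):
            np.savetxt(os.path.join(path, f"frame_{t:0{width}d}.txt"), field.frames[t])
    else:
        raise ValueError(f"unknown layout {layout!r}; expected one of {_LAYOUTS}")


# ---------------------------------------------------------------------------
# Environment primitives
# ---------------------------------------------------------------------------


def apply_noise_floor(field: OdorField, noise_level: float) -> OdorField:
    """Zero every concentration strictly below ``noise_level``.

    Entries below the sensor noise floor are indistinguishable from zero;
    the operation is idempotent.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    frames = field.frames.copy()
    frames[frames < noise_level] = 0.0
    return OdorField(frames, frame_index_wraps=field.frame_index_wraps)


def observe(field: OdorField, pos: GridPosition, t: int) -> float:
    """Concentration at ``pos`` at time ``t`` (0 outside the grid).

    Time wraps modulo ``n_frames``; agents that left the grid continue to
    receive zero signal.
    """
    x, y = pos
    nx, ny = field.grid_shape
    if x < 0 or y < 0 or x >= nx or y >= ny:
        return 0.0
    return float(field.frames[t % field.n_frames, x, y])


def move(pos: GridPosition, action: int, speed: int) -> GridPosition:
    """Displace ``pos`` by ``speed`` cells along the action's direction."""
    dx, dy = ACTION_VECTORS[action]
    return (pos[0] + dx * speed, pos[1] + dy * speed)


def in_source_region(pos: GridPosition, spec: EnvironmentSpec) -> bool:
    """True iff ``pos`` is within ``source_radius`` (Euclidean) of the source."""
    dx = pos[0] - spec.source_pos[0]
    dy = pos[1] - spec.source_pos[1]
    return dx * dx + dy * dy <= spec.source_radius * spec.source_radius


def _source_region_mask(field: OdorField, spec: EnvironmentSpec) -> np.ndarray:
    nx, ny = field.grid_shape
    xs = np.arange(nx)[:, None] - spec.source_pos[0]
    ys = np.arange(ny)[None, :] - spec.source_pos[1]
    return xs * xs + ys * ys <= spec.source_radius**2


def admissible_starts(
    field: OdorField, spec: EnvironmentSpec | None = None
) -> list[GridPosition]:
    """All in-grid cells where the odor is non-zero at least once.

    Assumes the noise floor was already applied.  When ``spec`` is given,
    cells inside the source region are excluded (they would be trivial
    zero-length searches).
    """
    mask = (field.frames > 0.0).any(axis=0)
    if spec is not None:
        mask &= ~_source_region_mask(field, spec)
    xs, ys = np.nonzero(mask)
    return [(int(x), int(y)) for x, y in zip(xs, ys)]


def valid_starts(
    field: OdorField,
    spec: EnvironmentSpec,
    t0: int,
    memory: int,
    c_thr: float = 0.5,
    n_thr: float | None = None,
) -> list[GridPosition]:
    """Cells whose observation at ``t0`` exceeds the sensitivity threshold.

    The threshold is that of a sensing buffer of length ``memory`` filled
    with the ``memory`` frames ending at ``t0`` (wrapping in time), i.e.
    ``max(c_thr * mean(window), n_thr)``.  Always a subset of
    :func:`admissible_starts`.
    """
    if n_thr is None:
        n_thr = spec.noise_level
    n = field.n_frames
    idx = [(t0 - memory + 1 + j) % n for j in range(memory)]
    window = field.frames[idx]  # (memory, nx, ny)
    s_thr = np.maximum(c_thr * window.mean(axis=0), n_thr)
    mask = field.frames[t0 % n] > s_thr
    mask &= ~_source_region_mask(field, spec)
    xs, ys = np.nonzero(mask)
    return [(int(x), int(y)) for x, y in zip(xs, ys)]
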