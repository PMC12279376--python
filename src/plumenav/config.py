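"""Structured run configuration and provenance manifest.

A run is described by a YAML file with blocks ``environment``,
``features``, ``recovery``, ``training``, ``evaluation`` and (for
generated plumes) ``synthetic``.  Every numeric default equals the
published value where one exists; a single top-level ``seed`` fans out
deterministically to the training, recovery and test-repetition random
streams (see :func:`plumenav.qlearning.derive_seed`).
"""

from __future__ import annotations

import hashlib
import json
import os
from datetime import datetime, timezone
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

__all__ = ["RunConfig", "load_config", "RunManifest", "dataset_checksum"]


class EnvironmentBlock(BaseModel):
    """Where the odor data come from and the gridworld geometry."""

    dataset: Optional[str] = None  # path; None -> synthetic block is used
    layout: Optional[Literal["hdf5", "npz", "frames_dir"]] = None
    source_pos: tuple[int, int] = (20, 142)
    source_radius: float = Field(10.0, ge=0)
    noise_level: float = Field(3e-6, ge=0)
    speed: int = Field(10, ge=1)
    decisions_per_stamp: int = Field(1, ge=1)
    horizon: int = Field(5000, ge=1)


class FeaturesBlock(BaseModel):
    memory: int = Field(20, ge=1)
    adaptive: bool = False
    buffer_capacity: int = Field(50, ge=1)
    c_thr: float = Field(0.5, gt=0)
    intermittency_cuts: tuple[float, float] = (0.33, 0.66)
    intensity_percentiles: tuple[float, float, float, float] = (25.0, 50.0, 80.0, 99.0)
    single_state: bool = False


class RecoveryBlock(BaseModel):
    strategy: Literal[
        "brownian", "backtracking", "circling", "cast_surge", "learned"
    ] = "backtracking"
    n_void_substates: int = Field(50, ge=1)


class TrainingBlock(BaseModel):
    n_episodes: int = Field(100_000, ge=0)
    gamma: float = Field(0.9999, gt=0, lt=1)
    sigma: float = Field(0.001, ge=0)
    success_reward: float = 1.0
    eta_init: float = Field(0.99, ge=0, le=1)
    eta_decay: float = Field(1e-4, ge=0)
    alpha_init: float = Field(0.25, gt=0)
    alpha_decay: float = Field(1e-3, ge=0)
    q_init: float = 0.6
    start_set: Literal["admissible", "valid"] = "admissible"
    log_every: int = Field(500, ge=1)


class EvaluationBlock(BaseModel):
    n_reps: int = Field(10, ge=1)
    start_set: Literal["admissible", "valid"] = "valid"
    memories: list[int] = Field(default_factory=lambda: [1, 2, 5, 10, 20, 50])


class SyntheticBlock(BaseModel):
    grid_shape: tuple[int, int] = (128, 64)
    source_pos: tuple[int, int] = (12, 32)
    n_frames: int = Field(2000, ge=1)
    mean_wind: float = 1.0
    puff_rate: float = Field(0.4, ge=0)
    puff_growth: float = Field(0.1, gt=0)
    meander_sd: float = Field(0.4, ge=0)
    emission_mass: float = Field(1.0, gt=0)
    noise_level: float = Field(1e-4, ge=0)


class RunConfig(BaseModel):
    """Top-level schema of a run configuration file."""

    seed: int = 0
    out_dir: str = "runs/run"
    environment: EnvironmentBlock = Field(default_factory=EnvironmentBlock)
    features: FeaturesBlock = Field(default_factory=FeaturesBlock)
    recovery: RecoveryBlock = Field(default_factory=RecoveryBlock)
    training: TrainingBlock = Field(default_factory=TrainingBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)
    synthetic: SyntheticBlock = Field(default_factory=SyntheticBlock)


def load_config(path: str) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Schema violations raise ``ValueError`` naming the offending key.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        keys = ", ".join(
            ".".join(str(loc) for loc in e["loc"]) for e in err.errors()
        )
        raise ValueError(f"invalid configuration ({path}): bad key(s): {keys}") from err


def dataset_checksum(path: str) -> str:
    """SHA-256 of a dataset file (or of the sorted file list of a directory)."""
    digest = hashlib.sha256()
    if os.path.isdir(path):
        for name in sorted(os.listdir(path)):
            digest.update(name.encode())
            with open(os.path.join(path, name), "rb") as handle:
                digest.update(handle.read())
    else:
        with open(path, "rb") as handle:
            for chunk in iter(lambda: handle.read(1 << 20), b""):
                digest.update(chunk)
    return digest.hexdigest()


class RunManifest(BaseModel):
    """Provenance record written next to every artifact."""

    command: str
    seed: int
    config: dict
    dataset: Optional[str] = None
    dataset_sha256: Optional[str] = None
    code_version: str = "plumenav 0.1.0"
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, config: RunConfig) -> "RunManifest":
        dataset = config.environment.dataset
        return cls(
            command=command,
            seed=config.seed,
            config=json.loads(config.model_dump_json()),
            dataset=dataset,
            dataset_sha256=dataset_checksum(dataset) if dataset else None,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, out_dir: str) -> str:
        os.makedirs(out_dir, exist_ok=True)
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w") as handle:
            handle.write(self.model_dump_json(indent=2))
        return path
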