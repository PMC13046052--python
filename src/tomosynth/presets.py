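"""Scale presets: the full-scale acquisition and a desk-scale configuration.

``full`` mirrors the study conditions (60 views of 2048x2048 at +/-15 deg,
180 cm source-detector distance, 31-px strips, 512-voxel CT grids, Adam at
3e-4 with batch 16); it is the default geometry/model contract.  ``desk``
is a proportionally shrunk configuration (16 views, 128x128 detector,
width-7 strips, 48^3 phantoms, 32x32 slice targets) sized so the whole
pipeline — simulation, training, evaluation — runs on one CPU in minutes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .geometry import AcquisitionGeometry
from .model import ModelConfig
from .projector import PhysicsConfig
from .training import TrainConfig


@dataclass
class RunConfig:
    preset: str = "desk"
    seed: int = 0
    n_phantoms: int = 200
    slices_per_patient: int = 2
    grid_shape: tuple = (48, 48, 48)
    voxel_size_mm: float = 3.0
    out_shape: tuple = (32, 32)
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def config_hash(self) -> str:
        """Hash of the fields that define shard compatibility: acquisition
        geometry, physics, grid and target shapes.  Cohort size and training
        hyperparameters do not change what a shard contains per sample."""
        d = asdict(self)
        keep = {k: d[k] for k in ("geometry", "physics", "grid_shape",
                                  "voxel_size_mm", "out_shape", "seed")}
        return hashlib.sha256(yaml.safe_dump(_plain(keep),
                                             sort_keys=True).encode()).hexdigest()[:16]


DESK_GEOMETRY = AcquisitionGeometry(
    sdd_mm=1800.0, sweep_deg=(-15.0, 15.0), n_views=16,
    detector_shape=(128, 128), detector_pitch_mm=1.4,
    patient_offset_mm=150.0, strip_width_px=7)

DESK_PHYSICS = PhysicsConfig(
    mu_water_per_mm=0.02, beam_hardening_beta=0.05, scatter_spr=0.2,
    scatter_sigma_px=8.0, motion_sd_mm=0.5, photons_n0=1e4)

DESK_MODEL = ModelConfig(
    input_shape=(16, 128, 7), output_shape=(32, 32),
    encoder_channels=(8, 16, 24, 32),
    encoder_strides=((2, 2, 1), (2, 2, 2), (2, 2, 2), (2, 2, 2)),
    decoder_channels=(24, 16), seed_channels=8,
    input_offset=0.6, input_scale=0.6)

FULL_GEOMETRY = AcquisitionGeometry()     # study defaults
FULL_PHYSICS = PhysicsConfig()
FULL_MODEL = ModelConfig()


def desk_run_config(seed: int = 0, n_phantoms: int = 200, epochs: int = 20) -> RunConfig:
    return RunConfig(
        preset="desk", seed=seed, n_phantoms=n_phantoms, slices_per_patient=3,
        grid_shape=(48, 48, 48), voxel_size_mm=3.0, out_shape=(32, 32),
        geometry=DESK_GEOMETRY, physics=DESK_PHYSICS, model=DESK_MODEL,
        train=TrainConfig(epochs=epochs, seed=seed))


def full_run_config(seed: int = 0) -> RunConfig:
    return RunConfig(
        preset="full", seed=seed, n_phantoms=2967, slices_per_patient=512,
        grid_shape=(512, 512, 512), voxel_size_mm=0.7, out_shape=(512, 512),
        geometry=FULL_GEOMETRY, physics=FULL_PHYSICS, model=FULL_MODEL,
        train=TrainConfig(epochs=400, seed=seed))


def get_run_config(preset: str, seed: int = 0, **overrides) -> RunConfig:
    if preset == "desk":
        cfg = desk_run_config(seed=seed)
    elif preset == "full":
        cfg = full_run_config(seed=seed)
    else:
        raise ValueError(f"unknown preset {preset!r} (expected 'desk' or 'full')")
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown RunConfig field {k!r}")
        setattr(cfg, k, v)
    return cfg


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(asdict(cfg)), fh, sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
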