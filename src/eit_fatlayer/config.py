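"""Experiment configuration: a single YAML/JSON-serializable description of
the domain, electrodes, protocol, layers, enumeration grids, network and
training settings, with a stable content hash stamped on every artifact."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import yaml

from .dataset import GAMMA_M_GRID, GAMMA_R_GRID
from .errors import ValidationError


@dataclass
class ExperimentConfig:
    """All knobs of one experiment, with the study defaults built in."""

    # geometry
    domain_kind: str = "disk"
    domain_params: dict = field(default_factory=dict)
    n_electrodes: int = 10
    arc_span: float = 0.5
    plate_span_cm: float | None = 16.0
    electrode_width: float = 1.0
    mesh_h: float = 0.6
    # protocol
    current_mA: float = 1.0
    # layers
    L: int = 15
    d0: float = 0.3
    roi: str | None = None
    # enumeration grids
    gamma_f: float = 1.0
    gamma_m_grid: list = field(default_factory=lambda: GAMMA_M_GRID.tolist())
    gamma_r_grid: list = field(default_factory=lambda: GAMMA_R_GRID.tolist())
    enforce_order: bool = False
    noise: float | None = None
    # network / training
    hidden: list = field(default_factory=lambda: [512, 256, 128, 64, 32])
    bias: bool = False
    output_activation: bool = True
    lr: float = 1e-3
    lr_decay: float = 0.5
    lr_decay_every: int = 200
    batch_size: int = 128
    epochs: int = 800
    patience: int = 800
    val_frac: float = 0.1
    input_transform: str = "whiten"
    input_clip: list | None = field(default_factory=lambda: [0.0, 20.0])
    select: str = "final"
    # estimation
    min_jump: float = 0.3
    # reproducibility
    seed: int = 1

    def __post_init__(self):
        if self.L < 3 or self.d0 <= 0 or self.mesh_h <= 0:
            raise ValidationError("invalid layer/mesh settings")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    def content_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    # -- derived arrays ---------------------------------------------------
    @property
    def gamma_m_array(self) -> np.ndarray:
        return np.asarray(self.gamma_m_grid, dtype=float)

    @property
    def gamma_r_array(self) -> np.ndarray:
        return np.asarray(self.gamma_r_grid, dtype=float)


def load_profile(name: str) -> ExperimentConfig:
    """Load a shipped profile: ``paper`` (full-scale) or ``quick`` (reduced)."""
    ref = resources.files("eit_fatlayer") / "profiles" / f"{name}.yaml"
    if not ref.is_file():
        raise ValidationError(f"no shipped profile named {name!r}")
    return ExperimentConfig.from_dict(yaml.safe_load(ref.read_text()) or {})
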