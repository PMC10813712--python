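"""Run configuration: model + loss + optimizer + data settings, with YAML
round-tripping and content hashing for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data import SynthConfig
from .losses import LossConfig
from .model import ModelConfig


@dataclass
class OptimizerConfig:
    """Adam settings.  The published protocol reports momentum 0.99 and
    weight decay 1e-8 together with Adam; we read "momentum" as beta1."""
    name: str = "adam"
    lr: float = 1.0e-4
    beta1: float = 0.99
    beta2: float = 0.999
    weight_decay: float = 1.0e-8

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be non-negative")


@dataclass
class DataConfig:
    train_manifest: str | None = None
    val_manifest: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_train: int = 64
    n_val: int = 16
    negative_fraction: float = 0.75
    augment: bool = True
    crop_stride_train: int = 64   # 50% overlap for dense training crops
    crop_stride_eval: int = 128


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    data: DataConfig = field(default_factory=DataConfig)
    epochs: int = 2000
    batch_size: int = 4
    max_steps: int | None = None   # optional hard cap on optimisation steps
    val_every: int = 1
    seed: int = 0
    output_dir: str = "runs/default"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs >= 1 and batch_size >= 1 required")


def to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def _build(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _build(f.type, v)
        kwargs[f.name] = v
    return cls(**kwargs)


def run_config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    sub = {"model": ModelConfig, "loss": LossConfig,
           "optimizer": OptimizerConfig, "data": DataConfig}
    kwargs = {}
    for key, cls in sub.items():
        if key in d:
            v = dict(d.pop(key))
            if key == "data" and isinstance(v.get("synth"), dict):
                v["synth"] = SynthConfig(**{k: tuple(x) if isinstance(x, list)
                                            else x for k, x in v["synth"].items()})
            v = {k: tuple(x) if isinstance(x, list) else x for k, x in v.items()}
            kwargs[key] = cls(**v)
    kwargs.update(d)
    return RunConfig(**kwargs)


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return run_config_from_dict(yaml.safe_load(fh) or {})


def config_hash(cfg: RunConfig) -> str:
    """Content hash of the fully resolved configuration."""
    canon = yaml.safe_dump(to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
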