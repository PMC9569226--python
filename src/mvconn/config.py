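"""Run configuration: one YAML file carrying every stage's parameters.

Unknown keys are rejected by name, defaults are filled in, and the effective
configuration can be echoed back to disk verbatim so every run records the
settings that produced it.  A single master seed fans out to per-stage seeds
by fixed offsets so stages are individually reproducible without colliding.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .encoder import EncoderSpec
from .network import FusionSpec, TrainConfig
from .prototypes import LossConfig

__all__ = ["RunConfig", "parse_config", "echo_config", "derive_seed"]

_STAGE_OFFSETS = {"cv": 0, "selection": 101, "pretrain": 211,
                  "train": 307, "synth": 401}


def derive_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: master seed plus a fixed, documented stage offset."""
    if stage not in _STAGE_OFFSETS:
        raise ValueError(f"unknown stage {stage!r}")
    return int(master_seed) + _STAGE_OFFSETS[stage]


@dataclass
class RunConfig:
    """Validated configuration tree for a full run."""

    selection: dict = field(default_factory=dict)
    encoder: dict = field(default_factory=dict)
    fusion: dict = field(default_factory=dict)
    loss: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    io: dict = field(default_factory=dict)

    def encoder_spec(self) -> EncoderSpec:
        return EncoderSpec(**self.encoder) if self.encoder else EncoderSpec()

    def fusion_spec(self) -> FusionSpec:
        return FusionSpec(**self.fusion) if self.fusion else FusionSpec()

    def loss_config(self) -> LossConfig:
        return LossConfig(**self.loss) if self.loss else LossConfig()

    def train_config(self) -> TrainConfig:
        return TrainConfig(**self.train) if self.train else TrainConfig()


_SCHEMA: dict[str, set[str]] = {
    "selection": {"a1", "lam", "max_iter", "tol", "standardize"},
    "encoder": {"layer_widths", "activation", "pretrain", "pretrain_epochs",
                "pretrain_lr"},
    "fusion": {"mode", "position", "K", "pairing"},
    "loss": {"gamma", "margin", "lambda1", "lambda2"},
    "train": {"batch_size", "learning_rate", "epochs", "seed"},
    "cv": {"seed", "positive_class"},
    "io": {"views", "labels", "out_dir"},
}

_DEFAULTS: dict[str, dict] = {
    "selection": {"a1": 0.2, "lam": 1.0, "max_iter": 5000, "tol": 1e-7,
                  "standardize": True},
    "encoder": {},
    "fusion": {},
    "loss": {},
    "train": {},
    "cv": {"seed": 0, "positive_class": 1},
    "io": {},
}


def _validate(tree: dict) -> RunConfig:
    if not isinstance(tree, dict):
        raise ValueError("config root must be a mapping")
    unknown_sections = set(tree) - set(_SCHEMA)
    if unknown_sections:
        raise ValueError(f"unknown config section(s): {sorted(unknown_sections)}")
    filled: dict[str, dict] = {}
    for section, allowed in _SCHEMA.items():
        body = tree.get(section) or {}
        if not isinstance(body, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        unknown = set(body) - allowed
        if unknown:
            raise ValueError(
                f"unknown key(s) in section {section!r}: "
                f"{sorted(section + '.' + k for k in unknown)}")
        merged = dict(_DEFAULTS[section])
        merged.update(body)
        if section == "encoder" and "layer_widths" in merged:
            merged["layer_widths"] = tuple(merged["layer_widths"])
        filled[section] = merged
    cfg = RunConfig(**filled)
    # construct every sub-config once so type errors surface at parse time
    cfg.encoder_spec(), cfg.fusion_spec(), cfg.loss_config(), cfg.train_config()
    return cfg


def parse_config(path) -> RunConfig:
    """Load, validate and default-fill a YAML run configuration."""
    text = Path(path).read_text()
    tree = yaml.safe_load(text) or {}
    return _validate(tree)


def echo_config(cfg: RunConfig, path) -> None:
    """Write the effective configuration; parse(echo(cfg)) round-trips."""
    tree = asdict(cfg)
    tree["encoder"] = dict(tree["encoder"])
    if "layer_widths" in tree["encoder"]:
        tree["encoder"]["layer_widths"] = list(tree["encoder"]["layer_widths"])
    Path(path).write_text(yaml.safe_dump(tree, sort_keys=True))
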