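"""Experiment configuration: one YAML/JSON file with `network`, `loss`
and `train` blocks mapped onto the corresponding dataclasses."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .losses import LossConfig
from .model import NetworkConfig
from .training import TrainConfig

__all__ = ["load_experiment_config", "dump_experiment_config"]


def load_experiment_config(path) -> TrainConfig:
    path = Path(path)
    text = path.read_text()
    obj = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    obj = obj or {}
    network = NetworkConfig(**obj.get("network", {}))
    loss = LossConfig(**obj.get("loss", {}))
    train = dict(obj.get("train", {}))
    return TrainConfig(network=network, loss=loss, **train)


def dump_experiment_config(cfg: TrainConfig, path) -> None:
    obj = {
        "network": cfg.network.to_dict(),
        "loss": {"gamma": cfg.loss.gamma, "alpha": cfg.loss.alpha,
                 "epsilon": cfg.loss.epsilon, "dice_classes": cfg.loss.dice_classes},
        "train": {"learning_rate": cfg.learning_rate, "batch_size": cfg.batch_size,
                  "max_epochs": cfg.max_epochs, "lr_floor": cfg.lr_floor,
                  "schedule_period": cfg.schedule_period,
                  "early_stop_patience": cfg.early_stop_patience,
                  "seed": cfg.seed, "side": cfg.side},
    }
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
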