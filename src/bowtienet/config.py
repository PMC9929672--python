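"""Run configuration: every experiment parameter with its study default.

Defaults are the printed constants of the study design: 15 classes, 30
inputs, noise S = 20, 1000 samples per class with a 1/3 validation split,
600 training epochs, 10 replicates, 80,000 masked predictions on the
20-node model.  The ``smoke`` profile scales replication and epochs down
for quick end-to-end runs on one CPU.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from bowtienet.sweeps import (
    DEFAULT_IO_CONFIGS, DEFAULT_NOISE_LEVELS, DEFAULT_WIDTH_GRID,
)

__all__ = ["RunConfig", "load_config", "save_config", "EXPERIMENTS"]

EXPERIMENTS = ("generate", "sweep", "noise", "iosweep", "mask", "prune")


@dataclass
class RunConfig:
    experiment: str = "sweep"
    # generator
    n_classes: int = 15
    n_dims: int = 30
    S: float = 20.0
    n_per_class: int = 1000
    validation_fraction: float = 1.0 / 3.0
    masked_fraction: float = 0.5
    lo_value: float = 0.3
    hi_value: float = 0.7
    # training
    epochs: int = 600
    learning_rate: float = 1e-3
    batch_size: int = 128
    # sweeps
    widths: list[int] = field(default_factory=lambda: list(DEFAULT_WIDTH_GRID))
    regimes: list[str] = field(
        default_factory=lambda: ["pre_evolved", "post_evolved", "transfer"])
    n_replicates: int = 10
    noise_levels: list[float] = field(
        default_factory=lambda: list(DEFAULT_NOISE_LEVELS))
    io_configs: list[list[int]] = field(
        default_factory=lambda: [list(p) for p in DEFAULT_IO_CONFIGS])
    # masking / pruning (the 30-input/30-class, 20-node model)
    mask_model_width: int = 20
    mask_rates: list[float] = field(
        default_factory=lambda: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
    n_predictions: int = 80_000
    prune_fractions: list[float] = field(
        default_factory=lambda: [0.0, 0.25, 0.5, 0.75])
    # bookkeeping
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> "RunConfig":
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}")
        if self.S <= 0 or any(s <= 0 for s in self.noise_levels):
            raise ValueError("noise level S must be positive")
        if self.n_classes < 2 or self.n_dims < 1:
            raise ValueError("need n_classes >= 2 and n_dims >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if not 0 <= self.masked_fraction <= 1:
            raise ValueError("masked_fraction must lie in [0, 1]")
        if self.epochs < 0 or self.n_replicates < 1:
            raise ValueError("epochs must be >= 0 and n_replicates >= 1")
        if not self.widths:
            raise ValueError("widths grid must be non-empty")
        return self

    def apply_profile(self, profile: str) -> "RunConfig":
        """``paper`` keeps the study defaults; ``smoke`` scales down for a
        quick single-CPU end-to-end run."""
        if profile == "paper":
            return self
        if profile == "smoke":
            self.epochs = min(self.epochs, 100)
            self.n_replicates = min(self.n_replicates, 2)
            self.widths = [h for h in self.widths if h in (1, 2, 5, 10, 15, 20, 30)] \
                or self.widths
            self.noise_levels = [s for s in self.noise_levels if s in (10, 70)] \
                or self.noise_levels
            self.n_predictions = min(self.n_predictions, 20_000)
            return self
        raise ValueError(f"unknown profile {profile!r}; choose paper or smoke")


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
    return path


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw).validate()
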