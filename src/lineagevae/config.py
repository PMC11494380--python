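"""Model and pipeline configuration.

Defaults mirror the settings used on the hematopoiesis lineage-tracing data:
a 10-dimensional latent space, encoder/decoder/dynamics networks with two
hidden layers of 50 units and layer normalization, Adam+AMSGrad at learning
rate 1e-4, single-lineage minibatches of at most 30 cells, one backward step
per observed day, 1000 highly variable genes and a lineage filter of strictly
more than 20 cells.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["ModelConfig", "RunConfig"]


def _strict_from_mapping(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; known keys are "
            f"{sorted(known)}"
        )
    return cls(**mapping)


@dataclass
class ModelConfig:
    """Hyperparameters of the model and its two-phase training procedure."""

    latent_dim: int = 10
    hidden: tuple[int, int] = (50, 50)
    layer_norm: bool = True
    epochs_phase1: int = 200
    epochs_phase2: int = 200
    lr: float = 1e-4
    batch_size: int = 30
    steps_per_day: int = 1
    prior_mode: str = "standard"  # "standard" (N(0, sigma0^2 I)) or "anchored"
    velocity: bool = False
    delta_t: float = 1.0
    learn_kinetics: bool = True
    encoder_input: str = "log1p"  # "log1p" (log1p(x/chi)) or "raw"
    unspliced_layer: str = "unspliced"
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden = tuple(int(h) for h in self.hidden)
        if self.prior_mode not in {"standard", "anchored"}:
            raise ValueError("prior_mode must be 'standard' or 'anchored'")
        if self.encoder_input not in {"log1p", "raw"}:
            raise ValueError("encoder_input must be 'log1p' or 'raw'")
        if self.latent_dim < 1 or self.batch_size < 1 or self.steps_per_day < 1:
            raise ValueError("latent_dim, batch_size and steps_per_day must be >= 1")
        if self.lr <= 0 or self.delta_t <= 0:
            raise ValueError("lr and delta_t must be positive")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ModelConfig":
        return _strict_from_mapping(cls, dict(mapping))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden"] = list(self.hidden)
        return d


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate -> ... -> evaluate)."""

    seed: int = 0
    outdir: str = "lineagevae_run"
    stages: tuple[str, ...] = (
        "simulate", "preprocess", "train", "infer", "reconstruct",
        "tf-activity", "dynamics-norm", "evaluate",
    )
    model: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    n_top_genes: int | None = None  # None: keep all simulated genes
    min_lineage_cells: int = 20
    require_day: int | None = None
    knn_k: int = 30
    ridge: float = 1e-3
    n_traj_samples: int = 1
    verbosity: str = "INFO"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        cfg = _strict_from_mapping(cls, dict(mapping))
        cfg.stages = tuple(cfg.stages)
        # validate nested configs eagerly so typos fail before any work runs
        ModelConfig.from_mapping(cfg.model)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    def model_config(self) -> ModelConfig:
        kwargs = dict(self.model)
        kwargs.setdefault("seed", self.seed)
        return ModelConfig.from_mapping(kwargs)
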