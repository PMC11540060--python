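"""Run configuration: every tunable of the pipeline in one flat record.

Defaults are the operating point of the method: fusion weight alpha = 0.28,
embedding dimension 128, two multi-neighborhood layers over neighborhood
orders 0..4, Adam-style optimisation at lr 1e-3 with weight decay 1e-5 for
2000 epochs.  Config files are flat YAML key-value mappings; unknown keys
are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "ConfigError"]

ABLATIONS = ("full", "SF", "Hom", "Het", "JK", "Dec")
NEG_STRATEGIES = ("random", "kmeans")


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class RunConfig:
    # similarity fusion
    alpha: float = 0.28          # convex weight of the diffused similarity vs FS/DS
    knn_divisor: int = 10        # neighbors per row = floor(N / knn_divisor), min 1
    fusion_tol: float = 1e-6     # relative Frobenius stopping tolerance
    fusion_max_iter: int = 1000
    renormalize_views: bool = True   # re-apply row normalization between iterations

    # encoders
    layer_size: int = 128        # embedding dimension after every encoder stage
    n_hetero_layers: int = 2     # multi-neighborhood GCN depth
    k_neighborhood: int = 4      # max power of the propagation operator (orders 0..k)
    literal_normalization: bool = False  # D^-1/2 G D^+1/2 instead of symmetric
    hetero_self_loops: bool = True       # add I to the bipartite block graph
    jk_learnable: bool = True    # layer-aggregation weights trained vs fixed 1/l

    # optimisation
    lr: float = 0.001
    wd: float = 1e-5
    epochs: int = 2000
    seed: int = 0
    loss_reduction: str = "sum"  # "sum" as defined, or "mean"

    # negative sampling / evaluation
    neg_strategy: str = "random"
    n_neg_clusters: int = 10     # k-means clusters for the "kmeans" strategy
    ablation: str = "full"
    threshold: float = 0.5       # cutoff for ACC/Pre/Recall/F1

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.fusion_tol <= 0:
            raise ConfigError("fusion_tol must be positive")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if self.layer_size < 1 or self.n_hetero_layers < 1:
            raise ConfigError("layer_size and n_hetero_layers must be >= 1")
        if self.k_neighborhood < 0:
            raise ConfigError("k_neighborhood must be >= 0")
        if self.knn_divisor < 1:
            raise ConfigError("knn_divisor must be >= 1")
        if self.ablation not in ABLATIONS:
            raise ConfigError(
                f"ablation must be one of {ABLATIONS}, got {self.ablation!r}"
            )
        if self.neg_strategy not in NEG_STRATEGIES:
            raise ConfigError(
                f"neg_strategy must be one of {NEG_STRATEGIES}, "
                f"got {self.neg_strategy!r}"
            )
        if self.loss_reduction not in ("sum", "mean"):
            raise ConfigError("loss_reduction must be 'sum' or 'mean'")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must be in (0, 1)")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML config file into a validated :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
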