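"""Structured run configuration: one YAML file drives the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .network import PathEnumerationConfig
from .objective import ObjectiveParams
from .solver import SolverConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Inputs, parameters and output location for an end-to-end run.

    Signature-derivation parameters follow the published study defaults:
    k=100 candidate sources per condition, d=100 knock-down-derived extra TF
    targets, hub filter over the top 100 of background rankings, and a DE
    threshold of |z| >= 2.
    """

    network: str = "network.tsv"
    signatures: str = "signatures.tsv"
    metadata: str = "metadata.tsv"
    gene_sets: str = "gene_sets.gmt"
    outdir: str = "results"
    objective: ObjectiveParams = field(default_factory=ObjectiveParams)
    paths: PathEnumerationConfig = field(default_factory=PathEnumerationConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    z_threshold: float = 2.0
    k_sources: int = 100
    d_extension: int = 100
    correlation_mode: str = "positive"
    correlation_method: str = "spearman"
    filter_top_n: int = 100
    background_rankings: list[str] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def resolve(self, base: Path) -> "RunConfig":
        """Resolve input paths relative to ``base`` (the config location)."""
        for attr in ("network", "signatures", "metadata", "gene_sets", "outdir"):
            p = Path(getattr(self, attr))
            if not p.is_absolute():
                setattr(self, attr, str(base / p))
        self.background_rankings = [
            str(base / p) if not Path(p).is_absolute() else p
            for p in self.background_rankings
        ]
        return self


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for key, value in raw.items():
        if key == "objective":
            cfg.objective = ObjectiveParams(**value)
        elif key == "paths":
            cfg.paths = PathEnumerationConfig(**value)
        elif key == "solver":
            cfg.solver = SolverConfig(**value)
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
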