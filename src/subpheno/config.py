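"""Structured pipeline configuration with validation and provenance hashing.

A single :class:`PipelineConfig` holds every numeric threshold the stages
use, so any run can stamp the resolved configuration into its outputs.
Flags and YAML files both populate the same object; CLI flags override the
file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # growth classification
    threshold_sd: float = 1.5
    so_percentile: float = 90.0
    ratio_cutoff: float = 0.7
    # trio variant filtering
    max_af: float = 0.002
    pli_cutoff: float = 0.9
    # network expansion / enrichment
    top_k: int = 10
    min_combined_score: int = 0
    # single-cell QC
    mito_ribo_max: float = 5.0
    min_features: int = 200
    nfeat_sd: float = 2.0
    # single-cell normalization / clustering
    n_pcs: int = 30
    n_variable_genes: int = 5000
    k_broad: int = 10
    k_brain: int = 18
    # differential expression
    logfc_floor: float = 0.1
    min_pct_de: float = 0.01
    min_pct_markers: float = 0.2
    return_thresh: float = 0.01
    expression_floor: float = 0.0001
    alpha: float = 0.05
    # morphometrics
    bonferroni_family: int | None = None
    # randomness
    seed: int = 0
    # stage toggles
    stages: tuple = ("simulate", "classify", "denovo", "network", "morpho", "sc")

    _RANGES = {
        "threshold_sd": (0.0, 10.0),
        "so_percentile": (0.0, 100.0),
        "ratio_cutoff": (0.0, 1.0),
        "max_af": (0.0, 0.5),
        "pli_cutoff": (0.0, 1.0),
        "mito_ribo_max": (0.0, 100.0),
        "alpha": (0.0, 1.0),
        "min_pct_de": (0.0, 1.0),
        "min_pct_markers": (0.0, 1.0),
        "expression_floor": (0.0, 1.0),
    }

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            value = getattr(self, name)
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside valid range [{lo}, {hi}]")
        for name in ("top_k", "n_pcs", "n_variable_genes", "k_broad", "k_brain",
                     "min_features"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        return d

    @property
    def hash(self) -> str:
        """Stable short digest of the resolved configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)
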