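"""Pipeline configuration: every protocol cut-off in one place.

Defaults are the study protocol values (trim windows, filter orders and
cut-offs, MSA threshold 0.5, complex-loading threshold 0.4, Kaiser 1.0,
selection alpha 0.1, classification threshold 0.5). A YAML file with any
subset of the keys overrides them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .features import ExtractionConfig
from .synthetic import CohortSpec

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    msa_threshold: float = 0.5
    loading_threshold: float = 0.4
    kaiser: float = 1.0
    selection_alpha: float = 0.1
    classification_threshold: float = 0.5
    model_choice: str = "reduced"  # which model classifies: full | reduced
    registry_path: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in (
            "msa_threshold",
            "loading_threshold",
            "selection_alpha",
            "classification_threshold",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.kaiser <= 0:
            raise ValueError("kaiser threshold must be > 0")
        if self.model_choice not in ("full", "reduced"):
            raise ValueError("model_choice must be 'full' or 'reduced'")
        # one seed drives everything
        self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _apply(obj, overrides: dict) -> None:
    for key, val in overrides.items():
        if not hasattr(obj, key):
            raise ValueError(f"unknown config key {key!r} for {type(obj).__name__}")
        current = getattr(obj, key)
        if isinstance(val, dict) and not isinstance(current, dict):
            _apply(current, val)
        elif isinstance(current, tuple) and isinstance(val, list):
            setattr(obj, key, tuple(val))
        else:
            setattr(obj, key, val)


def load_config(path=None, seed: int | None = None) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file and a seed
    override."""
    cfg = PipelineConfig()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        _apply(cfg, data)
        cfg.__post_init__()  # re-validate after overrides
    if seed is not None:
        cfg.seed = seed
        cfg.cohort.seed = seed
    return cfg
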