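"""Run configuration: every tunable of the pipeline with a documented default."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, Optional

import yaml

from .preprocessing import HuRanges

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # preprocessing
    hu_ranges: HuRanges = field(default_factory=HuRanges)
    reference_hu: float = 50.0        # muscle-median normalization target
    sigma_mm: float = 1.0             # Gaussian smoothing width
    target_spacing_mm: float = 1.0    # isotropic resampling edge
    # model building
    screening_alpha: float = 0.1
    vif_max: float = 10.0
    r_max: float = 0.8
    train_fraction: float = 0.7
    threshold_rule: str = "youden"    # operating point chosen on training only
    # simulation (end-to-end runs)
    n_subjects: int = 60
    seed: int = 0
    # paths
    out_dir: str = "run_output"
    image: Optional[str] = None
    muscle_compartment: Optional[str] = None
    subcut_compartment: Optional[str] = None

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["hu_ranges"] = dataclasses.asdict(self.hu_ranges)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: str | os.PathLike | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    data: Dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    hr = data.pop("hu_ranges", None)
    cfg = RunConfig(**data)
    if hr is not None:
        cfg.hu_ranges = HuRanges(**hr)
    return cfg
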