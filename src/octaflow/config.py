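"""Pipeline configuration: defaults, YAML files, and flag overrides.

Precedence is CLI flags > config file > built-in defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from octaflow.doppler import ScanMeta
from octaflow.segmentation import DEFAULT_SCALE_MM

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline in one place."""

    scale_mm_per_px: float = DEFAULT_SCALE_MM
    min_length_px: int = 10
    kmeans_k: int = 2
    fractal_window: int = 3
    fdr_low: float = 0.3
    fdr_high: float = 0.7
    scan_meta: ScanMeta = field(default_factory=ScanMeta)
    quality_min: float = 3.0
    covariates: tuple[str, ...] = ("map", "laterality")
    out_dir: str = "octaflow_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_low < self.fdr_high < 1:
            raise ValueError("FDR thresholds must satisfy 0 < low < high < 1")
        if self.quality_min < 0:
            raise ValueError("quality_min must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        meta = raw.pop("scan_meta", None)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        cfg = cls(**raw)
        if meta is not None:
            cfg.scan_meta = ScanMeta(**meta)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        """Short stable hash of the full configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
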