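"""Run configuration: validated, fully serializable to/from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .classify import ClassificationConfig
from .trajectory import DEFAULT_REGIONS

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a simulate/analyze run needs, in one validated object."""

    preset: str = "smoke"  # synthetic cohort name, or "" when reading inputs
    input_dir: str = ""  # trajectory/energy files, used when preset == ""
    out_dir: str = "results"
    seed: int = 0
    n_pcs: int = 3
    fel_bins: int = 50
    kT: float = 1.0
    well_bandwidth: float = 0.5  # PC units, Gaussian smoothing for well detection
    fallback_boundary: float = 0.0  # used if the GDP PC1 profile is unimodal
    n_ref_samples: int = 100  # evenly selected frames for reference RMSD
    embedding_method: str = "umap_default"
    trajectory_format: str = "frames_table"
    log_level: str = "INFO"
    regions: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_REGIONS.items()})
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    n_frames_override: int | None = None  # shrink preset cohorts (quick runs)
    n_residues_override: int | None = None

    def __post_init__(self) -> None:
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.fel_bins < 2:
            raise ValueError("fel_bins must be >= 2")
        if self.embedding_method not in ("umap_default", "pca_fallback"):
            raise ValueError(f"unknown embedding method {self.embedding_method!r}")
        if not self.preset and not self.input_dir:
            raise ValueError("either a synthetic preset or an input_dir is required")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["classification"] = asdict(self.classification)
        data["classification"]["hotspots"] = list(self.classification.hotspots)
        data["classification"]["families"] = list(self.classification.families)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cc = data.pop("classification", {})
        cc["hotspots"] = tuple(cc.get("hotspots", (12, 13, 61)))
        cc["families"] = tuple(
            cc.get("families", ClassificationConfig().families)
        )
        return cls(classification=ClassificationConfig(**cc), **data)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, classification=replace(self.classification, seed=seed))
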