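"""Analysis configuration.

All tunable parameters of the pipeline live in :class:`AnalysisConfig` so a
run is fully determined by (config, inputs, seed).  The defaults encode the
published analysis choices: a 30 μm proximity radius, intensity-tertile
stratification of checkpoint-positive cells pooled across the cohort, and a
kernel-density tumor/stroma delineation with a 30 μm bandwidth.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import SchemaError

#: Marker panel, in canonical order.  pan-CK flags tumor (epithelial) cells,
#: CD163 macrophages, CD8 cytotoxic T cells, FoxP3 regulatory-phenotype
#: T cells; PD-1/PD-L1 are the checkpoint receptor/ligand.
MARKERS = ("panCK", "CD163", "CD8", "FoxP3", "PD1", "PDL1")

#: Checkpoint markers that get low/mid/high tertile stratification.
CHECKPOINT_MARKERS = ("PD1", "PDL1")

DEFAULT_THRESHOLD = 4.4817  # exp(1.5): midpoint of the default bimodal log-intensity model


@dataclass
class RegionParams:
    """Parameters of the KDE tumor/stroma delineation."""

    grid_step_um: float = 10.0
    kde_bandwidth_um: float = 30.0
    threshold_fraction: float = 0.10  # tumor mask cut as a fraction of peak density
    min_region_area_um2: float = 2500.0

    def validate(self) -> None:
        if self.grid_step_um <= 0:
            raise SchemaError("grid_step_um must be > 0")
        if self.kde_bandwidth_um <= 0:
            raise SchemaError("kde_bandwidth_um must be > 0")
        if not 0 < self.threshold_fraction <= 1:
            raise SchemaError("threshold_fraction must be in (0, 1]")
        if self.min_region_area_um2 < 0:
            raise SchemaError("min_region_area_um2 must be >= 0")


@dataclass
class AnalysisConfig:
    """Run-level configuration; round-trips through YAML."""

    #: per-marker positivity thresholds, intensity units (threshold-inclusive)
    thresholds: dict[str, float] = field(
        default_factory=lambda: {m: DEFAULT_THRESHOLD for m in MARKERS}
    )
    #: proximity radius r, μm
    proximity_radius_um: float = 30.0
    #: tertile boundaries pooled over the whole cohort or computed per slide
    tertile_scope: str = "cohort"
    region: RegionParams = field(default_factory=RegionParams)
    #: Mann-Whitney: exact null enumeration up to this per-group n (no ties)
    mw_exact_max_n: int = 8
    #: Cox partial-likelihood tie handling: "breslow" or "efron"
    cox_ties: str = "breslow"
    #: rename mapping applied to raw CSV headers (HALO-style exports)
    column_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.region, dict):
            self.region = RegionParams(**self.region)
        self.validate()

    def validate(self) -> None:
        missing = [m for m in MARKERS if m not in self.thresholds]
        if missing:
            raise SchemaError(f"thresholds missing for markers: {missing}")
        if any(t <= 0 for t in self.thresholds.values()):
            raise SchemaError("all positivity thresholds must be > 0")
        if self.proximity_radius_um <= 0:
            raise SchemaError("proximity_radius_um must be > 0")
        if self.tertile_scope not in ("cohort", "slide"):
            raise SchemaError("tertile_scope must be 'cohort' or 'slide'")
        if self.cox_ties not in ("breslow", "efron"):
            raise SchemaError("cox_ties must be 'breslow' or 'efron'")
        self.region.validate()

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the configuration, for the run manifest."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
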