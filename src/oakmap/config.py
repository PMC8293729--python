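"""Pipeline configuration: one dataclass tree, YAML round-trippable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = [
    "SimulationParams",
    "PrepParams",
    "FitParams",
    "FilterParams",
    "ValidateParams",
    "PipelineConfig",
]


@dataclass
class SimulationParams:
    n_rows: int = 160
    n_cols: int = 240
    pixel_size: float = 50.0
    region_count: int = 3
    roughness: float = 350.0
    min_stand_area: float = 5.0
    max_stand_area: float = 30.0
    niche_coefficients: dict = field(
        default_factory=lambda: {"AT": 1.5, "CMD": -0.5, "DAMS": -1.0, "TWI": 0.4, "SMR": 0.3, "SNR": 0.3}
    )
    intercept: float = 0.0
    dem_optimum: float = 150.0
    dem_tolerance: float = 90.0
    management_bias: float = 120.0
    occupancy_area_fraction: float = 0.25
    estate_fraction: float = 0.35
    area_noise_sd: float = 0.0
    sample_fraction: float = 0.006
    min_sample_stands: int = 20
    n_validation_sites: int = 64
    export_geojson: bool = True


@dataclass
class PrepParams:
    oak_min_pct: float = 60.0
    oak_max_pct: float = 10.0
    presence_fraction: float = 0.5
    k_replicates: int = 15
    r_threshold: float = 0.7
    vif_threshold: float = 10.0
    training_ownership: str = "public"  # PFE-style training subset


@dataclass
class FitParams:
    algorithms: tuple = ("glm", "gbm", "rf", "ann")
    n_repeats: int = 30
    split: float = 0.5
    min_converged_fraction: float = 0.5
    per_algorithm_weighting: bool = False


@dataclass
class FilterParams:
    area_mode: str = "floor"
    apply_manual_adjustment: bool = False
    quota_scale: str = "area_target"  # or "none": use raw sample counts


@dataclass
class ValidateParams:
    p0: float = 0.5
    confidence: float = 0.95


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "oakmap_run"
    quiet: bool = False
    simulation: SimulationParams = field(default_factory=SimulationParams)
    prep: PrepParams = field(default_factory=PrepParams)
    fit: FitParams = field(default_factory=FitParams)
    filter: FilterParams = field(default_factory=FilterParams)
    validate: ValidateParams = field(default_factory=ValidateParams)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit"]["algorithms"] = list(d["fit"]["algorithms"])
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {
            "simulation": SimulationParams,
            "prep": PrepParams,
            "fit": FitParams,
            "filter": FilterParams,
            "validate": ValidateParams,
        }
        kwargs: dict = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            if f.name in sections:
                section_cls = sections[f.name]
                known = {x.name for x in fields(section_cls)}
                extra = set(data[f.name]) - known
                if extra:
                    raise ValueError(f"unknown config key(s) in {f.name}: {sorted(extra)}")
                kwargs[f.name] = section_cls(**data[f.name])
            else:
                kwargs[f.name] = data[f.name]
        extra = set(data) - {f.name for f in fields(cls)}
        if extra:
            raise ValueError(f"unknown config key(s): {sorted(extra)}")
        cfg = cls(**kwargs)
        cfg.fit.algorithms = tuple(cfg.fit.algorithms)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
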