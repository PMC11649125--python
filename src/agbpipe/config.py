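"""Pipeline configuration: a single YAML file, validated up front.

Every stage parameter lives here with its default, and the resolved values
are echoed into the run manifest so a run is fully reconstructible from its
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

ALL_STAGES = ("generate", "preprocess", "npp", "agb", "gi", "trends", "attribute")


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "results/run"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    # synthetic scenario
    scenario: dict = field(default_factory=dict)

    # preprocessing
    iqr_k: float = 1.5
    sg_window: int = 5
    sg_order: int = 2

    # CASA
    casa_params_csv: str | None = None
    water_mode: str = "pet"          # "pet" or "soil-moisture"

    # allocation / grazing
    allocation_strategy: str = "carbon_partition"
    allocation_table_csv: str | None = None
    daily_intake_p: float = 1800.0
    grazing_days_t: float = 365.0

    # trends / stability
    slope_threshold: float = 0.5     # g/m²/yr half-width of the stable band
    alpha: float = 0.05
    cv_breaks: object = "quantile"

    # attribution
    n_trees: int = 1000
    rf_unit: str = "pixel"           # or "pixel-year"

    # optional sub-period (start year, end year) restriction for trends
    period: list[int] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    for stage in cfg.stages:
        if stage not in ALL_STAGES:
            problems.append(f"stages: unknown stage {stage!r}")
    if cfg.sg_window % 2 == 0:
        problems.append("sg_window: window must be odd")
    if cfg.sg_order >= cfg.sg_window:
        problems.append("sg_order: order must be < window")
    if cfg.iqr_k <= 0:
        problems.append("iqr_k: must be > 0")
    if cfg.allocation_strategy not in ("carbon_partition", "literal"):
        problems.append(f"allocation_strategy: unknown {cfg.allocation_strategy!r}")
    if cfg.water_mode not in ("pet", "soil-moisture"):
        problems.append(f"water_mode: unknown {cfg.water_mode!r}")
    if cfg.daily_intake_p <= 0 or cfg.grazing_days_t <= 0:
        problems.append("grazing parameters must be positive")
    if cfg.slope_threshold < 0:
        problems.append("slope_threshold: must be non-negative")
    if not 0 < cfg.alpha < 1:
        problems.append("alpha: must lie in (0, 1)")
    if cfg.n_trees < 1:
        problems.append("n_trees: must be >= 1")
    if cfg.rf_unit not in ("pixel", "pixel-year"):
        problems.append(f"rf_unit: unknown {cfg.rf_unit!r}")
    for name in ("casa_params_csv", "allocation_table_csv"):
        path = getattr(cfg, name)
        if path is not None and not Path(path).exists():
            problems.append(f"{name}: file not found: {path}")
    if cfg.period is not None and (len(cfg.period) != 2
                                   or cfg.period[0] > cfg.period[1]):
        problems.append("period: must be [start_year, end_year]")
    return problems
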