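"""Pipeline configuration with the study's published defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one place.

    Defaults equal the published values where one exists: preservation
    screens C/S < 300 and N/S < 100, non-locality at 100 km, 10 folds x 5
    repeats with 80% training, assignment quantile q = 1/3, oxygen chain SD
    1.0 permil with the printed calibration coefficients.
    """

    # compilation
    column_map: dict = field(default_factory=dict)
    cs_max: float = 300.0
    ns_max: float = 100.0
    nonlocal_km: float = 100.0
    # model
    n_trees: int = 500
    max_features: str | int = "third"
    min_leaf: int = 5
    n_rank_forests: int = 10
    importance_sd_multiplier: float = 1.0
    addition_tolerance: float = 0.0
    folds: int = 10
    repeats: int = 5
    train_fraction: float | None = 0.8
    # oxygen conversion
    assume_input_scale: str = "VPDB"
    oxygen_uncertainty_mode: str = "quadrature"
    chain_sd: float = 1.0
    # assignment
    q: float = 1.0 / 3.0
    threshold_mode: str = "mass"   # or "area_fraction"
    subsets: str = "all"
    # reproducibility
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
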