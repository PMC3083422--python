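"""Run configuration: defaults, YAML round-trip, content hash."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "default_config"]


@dataclass
class RunConfig:
    """Every tunable of an end-to-end run, with embedded defaults.

    The defaults encode the study conditions: 28,000-probe arrays, four
    dose/time conditions in duplicate, four mice per group, 1.5-fold /
    two-condition / P<0.05 selection, and the multi-event model calibrated
    at the (0.2 Gy, 1 µm, F2 = 0.3%) reference point.
    """

    seed: int = 0

    # study design
    n_genes: int = 28000
    replicates_per_condition: int = 2
    mice_per_group: int = 4

    # noise model
    spot_sd: float = 0.1
    ct_sd: float = 0.15
    flag_rate: float = 0.02
    low_signal_rate: float = 0.01
    dye_bias_coeffs: tuple = (0.3, -0.1, 0.02, 0.01)
    densitometry_spread: float = 8.0
    densitometry_outlier_rate: float = 0.05

    # selection thresholds
    fold_threshold: float = 1.5
    min_conditions: int = 2
    alpha: float = 0.05
    lowess_span: float = 0.3
    lowess_iterations: int = 3
    t_mode: str = "pooled"
    heat_clip: float = 3.0

    # qPCR validation
    reference_gene: str = "Gapdh"
    calibrator_group: str = "sham"
    n_qpcr_genes_per_block: int = 2

    # microdosimetry scan
    doses: tuple = (0.2, 1.0)
    diameters: tuple = (0.25, 0.5, 1.0, 2.0, 7.0)
    ref_dose: float = 0.2
    ref_diameter: float = 1.0
    ref_f2: float = 0.003

    def __post_init__(self) -> None:
        for name in ("fold_threshold", "alpha", "lowess_span", "heat_clip"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_conditions < 1:
            raise ValueError("min_conditions must be >= 1")

    def to_yaml(self) -> str:
        data = asdict(self)
        for key in ("dye_bias_coeffs", "doses", "diameters"):
            data[key] = list(data[key])
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dye_bias_coeffs", "doses", "diameters"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    @property
    def header_comment(self) -> str:
        return f"config={self.config_hash} seed={self.seed}"


def default_config(seed: int = 0, **overrides) -> RunConfig:
    return RunConfig(seed=seed, **overrides)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_yaml(Path(path).read_text())
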