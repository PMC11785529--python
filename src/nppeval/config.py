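"""Pipeline configuration with the method's constants as explicit defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end synthetic pipeline needs.

    Defaults encode the method's stated constants: a 26-year series with a
    20-year jackknife retention window, significance level 0.05, Huber
    ε = 1.35, driver-variance tolerance 1e-10, IQR fence k = 3, and the
    0.03 kg m⁻³ / 10 m mixed-layer density criterion.
    """

    # grid and time span
    n_lat: int = 18
    n_lon: int = 36
    lat_extent: float = 80.0
    year_start: int = 1998
    n_years: int = 26

    # statistical constants
    window: int = 20
    alpha: float = 0.05
    huber_eps: float = 1.35
    var_tol: float = 1e-10
    fence_k: float = 3.0
    density_criterion: float = 0.03  # kg m-3
    reference_depth: float = 10.0  # m

    # synthetic study conditions
    n_biomes: int = 6
    n_algorithms: int = 6  # observation-like data sources
    n_models: int = 15
    ar1_phi: float = 0.3
    noise_sd: float = 0.03
    shift_sd: float = 0.15
    ensemble_shifts: list[list[float]] | None = None  # explicit (n_models, 3) override
    ensemble_delta_npp: list[float] | None = None

    # plumbing
    seed: int = 0
    output_dir: str = "results"
    unit_constants: dict = field(
        default_factory=lambda: {
            "carbon_molar_mass": 12.011,
            "days_per_year": 365.0,
            "grams_per_pg": 1e15,
        }
    )

    def __post_init__(self) -> None:
        if self.window > self.n_years or self.window <= 0:
            raise ConfigurationError("window must be in (0, n_years]")
        if self.ensemble_shifts is not None:
            if len(self.ensemble_shifts) != self.n_models:
                raise ConfigurationError("ensemble_shifts must have n_models rows")
            if any(len(row) != 3 for row in self.ensemble_shifts):
                raise ConfigurationError("each ensemble shift needs one value per driver")
        if self.ensemble_delta_npp is not None and len(self.ensemble_delta_npp) != self.n_models:
            raise ConfigurationError("ensemble_delta_npp must have n_models entries")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"malformed config file {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
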