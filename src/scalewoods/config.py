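"""Configuration objects for the synthetic plot, the sampling design and the
random-forest tuning protocol.

All lengths are metres, diameters centimetres, masses kilograms unless a
field name says otherwise.  Every stochastic component is driven by a single
integer seed so that identical configurations reproduce byte-identical
output tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic two-census stem-mapped plot.

    Defaults emulate a 30-ha (500 x 600 m) temperate mixed forest censused
    twice five years apart, with corner elevations on a 20-m grid and
    fine-scale growth noise that averages out at coarse grains.
    """

    plot_x: float = 500.0
    plot_y: float = 600.0
    census_interval: float = 5.0
    grid_spacing: float = 20.0
    seed: int = 0
    n_species: int = 20
    stem_density: float = 0.1            # stems / m^2 with DBH >= 1 cm
    dbh_weibull_shape: float = 1.2
    dbh_weibull_scale: float = 12.0      # cm
    height_params: tuple[float, float] = (1.5, 0.7)   # H = 1.3 + a * DBH^b
    allometry_defaults: tuple[float, float] = (0.1, 2.4)  # AGB_kg = a * DBH^b
    allometry_species_jitter: float = 0.1
    growth_params: tuple[float, float, float] = (0.5, 0.4, 0.3)  # g0, g1, g2
    elev_growth_coef: float = 0.2
    noise_range: float = 15.0            # m, correlation range of growth noise
    noise_sd: float = 0.4                # lognormal sd of growth noise
    mortality_base: float = 0.05         # 5-yr probability
    recruit_density: float = 0.01        # new stems / m^2 per census
    elev_base: float = 680.0
    elev_amplitude: float = 100.0
    elev_range: float = 150.0            # m, correlation range of elevation field
    # Thomas-process clustering of each species' stems
    cluster_mean_offspring: float = 20.0
    cluster_sd: float = 15.0             # m, Gaussian dispersal around parents
    # geometric species-abundance series parameter
    abundance_k: float = 0.15

    def __post_init__(self) -> None:
        if self.plot_x <= 0 or self.plot_y <= 0:
            raise ConfigurationError("plot dimensions must be positive")
        for dim, name in ((self.plot_x, "plot_x"), (self.plot_y, "plot_y")):
            if abs(dim / self.grid_spacing - round(dim / self.grid_spacing)) > 1e-9:
                raise ConfigurationError(
                    f"{name}={dim} is not divisible by grid_spacing={self.grid_spacing}"
                )
        for p, name in (
            (self.mortality_base, "mortality_base"),
            (self.abundance_k, "abundance_k"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if self.stem_density < 0 or self.recruit_density < 0:
            raise ConfigurationError("densities must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("height_params", "allometry_defaults", "growth_params"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SamplingDesign:
    """Scale series and quadrat counts of the random spatial sampling design."""

    side_min: float = 10.0
    side_max: float = 200.0
    step: float = 5.0
    quadrats_per_scale: int = 100
    repetitions: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_max < self.side_min:
            raise ConfigurationError("side_max must be >= side_min")
        if self.step <= 0:
            raise ConfigurationError("step must be positive")
        if self.quadrats_per_scale < 1:
            raise ConfigurationError("quadrats_per_scale must be >= 1")
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")


@dataclass
class TuningProtocol:
    """Random-forest hyper-parameter tuning protocol.

    ntree candidates run from 500 to 7000 in steps of 500; the selected ntree
    is the first candidate whose forward OOB-error difference falls below the
    stationarity threshold (0.1, escalated by 0.05 until one qualifies).
    """

    ntree_min: int = 500
    ntree_max: int = 7000
    ntree_step: int = 500
    stationarity_threshold: float = 0.1
    threshold_increment: float = 0.05
    mtry_step_factor: float = 2.0
    mtry_improve: float = 0.05
    mtry_ntree_try: int = 100
    boruta_max_iter: int = 100
    boruta_alpha: float = 0.05
    boruta_n_estimators: int = 50
    train_fraction: float = 0.7
    importance_repeats: int = 3

    def __post_init__(self) -> None:
        if self.ntree_min <= 0 or self.ntree_step <= 0 or self.ntree_max < self.ntree_min:
            raise ConfigurationError("invalid ntree candidate range")
        if self.stationarity_threshold <= 0 or self.threshold_increment <= 0:
            raise ConfigurationError("stationarity threshold and increment must be positive")
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")

    @property
    def ntree_candidates(self) -> list[int]:
        return list(range(self.ntree_min, self.ntree_max + 1, self.ntree_step))
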