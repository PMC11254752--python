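"""Configuration objects for the synthetic landscape and the analysis run.

All analysis thresholds default to the published protocol values (beam
sensitivity 0.98/0.95, 20 deg slope cap, 5 m minimum canopy height, 120 m
edge width, 300 m fire buffer, 3,000 m intactness distance, 30/600 sample
minima, 500x300 resampling).  The simulator presets encode the reported
continental structure of intact tropical moist forest canopies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration cannot produce a valid simulation/run."""


@dataclass(frozen=True)
class RegionPreset:
    """Mean and SD of intact-forest top-of-canopy height (RH98, metres)."""

    name: str
    rh98_mean: float
    rh98_sd: float


#: Continental intact-forest canopy height presets (mean +- sd, metres).
REGION_PRESETS = {
    "americas": RegionPreset("americas", 28.6, 7.4),
    "africa": RegionPreset("africa", 29.3, 8.6),
    "asia": RegionPreset("asia", 34.4, 10.7),
}

METRICS = ("rh98", "rh50", "agbd")

#: fractional immediate structure loss per driver and metric
DEFAULT_DISTURBANCE_LOSS = {
    "fire": {"rh98": 0.30, "rh50": 0.50, "agbd": 0.40},
    "logging": {"rh98": 0.15, "rh50": 0.25, "agbd": 0.25},
}

#: recovery toward intact, percent of intact per year, per driver and metric
DEFAULT_RECOVERY_RATE = {
    "fire": {"rh98": 0.3, "rh50": 0.3, "agbd": 0.3},
    "logging": {"rh98": 0.5, "rh50": 0.5, "agbd": 0.5},
}

#: marginal probability that a footprint violates each quality rule
DEFAULT_CONTAMINATION = {
    "beam": 0.25,          # coverage instead of power beam
    "quality": 0.05,       # quality flag 0
    "degrade": 0.03,       # degrade flag 1
    "daynight": 0.35,      # day acquisition
    "sensitivity": 0.10,   # beam sensitivity below 0.95
    "sensitivity_marginal": 0.0,  # in (0.95, 0.98]: fails intact intent only
    "slope": 0.05,         # terrain slope above 20 deg
    "water": 0.01,
    "urban": 0.01,
    "height": 0.02,        # RH98 forced below the 5 m forest definition
}


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic tropical landscape.

    The edge-desiccation gradient multiplies intact canopy height by
    ``f(d) = 1 - A_e * exp(-d / lambda_e)`` with ``lambda_e = D95 /
    ln(A_e / 0.05)`` so that the 95%-of-intact criterion is met exactly at
    distance ``edge_depth_d95`` from the forest edge.
    """

    grid_size: int = 256
    pixel_size: float = 30.0
    year_start: int = 1990
    year_end: int = 2022
    region: str = "americas"
    # optional overrides of the preset intact-field moments (used by the
    # controlled parameter-recovery scenarios; None = use the preset)
    rh98_mean: float | None = None
    rh98_sd: float | None = None

    # edge-effect truth
    edge_magnitude: float = 0.20      # A_e, fractional deficit at d = 0
    edge_depth_d95: float = 400.0     # metres

    # disturbance truth
    disturbance_loss: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DISTURBANCE_LOSS.items()})
    recovery_rate: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RECOVERY_RATE.items()})
    regrowth_plateau: float = 0.6     # P, fraction of intact
    regrowth_timescale: float = 5.0   # tau, years

    # allometry and measurement model
    allometry_kappa: float = 0.8      # AGBD = kappa * RH98^gamma (Mg/ha)
    allometry_gamma: float = 1.7
    se_fraction: tuple = (0.05, 0.20)  # AGBD_SE / AGBD bounds
    agbd_lognormal_sd: float = 0.15
    rh50_ratio: float = 0.45
    rh50_ratio_sd: float = 0.03
    measurement_sd: float = 0.5       # metres, vertical accuracy of heights
    geolocation_sd: float = 11.0      # metres, horizontal accuracy
    min_height: float = 5.0           # metres, forest definition floor

    # landscape dynamics
    smoothing_length_px: float = 4.0  # autocorrelation of the intact field
    nonforest_strip_px: int = 14      # pre-1990 converted land (420 m strip)
    n_water_blobs: int = 1
    n_savannah_blobs: int = 1
    deforestation_rate: float = 0.04  # frontier conversion prob / yr
    regrowth_prob: float = 0.08       # per-pixel abandoned -> regrowth prob / yr
    abandonment_events_per_year: float = 0.5  # patch-wise farm abandonment
    fire_events_per_year: float = 1.0
    logging_events_per_year: float = 1.0
    event_radius_px: tuple = (2, 5)
    driver_zones: bool = False        # confine fire/logging to separate halves
    steep_patch_fraction: float = 0.02

    # footprint sampling
    n_footprints: int = 20000
    along_track_spacing: float = 60.0  # metres
    acquisition_years: tuple = (2019, 2020, 2021, 2022)
    contamination: dict = field(default_factory=lambda: dict(DEFAULT_CONTAMINATION))

    # deforestation-risk truth: logit(pi) = alpha + beta_h * pct + beta_d * d
    risk_alpha: float = 2.0
    risk_beta_height: float = -0.06   # per percent-of-intact
    risk_beta_distance: float = 0.0   # per metre

    seed: int = 0

    def __post_init__(self):
        if self.region not in REGION_PRESETS:
            raise ConfigurationError(f"unknown region preset {self.region!r}")
        if not (self.edge_magnitude == 0.0 or 0.05 < self.edge_magnitude < 1.0):
            raise ConfigurationError("edge_magnitude must be 0 or in (0.05, 1)")
        extent = self.grid_size * self.pixel_size
        if self.edge_depth_d95 <= 0:
            raise ConfigurationError("edge_depth_d95 must be positive")
        if self.edge_depth_d95 > extent / 2:
            raise ConfigurationError(
                f"edge_depth_d95={self.edge_depth_d95} m exceeds half the grid "
                f"extent ({extent / 2} m); enlarge grid_size"
            )
        for driver, losses in self.disturbance_loss.items():
            for metric, loss in losses.items():
                if not 0.0 <= loss <= 1.0:
                    raise ConfigurationError(f"loss[{driver}][{metric}] outside [0, 1]")
        if not 0.0 < self.regrowth_plateau <= 1.0:
            raise ConfigurationError("regrowth_plateau must be in (0, 1]")
        lo, hi = self.se_fraction
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("se_fraction bounds must satisfy 0 < lo <= hi < 1")
        for rule, frac in self.contamination.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"contamination[{rule}] outside [0, 1]")
        if self.year_end <= self.year_start:
            raise ConfigurationError("year_end must exceed year_start")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def preset(self) -> RegionPreset:
        return REGION_PRESETS[self.region]

    @property
    def intact_mean(self) -> float:
        return self.preset.rh98_mean if self.rh98_mean is None else self.rh98_mean

    @property
    def intact_sd(self) -> float:
        return self.preset.rh98_sd if self.rh98_sd is None else self.rh98_sd

    @property
    def edge_decay_length(self) -> float:
        """lambda_e (m); defined only for edge_magnitude > 0.05."""
        if self.edge_magnitude <= 0.05:
            return np.nan
        return self.edge_depth_d95 / np.log(self.edge_magnitude / 0.05)

    def edge_multiplier(self, distance_m):
        """Latent canopy multiplier f(d) at distance d (m) into the forest."""
        d = np.asarray(distance_m, dtype=float)
        if self.edge_magnitude == 0.0:
            return np.ones_like(d)
        return 1.0 - self.edge_magnitude * np.exp(-d / self.edge_decay_length)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["se_fraction"] = list(self.se_fraction)
        d["event_radius_px"] = list(self.event_radius_px)
        d["acquisition_years"] = list(self.acquisition_years)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        for key in ("se_fraction", "event_radius_px", "acquisition_years"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class GridSpec:
    """Square analysis grid cells keyed by lower-left corner.

    The published analysis uses 1.5 degree cells (~167 km); the synthetic
    landscape lives in a local metric CRS, so the cell size is given in
    metres and defaults to covering a quarter of the default grid.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 7680.0  # metres (the full default synthetic grid)

    def cell_index(self, x, y):
        ix = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        return ix, iy

    def cell_id(self, x, y):
        ix, iy = self.cell_index(x, y)
        if np.isscalar(x) or np.ndim(x) == 0:
            return f"{int(ix)}_{int(iy)}"
        return np.char.add(np.char.add(ix.astype(str), "_"), iy.astype(str))


@dataclass
class QCThresholds:
    """Quality-filter thresholds; defaults are the published protocol."""

    sensitivity_intact: float = 0.98
    sensitivity_other: float = 0.95
    max_slope_deg: float = 20.0
    min_rh98: float = 5.0

    # how AGBD_SE enters the biomass average: "inv_var" (1/SE^2, default),
    # "inv_se" (1/SE) or "se" (SE itself) for sensitivity analysis
    agbd_weighting: str = "inv_var"


@dataclass
class AnalysisThresholds:
    """Sample-size and significance thresholds of the protocol."""

    min_samples_per_band: int = 30
    min_samples_per_scope: int = 600
    min_samples_per_step: int = 30
    min_samples_per_cell: int = 600
    alpha: float = 0.05
    edge_width_m: float = 120.0
    intact_distance_m: float = 3000.0
    fire_buffer_m: float = 300.0
    erosion_radius_m: float = 35.0
    low_deforestation_fraction: float = 0.02
    resample_iterations: int = 500
    resample_size: int = 300
    mc_anova_iterations: int = 500


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
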