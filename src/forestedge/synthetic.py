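"""Synthetic tropical landscape and LiDAR footprint generator.

Produces annual change-class rasters (1990-2022), auxiliary rasters, and
footprint tables with fully known statistical structure, so every analysis
stage downstream can be validated against ground truth without any
satellite download.

What is emulated
----------------
* a spatially correlated intact canopy-height field (Gaussian-smoothed
  white noise rescaled to a continental mean/SD preset);
* deforestation fronts expanding stochastically from converted land, with
  abandonment and saturating secondary regrowth;
* fire and selective-logging degradation events that keep a pixel in the
  degraded class for at most three annual maps (the product's maximum
  2.5-year disturbed period, discretised to annual snapshots) and leave a
  dated degradation history behind;
* an edge-desiccation gradient f(d) = 1 - A_e exp(-d/lambda_e) applied to
  standing forest, calibrated so 95% of intact canopy height is reached at
  exactly d = D95;
* a power-law height-biomass allometry with per-footprint prediction SE;
* ~11 m isotropic geolocation error and per-rule metadata contamination so
  every quality filter can be exercised at a known rate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import expit
from shapely.geometry import box

from . import codes
from ._rng import substream
from .config import ConfigurationError, SimulationConfig
from .raster_io import GridGeometry, write_polygons, write_raster

logger = logging.getLogger(__name__)

__all__ = [
    "AnnualChangeStack",
    "TruthParameters",
    "simulate_landscape",
    "simulate_footprints",
    "simulate_risk_dataset",
    "write_fixture_bundle",
]


@dataclass
class AnnualChangeStack:
    """Per-year class rasters on a common 30 m grid."""

    years: np.ndarray                 # (n_years,)
    data: np.ndarray                  # (n_years, ny, nx) uint8 class codes
    geom: GridGeometry

    def __post_init__(self):
        self.years = np.asarray(self.years)
        if self.data.shape[0] != len(self.years):
            raise ValueError("stack depth does not match year range")

    def year_index(self, year: int) -> int:
        idx = int(np.searchsorted(self.years, year))
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"year {year} not in stack")
        return idx

    def classes(self, year: int) -> np.ndarray:
        return self.data[self.year_index(year)]

    def forest_mask(self, year: int) -> np.ndarray:
        cls = self.classes(year)
        return np.isin(cls, codes.FOREST_CLASSES)


@dataclass
class TruthParameters:
    """Realised ground truth of a simulation, sufficient to compute every
    downstream expected estimate independently of the analysis code."""

    config: SimulationConfig
    intact_rh98: np.ndarray           # latent intact canopy field (m)
    slope_deg: np.ndarray
    fire_year: np.ndarray             # 0 = never burned
    last_degradation_year: np.ndarray  # 0 = never degraded
    degradation_driver: np.ndarray     # codes.DRIVER_*
    deforestation_year: np.ndarray     # 0 = never/pre-1990
    regrowth_start_year: np.ndarray    # 0 = never
    logging_events: list = field(default_factory=list)  # (year, shapely box)
    footprint_truth: pd.DataFrame | None = None

    # -- closed-form expectations ------------------------------------
    def edge_multiplier(self, distance_m):
        return self.config.edge_multiplier(distance_m)

    def disturbance_multiplier(self, driver: str, metric: str, age):
        """Latent multiplier at 1-based age since the disturbance event."""
        loss = self.config.disturbance_loss[driver][metric]
        rate = self.config.recovery_rate[driver][metric]
        age = np.asarray(age, dtype=float)
        return np.minimum(1.0, (1.0 - loss) + rate / 100.0 * (age - 1.0))

    def regrowth_multiplier(self, age):
        """Saturating regrowth P(1 - exp(-age/tau)) at 1-based age."""
        cfg = self.config
        age = np.asarray(age, dtype=float)
        return cfg.regrowth_plateau * (1.0 - np.exp(-age / cfg.regrowth_timescale))

    def expected_percent(self, disturbance: str, metric: str, age):
        """Expected trajectory value (percent of intact) at 1-based age."""
        if disturbance == "regrowth":
            return 100.0 * self.regrowth_multiplier(age)
        return 100.0 * self.disturbance_multiplier(disturbance, metric, age)

    def to_json_dict(self) -> dict:
        d = {
            "config": self.config.to_dict(),
            "intact_rh98": np.round(self.intact_rh98, 4).tolist(),
            "slope_deg": np.round(self.slope_deg, 3).tolist(),
            "fire_year": self.fire_year.tolist(),
            "last_degradation_year": self.last_degradation_year.tolist(),
            "degradation_driver": self.degradation_driver.tolist(),
            "deforestation_year": self.deforestation_year.tolist(),
            "regrowth_start_year": self.regrowth_start_year.tolist(),
            "logging_events": [
                {"year": int(y), "bounds": list(poly.bounds)} for y, poly in self.logging_events
            ],
        }
        return d


def _random_blobs(rng, shape, n_blobs, radius_range, row_range=None):
    """Binary mask of n random disks (centres optionally row-restricted)."""
    mask = np.zeros(shape, dtype=bool)
    ny, nx = shape
    yy, xx = np.ogrid[:ny, :nx]
    for _ in range(n_blobs):
        r = rng.integers(radius_range[0], radius_range[1] + 1)
        lo, hi = (r, ny - r) if row_range is None else (max(r, row_range[0]),
                                                        min(ny - r, row_range[1]))
        cy = rng.integers(lo, hi)
        cx = rng.integers(r, nx - r)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def _smooth_field(rng, shape, smoothing_px, mean, sd):
    f = ndi.gaussian_filter(rng.standard_normal(shape), smoothing_px)
    f = (f - f.mean()) / f.std()
    return mean + sd * f


def simulate_landscape(config: SimulationConfig):
    """Simulate the annual change stack, auxiliary rasters and ground truth.

    Returns
    -------
    stack : AnnualChangeStack
    aux : dict of auxiliary rasters (``slope_deg``, ``fire_year``,
        ``water_mask``) plus ``logging_polygons``
    truth : TruthParameters
    """
    G = int(config.grid_size)
    if G < 16:
        raise ConfigurationError("grid_size too small to host landscape features")
    rng = substream(config.seed, "landscape")
    geom = GridGeometry(0.0, G * config.pixel_size, config.pixel_size)
    shape = (G, G)

    intact = np.clip(
        _smooth_field(rng, shape, config.smoothing_length_px,
                      config.intact_mean, config.intact_sd),
        config.min_height, None,
    )

    # terrain slope with optional steep (>20 deg) patches
    slope = np.clip(_smooth_field(rng, shape, 6.0, 8.0, 4.0), 0.0, None)
    if config.steep_patch_fraction > 0:
        steep_field = ndi.gaussian_filter(rng.standard_normal(shape), 6.0)
        thr = np.quantile(steep_field, 1.0 - config.steep_patch_fraction)
        slope[steep_field > thr] = rng.uniform(22.0, 35.0, int((steep_field > thr).sum()))

    # initial 1990 state: old converted land along one margin + natural features
    cls = np.full(shape, codes.UNDISTURBED, dtype=np.uint8)
    deforestation_year = np.zeros(shape, dtype=np.int16)
    if config.nonforest_strip_px > 0:
        cls[:, : config.nonforest_strip_px] = codes.DEFORESTED  # pre-1990 conversion
    water = _random_blobs(rng, shape, config.n_water_blobs, (3, 6))
    savannah = _random_blobs(rng, shape, config.n_savannah_blobs, (3, 6))
    savannah &= ~water
    cls[water] = codes.WATER
    cls[savannah] = codes.OTHER_NONFOREST

    last_degr = np.zeros(shape, dtype=np.int16)
    degr_driver = np.zeros(shape, dtype=np.int8)
    degr_until = np.zeros(shape, dtype=np.int16)
    regrowth_start = np.zeros(shape, dtype=np.int16)
    fire_year = np.zeros(shape, dtype=np.int16)
    logging_events: list = []

    years = config.years
    stack = np.empty((len(years), G, G), dtype=np.uint8)
    stack[0] = cls
    struct8 = np.ones((3, 3), dtype=bool)

    for yi, year in enumerate(years[1:], start=1):
        cls = cls.copy()

        # 1) deforestation front: forest/regrowth adjacent to converted land
        converted = cls == codes.DEFORESTED
        frontier = ndi.binary_dilation(converted, structure=struct8) & ~converted
        frontier &= np.isin(cls, (codes.UNDISTURBED, codes.DEGRADED, codes.REGROWTH))
        convert = frontier & (rng.random(shape) < config.deforestation_rate)
        cls[convert] = codes.DEFORESTED
        deforestation_year[convert] = year
        regrowth_start[convert] = 0

        # 2a) per-pixel abandonment: post-1990 deforested land may regrow
        abandoned = (cls == codes.DEFORESTED) & (deforestation_year > 0) & (deforestation_year < year)
        regrow = abandoned & (rng.random(shape) < config.regrowth_prob)
        cls[regrow] = codes.REGROWTH
        regrowth_start[regrow] = year

        # 2b) patch-wise abandonment: whole fields revert to regrowth at once
        # (patches are centred on converted land so abandonment actually
        # happens where farms are)
        n_abandon = rng.poisson(config.abandonment_events_per_year)
        if n_abandon:
            cand = np.argwhere(cls == codes.DEFORESTED)
            for _ in range(min(n_abandon, len(cand))):
                rmin, rmax = config.event_radius_px
                w = int(rng.integers(rmin * 2, rmax * 2 + 1))
                h = int(rng.integers(rmin * 2, rmax * 2 + 1))
                cy, cx = cand[rng.integers(len(cand))]
                r0 = int(np.clip(cy - h // 2, 0, G - h))
                c0 = int(np.clip(cx - w // 2, 0, G - w))
                patch = np.zeros(shape, dtype=bool)
                patch[r0 : r0 + h, c0 : c0 + w] = True
                patch &= cls == codes.DEFORESTED
                cls[patch] = codes.REGROWTH
                regrowth_start[patch] = year

        # 3) degradation events (fire disks, logging rectangles); with
        # driver_zones the drivers act in separate halves of the landscape
        fire_rows = (0, G // 2 - 15) if config.driver_zones else None
        n_fire = rng.poisson(config.fire_events_per_year)
        for _ in range(n_fire):
            blob = _random_blobs(rng, shape, 1, config.event_radius_px, fire_rows)
            hit = blob & (cls == codes.UNDISTURBED)
            # drivers act on disjoint pixel histories (fire-prone vs logged
            # zones), keeping the driver attribution of the analysis exact
            hit &= degr_driver != codes.DRIVER_LOGGING
            if not hit.any():
                continue
            cls[hit] = codes.DEGRADED
            last_degr[hit] = year
            degr_driver[hit] = codes.DRIVER_FIRE
            fire_year[hit] = year
            # degraded state shows in 2 or 3 annual maps (max 2.5 years)
            degr_until[hit] = year + rng.choice([1, 2])
        n_log = rng.poisson(config.logging_events_per_year)
        for _ in range(n_log):
            w = rng.integers(config.event_radius_px[0] * 2, config.event_radius_px[1] * 2 + 1)
            h = rng.integers(config.event_radius_px[0] * 2, config.event_radius_px[1] * 2 + 1)
            r0_lo = G // 2 + 15 if config.driver_zones else 0
            r0 = rng.integers(r0_lo, G - h)
            c0 = rng.integers(0, G - w)
            hit = np.zeros(shape, dtype=bool)
            hit[r0 : r0 + h, c0 : c0 + w] = True
            hit &= cls == codes.UNDISTURBED
            hit &= degr_driver != codes.DRIVER_FIRE
            if not hit.any():
                continue
            cls[hit] = codes.DEGRADED
            last_degr[hit] = year
            degr_driver[hit] = codes.DRIVER_LOGGING
            degr_until[hit] = year + rng.choice([1, 2])
            x0, y1 = geom.pixel_center(r0, c0)
            x1, y0 = geom.pixel_center(r0 + h - 1, c0 + w - 1)
            half = config.pixel_size / 2
            logging_events.append(
                (int(year), box(x0 - half, min(y0, y1) - half, x1 + half, max(y0, y1) + half))
            )

        # 4) degraded pixels revert to undisturbed after their disturbed period
        revert = (cls == codes.DEGRADED) & (degr_until < year)
        cls[revert] = codes.UNDISTURBED

        stack[yi] = cls

    aux = {
        "slope_deg": slope,
        "fire_year": fire_year,
        "water_mask": water,
        "logging_polygons": logging_events,
    }
    truth = TruthParameters(
        config=config,
        intact_rh98=intact,
        slope_deg=slope,
        fire_year=fire_year,
        last_degradation_year=last_degr,
        degradation_driver=degr_driver,
        deforestation_year=deforestation_year,
        regrowth_start_year=regrowth_start,
        logging_events=logging_events,
    )
    return AnnualChangeStack(years, stack, geom), aux, truth


# ---------------------------------------------------------------------------
# footprint sampling
# ---------------------------------------------------------------------------

def _track_positions(config: SimulationConfig, rng):
    """True footprint coordinates along parallel pseudo-orbital transects."""
    extent = config.grid_size * config.pixel_size
    margin = config.pixel_size  # keep jittered points inside the grid
    n_along = int((extent - 2 * margin) // config.along_track_spacing)
    if n_along < 1:
        raise ConfigurationError("grid extent smaller than along-track spacing")
    min_track_separation = 15.0
    max_tracks = int(extent // min_track_separation)
    n_tracks = int(np.ceil(config.n_footprints / n_along))
    if n_tracks > max_tracks:
        raise ConfigurationError(
            f"requested {config.n_footprints} footprints exceeds track capacity "
            f"({max_tracks * n_along})"
        )
    pitch = (extent - 2 * margin) / n_tracks
    xs = margin + (np.arange(n_tracks) + 0.5) * pitch + rng.uniform(-pitch / 4, pitch / 4, n_tracks)
    ys = margin + np.arange(n_along) * config.along_track_spacing + rng.uniform(
        0, config.along_track_spacing / 2
    )
    track_year = rng.choice(config.acquisition_years, size=n_tracks)
    x = np.repeat(xs, n_along)
    y = np.tile(ys, n_tracks)
    year = np.repeat(track_year, n_along)
    keep = slice(0, config.n_footprints)
    order = rng.permutation(x.size)
    return x[order][keep], y[order][keep], year[order][keep]


def simulate_footprints(stack: AnnualChangeStack, truth: TruthParameters,
                        config: SimulationConfig | None = None) -> pd.DataFrame:
    """Sample LiDAR footprints over the simulated landscape.

    Latent canopy height at a footprint is the intact field value times the
    edge-desiccation multiplier f(d) (standing forest only) times the
    disturbance/regrowth multiplier for the local state and age, plus
    measurement noise.  Reported coordinates carry isotropic Gaussian
    geolocation error; metadata columns are contaminated at the configured
    rates.  A per-footprint deforestation outcome is drawn from the logistic
    risk truth for model-recovery testing.
    """
    config = config or truth.config
    rng = substream(config.seed, "footprints")
    tx, ty, year = _track_positions(config, rng)
    n = tx.size
    row, col = stack.geom.rowcol(tx, ty)

    acq_years = sorted(set(config.acquisition_years))
    dist_by_year = {}
    for y in acq_years:
        fmask = stack.forest_mask(y)
        dist_by_year[y] = ndi.distance_transform_edt(fmask) * config.pixel_size

    cls = np.empty(n, dtype=np.uint8)
    dist = np.empty(n, dtype=float)
    for y in acq_years:
        sel = year == y
        cls[sel] = stack.classes(y)[row[sel], col[sel]]
        dist[sel] = dist_by_year[y][row[sel], col[sel]]

    intact_val = truth.intact_rh98[row, col]
    last_degr = truth.last_degradation_year[row, col]
    driver = truth.degradation_driver[row, col]
    regrow_start = truth.regrowth_start_year[row, col]

    is_forest = np.isin(cls, codes.FOREST_CLASSES)
    is_regrowth = cls == codes.REGROWTH
    edge_mult = np.where(is_forest, truth.edge_multiplier(dist), 1.0)

    # per-metric state multipliers
    state_mult = {m: np.ones(n) for m in ("rh98", "rh50", "agbd")}
    degraded_hist = is_forest & (last_degr > 0)
    age_degr = np.where(degraded_hist, year - last_degr + 1, 0)
    for metric in state_mult:
        for drv_code, drv in ((codes.DRIVER_FIRE, "fire"), (codes.DRIVER_LOGGING, "logging")):
            sel = degraded_hist & (driver == drv_code)
            if sel.any():
                state_mult[metric][sel] = truth.disturbance_multiplier(drv, metric, age_degr[sel])
        sel = is_regrowth & (regrow_start > 0)
        if sel.any():
            age_re = year[sel] - regrow_start[sel] + 1
            state_mult[metric][sel] = truth.regrowth_multiplier(age_re)

    latent_rh98 = intact_val * edge_mult * state_mult["rh98"]
    ratio = np.clip(config.rh50_ratio + rng.normal(0, config.rh50_ratio_sd, n), 0.05, 0.9)
    latent_rh50 = intact_val * ratio * edge_mult * state_mult["rh50"]
    # non-forest ground cover: low scrub heights so the 5 m filter is exercised
    nonforest = ~is_forest & ~is_regrowth
    latent_rh98[nonforest] = rng.uniform(0.5, 4.0, nonforest.sum())
    latent_rh50[nonforest] = latent_rh98[nonforest] * 0.5
    latent_agbd = (
        config.allometry_kappa
        * (intact_val * edge_mult) ** config.allometry_gamma
        * state_mult["agbd"]
    )
    latent_agbd[nonforest] = config.allometry_kappa * latent_rh98[nonforest] ** config.allometry_gamma

    rh98 = latent_rh98 + rng.normal(0, config.measurement_sd, n)
    rh50 = latent_rh50 + rng.normal(0, config.measurement_sd, n)
    rh98 = np.clip(rh98, 0.1, None)
    rh50 = np.clip(np.minimum(rh50, 0.99 * rh98), 0.05, None)
    agbd = latent_agbd * rng.lognormal(0.0, config.agbd_lognormal_sd, n)
    agbd_se = agbd * rng.uniform(*config.se_fraction, n)

    # metadata with per-rule contamination
    c = config.contamination
    beam = np.where(rng.random(n) < c["beam"], "coverage", "power")
    quality = np.where(rng.random(n) < c["quality"], 0, 1)
    degrade = np.where(rng.random(n) < c["degrade"], 1, 0)
    night = rng.random(n) >= c["daynight"]
    u = rng.random(n)
    sensitivity = rng.uniform(0.981, 1.0, n)
    low = u < c["sensitivity"]
    sensitivity[low] = rng.uniform(0.50, 0.949, low.sum())
    marginal = (u >= c["sensitivity"]) & (u < c["sensitivity"] + c.get("sensitivity_marginal", 0.0))
    sensitivity[marginal] = rng.uniform(0.951, 0.979, marginal.sum())
    # footprint-scale slope: exceedance of the 20 deg cap at the configured rate
    slope_fp = rng.uniform(0.0, 18.0, n)
    steep = rng.random(n) < c["slope"]
    slope_fp[steep] = rng.uniform(20.5, 35.0, steep.sum())
    water_flag = rng.random(n) < c["water"]
    urban_flag = rng.random(n) < c["urban"]
    forced_low = rng.random(n) < c["height"]
    rh98[forced_low] = rng.uniform(1.0, 4.9, forced_low.sum())
    rh50[forced_low] = np.minimum(rh50[forced_low], 0.9 * rh98[forced_low])

    # deforestation-risk truth: logit(pi) = alpha + beta_h * pct + beta_d * d
    pct_latent = 100.0 * edge_mult * state_mult["rh98"]
    eta = config.risk_alpha + config.risk_beta_height * pct_latent + config.risk_beta_distance * dist
    pi = expit(eta)
    outcome = rng.random(n) < pi

    x = tx + rng.normal(0, config.geolocation_sd, n)
    y_rep = ty + rng.normal(0, config.geolocation_sd, n)
    doy = rng.integers(1, 366, n)
    date = pd.to_datetime(year.astype(int) * 1000 + doy, format="%Y%j")

    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "x": x,
            "y": y_rep,
            "acq_year": year.astype(int),
            "acq_date": date.strftime("%Y-%m-%d"),
            "beam_type": beam,
            "quality_flag": quality,
            "degrade_flag": degrade,
            "night_flag": night,
            "sensitivity": sensitivity,
            "slope_deg": slope_fp,
            "water_flag": water_flag,
            "urban_flag": urban_flag,
            "rh50": rh50,
            "rh98": rh98,
            "agbd": agbd,
            "agbd_se": agbd_se,
            "deforested_followup": outcome.astype(int),
        }
    )
    truth.footprint_truth = pd.DataFrame(
        {
            "id": np.arange(n),
            "true_x": tx,
            "true_y": ty,
            "acq_year": year.astype(int),
            "class": cls,
            "dist_edge": dist,
            "latent_rh98": latent_rh98,
            "latent_rh50": latent_rh50,
            "latent_agbd": latent_agbd,
            "edge_multiplier": edge_mult,
            "pct_of_intact_rh98": pct_latent,
            "deforestation_probability": pi,
        }
    )
    return table


def simulate_risk_dataset(n: int, alpha: float, beta_height: float,
                          beta_distance: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Draw a degradation->deforestation dataset directly from the logistic
    truth logit(pi) = alpha + beta_h * height_pct + beta_d * distance.

    Heights (percent of intact) and edge distances follow the ranges typical
    of degraded-forest samples; used for coefficient-recovery testing of the
    risk model without the full landscape machinery.
    """
    rng = substream(seed, "risk_dataset")
    height_pct = rng.uniform(20.0, 100.0, n)
    distance = rng.uniform(0.0, 1000.0, n)
    eta = alpha + beta_height * height_pct + beta_distance * distance
    pi = expit(eta)
    y = (rng.random(n) < pi).astype(int)
    return pd.DataFrame(
        {
            "outcome": y,
            "height_pct": height_pct,
            "distance": distance,
            "edge_zone": distance <= 120.0,
            "cohort_year": rng.choice([2019, 2020, 2021], n),
            "probability_truth": pi,
        }
    )


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(config: SimulationConfig, output_dir) -> dict:
    """Simulate and write the full fixture bundle; returns the manifest.

    Emits one GeoTIFF-style raster per year, auxiliary rasters, logging
    polygons (GeoJSON), the footprint table (CSV), ground truth (JSON) and a
    manifest with SHA-256 checksums.  Re-running with the same seed
    reproduces the checksums byte for byte.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, aux, truth = simulate_landscape(config)
    footprints = simulate_footprints(stack, truth, config)

    files = []
    for yi, year in enumerate(stack.years):
        p = out / f"change_{year}.tif"
        write_raster(p, stack.data[yi], stack.geom, tags={"year": int(year), "classes": codes.CLASS_NAMES})
        files.append(p)
    for name, arr in (("slope_deg", aux["slope_deg"]),
                      ("fire_year", aux["fire_year"]),
                      ("water_mask", aux["water_mask"].astype(np.uint8))):
        p = out / f"{name}.tif"
        write_raster(p, np.asarray(arr), stack.geom)
        files.append(p)
    p = out / "logging_polygons.geojson"
    write_polygons(p, [poly for _, poly in aux["logging_polygons"]],
                   [{"year": int(y)} for y, _ in aux["logging_polygons"]])
    files.append(p)
    p = out / "footprints.csv"
    footprints.to_csv(p, index=False, float_format="%.6f")
    files.append(p)
    p = out / "truth.json"
    with open(p, "w") as fh:
        json.dump(truth.to_json_dict(), fh, sort_keys=True)
    files.append(p)

    manifest = {
        "seed": config.seed,
        "n_years": int(len(stack.years)),
        "n_footprints": int(len(footprints)),
        "class_codes": {str(k): v for k, v in codes.CLASS_NAMES.items()},
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
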