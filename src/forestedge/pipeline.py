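"""End-to-end pipeline: simulate -> stratify -> QC -> edge / recovery /
risk / IFL, with per-stage outputs, provenance and checksums.

Every stochastic stage draws from a named substream of the single run seed,
so a run with identical configuration and seed writes byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, codes
from .config import (AnalysisThresholds, ConfigurationError, GridSpec,
                     QCThresholds, SimulationConfig, load_yaml_config)
from .edges import edge_sample, penetration_depth_95, penetration_depth_anova, profile_by_distance
from .ifl import aggregate_to_km, connected_patches, intact_input_mask, overlap_stats
from .qc import apply_quality_filters
from .raster_io import write_raster
from .recovery import build_trajectory, recovery_rate
from .risk import build_risk_dataset, evaluate_roc, fit_risk_model, height_at_probability
from .strata import colocate_footprints, derive_strata, mask_low_deforestation_cells
from .synthetic import simulate_footprints, simulate_landscape, write_fixture_bundle

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_KEYS = {"simulation", "grid_cell_size", "qc", "thresholds", "seed",
               "region", "risk_backend", "recovery_age_window", "output_dir"}


@dataclass
class RunConfig:
    """Fully serialisable run configuration (YAML-loadable)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    grid_cell_size: float = 7680.0
    qc: QCThresholds = field(default_factory=QCThresholds)
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    seed: int = 0
    region: str = "synthetic"
    risk_backend: str = "mle"
    recovery_age_window: tuple = (10, 20)

    def __post_init__(self):
        # the run seed governs the simulation too
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = load_yaml_config(path)
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown RunConfig keys: {sorted(unknown)}")
        kwargs = {}
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        if "qc" in raw:
            kwargs["qc"] = QCThresholds(**raw["qc"])
        if "thresholds" in raw:
            kwargs["thresholds"] = AnalysisThresholds(**raw["thresholds"])
        for key in ("grid_cell_size", "seed", "region", "risk_backend"):
            if key in raw:
                kwargs[key] = raw[key]
        if "recovery_age_window" in raw:
            kwargs["recovery_age_window"] = tuple(raw["recovery_age_window"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "grid_cell_size": self.grid_cell_size,
            "qc": asdict(self.qc),
            "thresholds": asdict(self.thresholds),
            "seed": self.seed,
            "region": self.region,
            "risk_backend": self.risk_backend,
            "recovery_age_window": list(self.recovery_age_window),
        }


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _csv(df: pd.DataFrame, path):
    df.to_csv(path, index=False, float_format="%.6f")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: RunConfig, output_dir) -> Path:
    """Run every stage; returns the run directory.

    Stage outputs land in per-stage subdirectories; ``provenance.json``
    records the configuration, seeds, software version, per-stage counts
    and SHA-256 checksums of every file written.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov: dict = {"config": config.to_dict(), "config_hash": _config_hash(config),
                  "seed": config.seed, "version": __version__, "stages": {}}
    grid_spec = GridSpec(cell_size=config.grid_cell_size)
    stage = "simulate"
    try:
        sim_dir = out / "simulate"
        manifest = write_fixture_bundle(config.simulation, sim_dir)
        stack, aux, truth = simulate_landscape(config.simulation)
        footprints = simulate_footprints(stack, truth, config.simulation)
        prov["stages"][stage] = {"n_footprints": len(footprints),
                                 "n_years": int(len(stack.years))}

        stage = "stratify"
        st_dir = out / "stratify"
        st_dir.mkdir(exist_ok=True)
        strata = derive_strata(stack, aux["fire_year"], aux["logging_polygons"],
                               thresholds=config.thresholds)
        write_raster(st_dir / "stratum.tif", strata.stratum.astype(np.uint8), stack.geom,
                     tags={"codes": {str(k): v for k, v in codes.STRATUM_NAMES.items()}})
        write_raster(st_dir / "distance_m.tif", strata.distance_m.astype(np.float32), stack.geom)
        cells = mask_low_deforestation_cells(stack, grid_spec, config.thresholds)
        _csv(cells, st_dir / "cell_inclusion.csv")
        prov["stages"][stage] = dict(strata.counts)

        stage = "qc"
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        clean_other, rej_other = apply_quality_filters(footprints, "other", config.qc)
        _, rej_intact = apply_quality_filters(footprints, "intact_or_undisturbed", config.qc)
        _write_json(qc_dir / "rejections.json",
                    {"other": rej_other, "intact_or_undisturbed": rej_intact})
        sample, report = colocate_footprints(clean_other, strata, grid_spec,
                                             config.thresholds, region=config.region)
        _csv(sample, qc_dir / "stratified_sample.csv")
        prov["stages"][stage] = {"n_retained": len(clean_other), **report}

        stage = "edge"
        edge_dir = out / "edge"
        edge_dir.mkdir(exist_ok=True)
        esample = edge_sample(sample, cell_inclusion=None)
        profile = profile_by_distance(esample, "rh98", thresholds=config.thresholds)
        _csv(profile.to_frame(), edge_dir / "profile_rh98.csv")
        edge_results = {"qualifying": bool(profile.qualifying),
                        "intact_mean": profile.intact_mean,
                        "intact_n": profile.intact_n}
        if profile.qualifying:
            d95 = penetration_depth_95(profile)
            d_anova, F, p, tukey = penetration_depth_anova(
                esample, "rh98", thresholds=config.thresholds)
            _csv(tukey, edge_dir / "tukey_rh98.csv")
            first_band = profile.band_mean[0] if profile.band_index[0] == 0 else np.nan
            edge_results.update({
                "penetration_95_m": d95, "penetration_anova_m": d_anova,
                "anova_F": F, "anova_p": p,
                "edge_magnitude_hat": 1.0 - first_band / profile.intact_mean,
            })
        _write_json(edge_dir / "edge_results.json", edge_results)
        prov["stages"][stage] = {"n_profile_footprints": int(len(esample))}

        stage = "recovery"
        rec_dir = out / "recovery"
        rec_dir.mkdir(exist_ok=True)
        rec_results = {}
        for dtype in ("logging", "fire", "regrowth"):
            traj = build_trajectory(sample, dtype, "rh98", thresholds=config.thresholds,
                                    qc=config.qc)
            if not traj.empty:
                _csv(traj.to_frame(), rec_dir / f"trajectory_{dtype}.csv")
                entry = {"n_steps": int(len(traj.ages)),
                         "mean_pct_overall": float(np.mean(traj.mean_pct))}
                try:
                    entry["rate_pct_per_yr"] = recovery_rate(traj, config.recovery_age_window)
                except ValueError:
                    pass
                rec_results[dtype] = entry
        _write_json(rec_dir / "recovery_results.json", rec_results)
        prov["stages"][stage] = {k: v["n_steps"] for k, v in rec_results.items()}

        stage = "risk"
        risk_dir = out / "risk"
        risk_dir.mkdir(exist_ok=True)
        dataset = build_risk_dataset(clean_other, stack, aux["fire_year"],
                                     aux["logging_polygons"], grid_spec,
                                     config.thresholds, region=config.region)
        risk_results = {"n": int(len(dataset))}
        if len(dataset) and dataset["outcome"].nunique() == 2:
            _csv(dataset, risk_dir / "risk_dataset.csv")
            fit = fit_risk_model(dataset, ("height_pct",), backend=config.risk_backend,
                                 seed=config.seed)
            roc, auc = evaluate_roc(fit, dataset)
            _csv(roc, risk_dir / "roc.csv")
            risk_results.update({
                "backend": fit.backend, "coef": fit.coef, "coef_se": fit.coef_se,
                "rhat": fit.rhat, "auc": auc,
                "height_pct_at_p50": height_at_probability(fit, 0.5),
            })
        _write_json(risk_dir / "risk_fit.json", risk_results)
        prov["stages"][stage] = {"n_cohort": int(len(dataset))}

        stage = "ifl"
        ifl_dir = out / "ifl"
        ifl_dir.mkdir(exist_ok=True)
        intact30 = intact_input_mask(strata)
        km = aggregate_to_km(intact30, config.simulation.pixel_size)
        # synthetic grids are far smaller than 500 km^2; scale the area
        # threshold with the available grid so the filter stays meaningful
        min_px = min(500, max(1, km.size // 20))
        iflm = connected_patches(km, min_pixels=min_px,
                                 provenance={"source": "strata_intact"})
        write_raster(ifl_dir / "ifl_1km.tif", iflm.mask.astype(np.uint8), stack.geom)
        _write_json(ifl_dir / "ifl_report.json", {
            "n_components": iflm.n_components,
            "component_pixels": iflm.component_pixels,
            "min_pixels": min_px,
            "intact_30m_px": int(intact30.sum()),
        })
        prov["stages"][stage] = {"n_components": iflm.n_components}
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        _write_json(out / "provenance.json", prov)
        raise StageError(stage, err) from err

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "provenance.json")
    prov["checksums"] = {
        str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest() for p in files
    }
    _write_json(out / "provenance.json", prov)
    return out
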