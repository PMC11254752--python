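"""Space-for-time recovery trajectories.

Structure metrics are first normalised to the intact reference of the same
grid cell (percent of intact), then footprints are grouped by disturbance
type and 1-based age since the event; the trajectory at each age step is
the unweighted mean over qualifying cells of the cell-level percent means,
with the spatial SD taken across cells.  A single acquisition epoch thus
stands in for a longitudinal record — the space-for-time substitution whose
validity the synthetic generator makes testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisThresholds, QCThresholds
from .qc import weighted_agbd_mean
from .stats import AnovaResult, one_way_anova

logger = logging.getLogger(__name__)

__all__ = ["RecoveryTrajectory", "normalize_to_intact", "build_trajectory", "recovery_rate"]

#: trajectory disturbance types -> contributing strata
DISTURBANCE_STRATA = {
    "logging": ("degraded_logging",),
    "fire": ("degraded_fire",),
    "edge_undisturbed": ("edge_undisturbed",),
    "edge_degraded": ("edge_burned", "edge_logged"),
    "regrowth": ("regrowth",),
}


def _cell_intact_means(sample: pd.DataFrame, metric: str,
                       thresholds: AnalysisThresholds, qc: QCThresholds) -> pd.Series:
    intact = sample.loc[sample["stratum"] == "intact"]
    means = {}
    for cell, grp in intact.groupby("cell_id", observed=True):
        if len(grp) < thresholds.min_samples_per_band:
            continue  # cell lacks a qualifying intact reference
        vals = grp[metric].to_numpy(float)
        if metric == "agbd":
            means[cell] = weighted_agbd_mean(vals, grp["agbd_se"].to_numpy(float),
                                             qc.agbd_weighting).mean
        else:
            means[cell] = float(vals.mean())
    return pd.Series(means, dtype=float)


def normalize_to_intact(sample: pd.DataFrame, metric: str = "rh98",
                        thresholds: AnalysisThresholds | None = None,
                        qc: QCThresholds | None = None) -> pd.Series:
    """Per-footprint percent-of-intact: 100 x value / (cell intact mean).

    Footprints in cells without a qualifying intact reference get NaN (and
    are counted in the log).
    """
    thresholds = thresholds or AnalysisThresholds()
    qc = qc or QCThresholds()
    cell_means = _cell_intact_means(sample, metric, thresholds, qc)
    ref = sample["cell_id"].map(cell_means)
    n_dropped = int(ref.isna().sum())
    if n_dropped:
        logger.info("%d footprints in cells lacking an intact reference dropped", n_dropped)
    return 100.0 * sample[metric] / ref


@dataclass
class RecoveryTrajectory:
    disturbance_type: str
    metric: str
    region: str
    ages: np.ndarray             # 1-based age steps present
    mean_pct: np.ndarray         # unweighted mean over cells
    spatial_sd: np.ndarray       # SD across cell means (NaN with one cell)
    n_footprints: np.ndarray
    n_cells: np.ndarray
    anova: AnovaResult | None = None
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages, "mean_pct": self.mean_pct,
            "spatial_sd": self.spatial_sd, "n_footprints": self.n_footprints,
            "n_cells": self.n_cells,
        })


def build_trajectory(sample: pd.DataFrame, disturbance_type: str,
                     metric: str = "rh98", region: str = "all",
                     thresholds: AnalysisThresholds | None = None,
                     qc: QCThresholds | None = None,
                     pooled: bool = False) -> RecoveryTrajectory:
    """Age trajectory of percent-of-intact structure for one disturbance type.

    A (cell, age) contributes when the cell holds at least the per-step
    sample minimum at that age and at least the per-cell total minimum over
    all steps.  With ``pooled`` the trajectory uses pooled footprints
    instead of cell means (variant; the default matches spatial-SD
    semantics).
    """
    thresholds = thresholds or AnalysisThresholds()
    qc = qc or QCThresholds()
    if disturbance_type not in DISTURBANCE_STRATA:
        raise ValueError(f"unknown disturbance type {disturbance_type!r}")
    strata = DISTURBANCE_STRATA[disturbance_type]

    sub = sample.loc[sample["stratum"].isin(strata)].copy()
    if region != "all":
        sub = sub.loc[sub["region"] == region]
    sub["pct"] = normalize_to_intact(sample, metric, thresholds, qc).loc[sub.index]
    sub = sub.dropna(subset=["pct", "age"])
    sub["age"] = sub["age"].astype(int)

    # per-cell totals over all steps
    cell_tot = sub.groupby("cell_id", observed=True)["pct"].size()
    ok_cells = set(cell_tot[cell_tot >= thresholds.min_samples_per_cell].index)
    sub = sub.loc[sub["cell_id"].isin(ok_cells)]
    if len(sub) == 0:
        logger.warning("no qualifying cells for %s/%s", disturbance_type, metric)
        return RecoveryTrajectory(disturbance_type, metric, region,
                                  np.array([], int), np.array([]), np.array([]),
                                  np.array([], int), np.array([], int), empty=True)

    grp = sub.groupby(["age", "cell_id"], observed=True)["pct"].agg(["mean", "size"]).reset_index()
    grp = grp.loc[grp["size"] >= thresholds.min_samples_per_step]

    ages, means, sds, nf, nc = [], [], [], [], []
    for age, g in grp.groupby("age"):
        ages.append(int(age))
        if pooled:
            means.append(float((g["mean"] * g["size"]).sum() / g["size"].sum()))
        else:
            means.append(float(g["mean"].mean()))
        sds.append(float(g["mean"].std(ddof=1)) if len(g) > 1 else np.nan)
        nf.append(int(g["size"].sum()))
        nc.append(int(len(g)))

    anova = None
    kept = sub.merge(grp[["age", "cell_id"]], on=["age", "cell_id"])
    groups = [g["pct"].to_numpy(float) for _, g in kept.groupby("age") if len(g) >= 2]
    if len(groups) >= 2:
        try:
            anova = one_way_anova(groups)
        except ValueError:
            anova = None

    order = np.argsort(ages)
    return RecoveryTrajectory(
        disturbance_type, metric, region,
        ages=np.array(ages, int)[order], mean_pct=np.array(means)[order],
        spatial_sd=np.array(sds)[order], n_footprints=np.array(nf, int)[order],
        n_cells=np.array(nc, int)[order], anova=anova,
        empty=len(ages) == 0,
    )


def recovery_rate(trajectory: RecoveryTrajectory, age_window: tuple = (10, 20)) -> float:
    """OLS slope of percent-of-intact versus age over the window (%/yr).

    The default window (ages 10-20) targets the post-plateau region where
    residual growth rates are reported.
    """
    lo, hi = age_window
    sel = (trajectory.ages >= lo) & (trajectory.ages <= hi)
    if sel.sum() < 2:
        raise ValueError("need at least 2 trajectory steps inside the window")
    x = trajectory.ages[sel].astype(float)
    y = trajectory.mean_pct[sel]
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)
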