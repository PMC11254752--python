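"""Distance-band structure profiles and edge-penetration depth statistics.

Two penetration criteria are computed from a profile of canopy structure
versus distance to the forest/non-forest edge:

* the conservative 95%-of-intact criterion — the first distance at which
  the band-mean curve reaches 95% of the intact reference mean, located by
  linear interpolation between band midpoints;
* the ANOVA criterion — the upper bound of the farthest distance band that
  still differs significantly from intact forest (Tukey HSD, p < 0.05)
  with every farther band non-significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisThresholds, QCThresholds
from .qc import weighted_agbd_mean
from .stats import one_way_anova, tukey_hsd
from .strata import DistanceBandScheme

logger = logging.getLogger(__name__)

__all__ = ["EdgeProfile", "profile_by_distance", "penetration_depth_95",
           "penetration_depth_anova", "edge_sample"]


@dataclass
class EdgeProfile:
    """Per-distance-band structure statistics for one scope."""

    scope: str
    metric: str
    scheme: DistanceBandScheme
    band_index: np.ndarray       # bands with n >= minimum only
    band_mean: np.ndarray
    band_sd: np.ndarray
    band_n: np.ndarray
    intact_mean: float
    intact_sd: float
    intact_n: int
    qualifying: bool

    def to_frame(self) -> pd.DataFrame:
        mids = self.scheme.midpoints[self.band_index]
        lo = [self.scheme.intervals[i][0] for i in self.band_index]
        hi = [self.scheme.intervals[i][1] for i in self.band_index]
        return pd.DataFrame({
            "band": self.band_index, "lower_m": lo, "upper_m": hi,
            "midpoint_m": mids, "mean": self.band_mean, "sd": self.band_sd,
            "n": self.band_n,
        })


def edge_sample(sample: pd.DataFrame, all_forests: bool = False,
                cell_inclusion: pd.DataFrame | None = None) -> pd.DataFrame:
    """Select the footprints that enter the distance profile.

    Default: undisturbed forest located more than 120 m from degraded
    forest, at any distance band (the intact stratum included).  With
    ``all_forests`` degraded footprints are kept too.  ``cell_inclusion``
    (from :func:`forestedge.strata.mask_low_deforestation_cells`) drops
    cells with negligible accumulated deforestation.
    """
    sel = sample["band"] >= 0
    if all_forests:
        sel &= sample["far_from_degraded"] | ~sample["undisturbed"]
    else:
        sel &= sample["undisturbed"] & sample["far_from_degraded"]
    out = sample.loc[sel]
    if cell_inclusion is not None:
        included = set(cell_inclusion.loc[cell_inclusion["included"], "cell_id"])
        out = out.loc[out["cell_id"].isin(included)]
    return out


def _intact_reference(sample: pd.DataFrame, metric: str, thresholds: AnalysisThresholds,
                      qc: QCThresholds):
    intact = sample.loc[sample["stratum"] == "intact"]
    if len(intact) == 0:
        return np.nan, np.nan, 0
    vals = intact[metric].to_numpy(dtype=float)
    if metric == "agbd":
        mean = weighted_agbd_mean(vals, intact["agbd_se"].to_numpy(float), qc.agbd_weighting).mean
    else:
        mean = float(vals.mean())
    return mean, float(vals.std(ddof=1)) if len(vals) > 1 else np.nan, len(vals)


def profile_by_distance(sample: pd.DataFrame, metric: str = "rh98",
                        scope: str = "pooled",
                        thresholds: AnalysisThresholds | None = None,
                        qc: QCThresholds | None = None) -> EdgeProfile:
    """Band-wise mean/SD/count of a structure metric plus the intact
    reference of the same scope.

    ``sample`` should already be restricted via :func:`edge_sample` (and to
    one grid cell if the scope is a cell).  AGBD uses the uncertainty-
    weighted mean.  Bands below the per-band minimum are absent; the scope
    qualifies only if the band total and the intact reference meet the
    protocol minima.
    """
    thresholds = thresholds or AnalysisThresholds()
    qc = qc or QCThresholds()
    if len(sample) == 0:
        raise ValueError("empty sample")
    in_band = sample.loc[sample["band"] >= 0]

    idx, means, sds, ns = [], [], [], []
    for band, grp in in_band.groupby("band", observed=True):
        vals = grp[metric].to_numpy(dtype=float)
        if metric == "agbd":
            mean = weighted_agbd_mean(vals, grp["agbd_se"].to_numpy(float), qc.agbd_weighting).mean
        else:
            mean = float(vals.mean())
        if vals.size < thresholds.min_samples_per_band:
            continue
        idx.append(int(band))
        means.append(mean)
        sds.append(float(vals.std(ddof=1)))
        ns.append(int(vals.size))

    intact_mean, intact_sd, intact_n = _intact_reference(sample, metric, thresholds, qc)
    total_n = int(np.sum(ns)) if ns else 0
    qualifying = (
        total_n >= thresholds.min_samples_per_scope
        and len(idx) > 0
        and intact_n >= thresholds.min_samples_per_band
    )
    scheme = DistanceBandScheme()
    return EdgeProfile(
        scope=scope, metric=metric, scheme=scheme,
        band_index=np.array(idx, dtype=int), band_mean=np.array(means),
        band_sd=np.array(sds), band_n=np.array(ns, dtype=int),
        intact_mean=intact_mean, intact_sd=intact_sd, intact_n=intact_n,
        qualifying=qualifying,
    )


def penetration_depth_95(profile: EdgeProfile, threshold: float = 0.95) -> float:
    """Distance at which the band-mean curve first attains ``threshold`` x
    the intact reference mean (metres).

    Linear interpolation between consecutive band midpoints; 0 if the first
    band already meets the threshold; NaN (unresolved) if it is never met
    within the profiled distances.
    """
    if not np.isfinite(profile.intact_mean) or profile.intact_mean <= 0:
        raise ValueError("profile lacks a usable intact reference")
    if profile.band_index.size == 0:
        raise ValueError("profile has no qualifying bands")
    target = threshold * profile.intact_mean
    mids = profile.scheme.midpoints[profile.band_index]
    means = profile.band_mean

    above = means >= target
    if above[0]:
        return 0.0
    if not above.any():
        logger.info("95%% threshold never attained within profiled bands (scope %s)",
                    profile.scope)
        return float("nan")
    crossings = np.nonzero(above[1:] & ~above[:-1])[0]
    if crossings.size > 1:
        logger.info("non-monotone profile: %d crossings, using the first", crossings.size)
    i = int(crossings[0])
    d0, d1 = mids[i], mids[i + 1]
    v0, v1 = means[i], means[i + 1]
    return float(d0 + (target - v0) / (v1 - v0) * (d1 - d0))


def penetration_depth_anova(sample: pd.DataFrame, metric: str = "rh98",
                            scope: str = "pooled",
                            thresholds: AnalysisThresholds | None = None,
                            comparisons: str = "vs_intact"):
    """ANOVA-based penetration depth.

    One-way ANOVA across all qualifying distance bands plus the intact
    reference group, then Tukey HSD of each band against intact; the
    penetration depth is the upper bound of the farthest band whose
    band-vs-intact comparison is significant (p < 0.05) with all farther
    bands non-significant (contiguity rule).

    Returns (metres, F, p, tukey table).
    """
    thresholds = thresholds or AnalysisThresholds()
    profile = profile_by_distance(sample, metric=metric, scope=scope, thresholds=thresholds)
    in_band = sample.loc[sample["band"].isin(profile.band_index)]
    groups, labels = [], []
    for band in profile.band_index:
        groups.append(in_band.loc[in_band["band"] == band, metric].to_numpy(float))
        labels.append(f"band_{band}")
    intact_vals = sample.loc[sample["stratum"] == "intact", metric].to_numpy(float)
    groups.append(intact_vals)
    labels.append("intact")
    if len(groups) < 2:
        raise ValueError("need at least one band plus the intact reference")

    res = one_way_anova(groups)
    mode = "vs_last" if comparisons == "vs_intact" else "all_pairs"
    table = tukey_hsd(groups, alpha=thresholds.alpha, labels=labels, comparisons=mode)
    vs_intact = table.loc[table["group_b"] == "intact"] if mode == "vs_last" else (
        table.loc[(table["group_b"] == "intact") | (table["group_a"] == "intact")])

    sig = {}
    for _, r in vs_intact.iterrows():
        lab = r["group_a"] if r["group_b"] == "intact" else r["group_b"]
        if lab.startswith("band_"):
            sig[int(lab.split("_")[1])] = bool(r["significant"])
    # farthest significant band; the contiguity rule means every band beyond
    # it must be non-significant, so the farthest significant band is it
    bands_sorted = sorted(sig)
    sig_bands = [b for b in bands_sorted if sig[b]]
    depth = float(profile.scheme.intervals[max(sig_bands)][1]) if sig_bands else 0.0
    return depth, res.F, res.p, table
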