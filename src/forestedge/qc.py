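"""LiDAR footprint quality filtering and uncertainty-aware biomass averaging.

The filter chain mirrors the published protocol: power beam only, quality
flag 1, degrade flag 0, night acquisitions, terrain slope at most 20 deg,
no water or urban contamination, RH98 at least 5 m (forest definition), and
beam sensitivity above 0.98 for intact/undisturbed samples or 0.95 for the
other classes.  The chain is a pure conjunction — the retained set does not
depend on rule order — but rejection reasons are tallied by the first
failing rule in the documented order below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QCThresholds

__all__ = ["RULE_ORDER", "apply_quality_filters", "weighted_agbd_mean", "rule_violations"]

#: fixed attribution order of the filter rules
RULE_ORDER = (
    "beam", "quality", "degrade", "daynight", "slope",
    "water", "urban", "height", "sensitivity",
)

_REQUIRED = {
    "beam": "beam_type",
    "quality": "quality_flag",
    "degrade": "degrade_flag",
    "daynight": "night_flag",
    "slope": "slope_deg",
    "water": "water_flag",
    "urban": "urban_flag",
    "height": "rh98",
    "sensitivity": "sensitivity",
}


def rule_violations(table: pd.DataFrame, stratum_intent: str = "other",
                    thresholds: QCThresholds | None = None) -> dict[str, np.ndarray]:
    """Boolean violation mask per rule, evaluated independently of order."""
    thresholds = thresholds or QCThresholds()
    if stratum_intent not in ("intact_or_undisturbed", "other"):
        raise ValueError("stratum_intent must be 'intact_or_undisturbed' or 'other'")
    for rule, colname in _REQUIRED.items():
        if colname not in table.columns:
            raise KeyError(f"missing required column {colname!r} (rule {rule!r})")
    sens_thr = (thresholds.sensitivity_intact if stratum_intent == "intact_or_undisturbed"
                else thresholds.sensitivity_other)
    return {
        "beam": (table["beam_type"] != "power").to_numpy(),
        "quality": (table["quality_flag"] != 1).to_numpy(),
        "degrade": (table["degrade_flag"] != 0).to_numpy(),
        "daynight": (~table["night_flag"].astype(bool)).to_numpy(),
        # strictly above 20 deg rejected; the 20.0 boundary is retained
        "slope": (table["slope_deg"] > thresholds.max_slope_deg).to_numpy(),
        "water": table["water_flag"].astype(bool).to_numpy(),
        "urban": table["urban_flag"].astype(bool).to_numpy(),
        "height": (table["rh98"] < thresholds.min_rh98).to_numpy(),
        "sensitivity": (table["sensitivity"] <= sens_thr).to_numpy(),
    }


def apply_quality_filters(table: pd.DataFrame, stratum_intent: str = "other",
                          thresholds: QCThresholds | None = None
                          ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the full quality-filter chain.

    Returns the retained table and per-rule rejection counts attributed to
    the first failing rule in :data:`RULE_ORDER`.
    """
    violations = rule_violations(table, stratum_intent, thresholds)
    n = len(table)
    rejected_by = np.full(n, -1, dtype=int)
    for i, rule in enumerate(RULE_ORDER):
        newly = (rejected_by == -1) & violations[rule]
        rejected_by[newly] = i
    counts = {rule: int((rejected_by == i).sum()) for i, rule in enumerate(RULE_ORDER)}
    retained = table.loc[rejected_by == -1].reset_index(drop=True)
    return retained, counts


@dataclass
class WeightedMean:
    mean: float
    effective_n: float


def weighted_agbd_mean(values, ses, weighting: str = "inv_var") -> WeightedMean:
    """Uncertainty-weighted biomass average.

    The default reads "weighted by the prediction standard error" as
    inverse-variance weighting w = 1/SE^2 (standard precision weighting);
    ``weighting`` may be "inv_se" (1/SE) or "se" for sensitivity analysis.
    The effective sample size is (sum w)^2 / sum w^2.
    """
    values = np.asarray(values, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if values.shape != ses.shape:
        raise ValueError("values and ses must have equal length")
    if values.size == 0:
        raise ValueError("empty input")
    if np.any(ses <= 0):
        raise ValueError("all SEs must be positive (degenerate weight otherwise)")
    if weighting == "inv_var":
        w = 1.0 / ses**2
    elif weighting == "inv_se":
        w = 1.0 / ses
    elif weighting == "se":
        w = ses.copy()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    mean = float(np.sum(w * values) / np.sum(w))
    eff_n = float(np.sum(w) ** 2 / np.sum(w**2))
    return WeightedMean(mean=mean, effective_n=eff_n)
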