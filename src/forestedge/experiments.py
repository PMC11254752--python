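"""Parameter-recovery experiments on the synthetic landscape.

Each function runs one controlled study end to end — generate a landscape
with known truth, push it through the full analysis chain, and return the
estimates next to the generator truth — so that the same code serves the
validation suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import GridSpec
from .edges import edge_sample, penetration_depth_95, penetration_depth_anova, profile_by_distance
from .qc import apply_quality_filters
from .recovery import build_trajectory, recovery_rate
from .risk import evaluate_roc, fit_risk_model, height_at_probability
from .scenarios import edge_recovery_config, stationary_world_config
from .strata import colocate_footprints, derive_strata
from .synthetic import simulate_footprints, simulate_landscape, simulate_risk_dataset

__all__ = [
    "stratified_sample_for",
    "edge_penetration_experiment",
    "trajectory_experiment",
    "regrowth_rate_experiment",
    "risk_recovery_experiment",
]


def stratified_sample_for(config, single_cell: bool = True):
    """Simulate, QC-filter and co-locate footprints for a config.

    Returns (sample, truth, stack).  With ``single_cell`` the analysis grid
    is one cell covering the whole landscape (a synthetic landscape is far
    smaller than a 1.5 degree cell).
    """
    stack, aux, truth = simulate_landscape(config)
    footprints = simulate_footprints(stack, truth, config)
    clean, _ = apply_quality_filters(footprints, "other")
    strata = derive_strata(stack, aux["fire_year"], aux["logging_polygons"])
    cell = config.grid_size * config.pixel_size if single_cell else None
    grid_spec = GridSpec(cell_size=cell) if cell else GridSpec()
    sample, _ = colocate_footprints(clean, strata, grid_spec)
    return sample, truth, stack


def edge_penetration_experiment(seed: int, edge_magnitude: float = 0.20,
                                edge_depth_d95: float = 400.0,
                                n_footprints: int = 50000,
                                with_anova: bool = False) -> dict:
    """Recover the edge-penetration depth and magnitude from one replicate.

    Returns the 95%-criterion depth estimate (NaN when unresolved), the
    first-band edge-magnitude estimate, and optionally the ANOVA-criterion
    depth with its F statistic.
    """
    config = edge_recovery_config(seed=seed, edge_magnitude=edge_magnitude,
                                  edge_depth_d95=edge_depth_d95,
                                  n_footprints=n_footprints)
    sample, truth, _ = stratified_sample_for(config)
    esample = edge_sample(sample)
    profile = profile_by_distance(esample, "rh98")
    out = {
        "seed": seed,
        "qualifying": bool(profile.qualifying),
        "truth_d95_m": edge_depth_d95,
        "truth_edge_magnitude": edge_magnitude,
        "d95_hat_m": penetration_depth_95(profile),
        "edge_magnitude_hat": float(1.0 - profile.band_mean[0] / profile.intact_mean)
        if profile.band_index[0] == 0 else float("nan"),
        "intact_mean_m": profile.intact_mean,
        "n_profile": int(profile.band_n.sum()),
    }
    if with_anova:
        depth, F, p, _ = penetration_depth_anova(esample, "rh98")
        out.update({"d_anova_m": depth, "anova_F": F, "anova_p": p})
    return out


def trajectory_experiment(seed: int, disturbance_types=("logging", "fire", "regrowth"),
                          metric: str = "rh98") -> pd.DataFrame:
    """Space-for-time trajectories on a stationary world, next to truth.

    One row per (disturbance type, age step): estimated percent-of-intact,
    the generator's expected value at that age, and the step sample size.
    """
    config = stationary_world_config(seed=seed)
    sample, truth, _ = stratified_sample_for(config)
    rows = []
    for dtype in disturbance_types:
        traj = build_trajectory(sample, dtype, metric)
        for age, mean, n in zip(traj.ages, traj.mean_pct, traj.n_footprints):
            rows.append({
                "disturbance": dtype, "age": int(age), "mean_pct": float(mean),
                "truth_pct": float(truth.expected_percent(dtype, metric, age)),
                "n": int(n),
            })
    df = pd.DataFrame(rows)
    if len(df):
        df["error_pct"] = df["mean_pct"] - df["truth_pct"]
    return df


def regrowth_rate_experiment(seed: int, age_window=(10, 20)) -> dict:
    """Late-stage regrowth rate (%/yr) versus the analytic derivative mean."""
    config = stationary_world_config(seed=seed)
    sample, truth, _ = stratified_sample_for(config)
    traj = build_trajectory(sample, "regrowth", "rh98")
    rate = recovery_rate(traj, age_window)
    P, tau = config.regrowth_plateau, config.regrowth_timescale
    lo, hi = age_window
    analytic = 100.0 * P * (np.exp(-lo / tau) - np.exp(-hi / tau)) / (hi - lo)
    return {"seed": seed, "rate_hat_pct_per_yr": rate,
            "analytic_rate_pct_per_yr": float(analytic),
            "n_steps": int(len(traj.ages))}


def risk_recovery_experiment(seed: int, n: int = 5000, alpha: float = 2.0,
                             beta_height: float = -0.06, backend: str = "mle",
                             interval: float = 0.90) -> dict:
    """Fit the deforestation-risk model to data drawn from known truth.

    Reports the coefficient estimates, whether the central ``interval``
    covers the truth, the ROC AUC and the 50%-probability height.
    """
    dataset = simulate_risk_dataset(n, alpha, beta_height, seed=seed)
    fit = fit_risk_model(dataset, ("height_pct",), backend=backend, seed=seed)
    _, auc = evaluate_roc(fit, dataset)
    z = norm.ppf(0.5 + interval / 2)
    if backend == "mcmc" and fit.samples is not None:
        qa = fit.samples["alpha"].quantile([(1 - interval) / 2, (1 + interval) / 2])
        qb = fit.samples["height_pct"].quantile([(1 - interval) / 2, (1 + interval) / 2])
        cover_a = bool(qa.iloc[0] <= alpha <= qa.iloc[1])
        cover_b = bool(qb.iloc[0] <= beta_height <= qb.iloc[1])
    else:
        a, sa = fit.coef["alpha"], fit.coef_se["alpha"]
        b, sb = fit.coef["height_pct"], fit.coef_se["height_pct"]
        cover_a = bool(a - z * sa <= alpha <= a + z * sa)
        cover_b = bool(b - z * sb <= beta_height <= b + z * sb)
    rhats = np.array(list(fit.rhat.values()), dtype=float)
    return {
        "seed": seed, "backend": fit.backend,
        "alpha_hat": fit.coef["alpha"], "beta_height_hat": fit.coef["height_pct"],
        "covers_alpha": cover_a, "covers_beta": cover_b,
        "auc": auc,
        "rhat_max": (float(np.nanmax(rhats)) if np.isfinite(rhats).any()
                     else float("nan")),
        "height_pct_at_p50": height_at_probability(fit, 0.5),
        "truth_height_pct_at_p50": -alpha / beta_height,
    }
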