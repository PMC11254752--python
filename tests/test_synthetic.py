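"""Generator behaviour: limits, transition legality, truth consistency."""

import numpy as np
import pandas as pd
import pytest

import forestedge as fe
from forestedge import codes
from forestedge.config import ConfigurationError
from forestedge.qc import rule_violations
from forestedge.scenarios import clean_contamination, qc_fixture_config


def _quiet_config(**kw):
    base = dict(grid_size=64, nonforest_strip_px=0, n_water_blobs=0,
                n_savannah_blobs=0, deforestation_rate=0.0,
                fire_events_per_year=0.0, logging_events_per_year=0.0,
                abandonment_events_per_year=0.0, regrowth_prob=0.0,
                edge_depth_d95=400.0, n_footprints=500, seed=1)
    base.update(kw)
    return fe.SimulationConfig(**base)


def test_no_event_limit_every_year_identical_all_undisturbed():
    stack, aux, truth = fe.simulate_landscape(_quiet_config())
    assert (stack.data == codes.UNDISTURBED).all()


def test_transition_graph_audited_per_pixel(small_world):
    """Exhaustive per-pixel scan: no deforested -> undisturbed transition
    without a regrowth interlude; degraded only arises from undisturbed."""
    _, stack, _, _ = small_world
    a = stack.data
    for t in range(1, a.shape[0]):
        prev, cur = a[t - 1], a[t]
        # deforested may only stay deforested or start regrowing
        assert np.isin(cur[prev == codes.DEFORESTED],
                       (codes.DEFORESTED, codes.REGROWTH)).all()
        # regrowth never jumps straight back to undisturbed/degraded
        assert np.isin(cur[prev == codes.REGROWTH],
                       (codes.REGROWTH, codes.DEFORESTED)).all()
        # water and other natural non-forest are static
        for static in (codes.WATER, codes.OTHER_NONFOREST):
            assert (cur[prev == static] == static).all()


def test_degraded_state_lasts_at_most_three_annual_maps(small_world):
    """The temporarily-disturbed class persists for at most 2.5 years,
    i.e. at most 3 consecutive annual maps."""
    _, stack, _, _ = small_world
    degraded = stack.data == codes.DEGRADED
    run = np.zeros(degraded.shape[1:], dtype=int)
    longest = np.zeros_like(run)
    for t in range(degraded.shape[0]):
        run = np.where(degraded[t], run + 1, 0)
        longest = np.maximum(longest, run)
    assert longest.max() <= 3


def test_fixed_seed_bit_identical_outputs():
    cfg = fe.SimulationConfig(grid_size=64, n_footprints=1000, seed=42)
    s1, a1, t1 = fe.simulate_landscape(cfg)
    s2, a2, t2 = fe.simulate_landscape(cfg)
    assert (s1.data == s2.data).all()
    assert np.array_equal(t1.intact_rh98, t2.intact_rh98)
    f1 = fe.simulate_footprints(s1, t1, cfg)
    f2 = fe.simulate_footprints(s2, t2, cfg)
    pd.testing.assert_frame_equal(f1, f2)


def test_intact_field_converges_to_region_preset():
    """Mean/SD of intact-area RH98 within 3 standard errors at n=10,000."""
    cfg = qc_fixture_config(seed=5, n_footprints=10000)
    cfg.contamination = clean_contamination()
    stack, aux, truth = fe.simulate_landscape(cfg)
    fp = fe.simulate_footprints(stack, truth, cfg)
    n = len(fp)
    preset = cfg.preset
    se_mean = preset.rh98_sd / np.sqrt(n / 50)  # ~50 px per correlated patch
    assert abs(fp["rh98"].mean() - preset.rh98_mean) < 3 * se_mean
    assert abs(fp["rh98"].std() - preset.rh98_sd) < 0.15 * preset.rh98_sd


def test_contamination_rates_within_binomial_99ci():
    cfg = qc_fixture_config(seed=11, n_footprints=10000)
    stack, aux, truth = fe.simulate_landscape(cfg)
    fp = fe.simulate_footprints(stack, truth, cfg)
    viol = rule_violations(fp, "other")
    mapping = {"beam": "beam", "quality": "quality", "degrade": "degrade",
               "daynight": "daynight", "slope": "slope", "water": "water",
               "urban": "urban", "height": "height", "sensitivity": "sensitivity"}
    n = len(fp)
    for rule, key in mapping.items():
        p = cfg.contamination[key]
        half = 2.576 * np.sqrt(p * (1 - p) / n)
        assert abs(viol[rule].mean() - p) <= half + 1e-12, rule


def test_edge_multiplier_closed_form_and_limits():
    cfg = _quiet_config(edge_magnitude=0.2, edge_depth_d95=400.0)
    assert cfg.edge_multiplier(0.0) == pytest.approx(0.80)
    assert cfg.edge_multiplier(400.0) == pytest.approx(0.95)
    assert cfg.edge_multiplier(1e5) == pytest.approx(1.0)
    flat = _quiet_config(edge_magnitude=0.0)
    assert flat.edge_multiplier(np.array([0.0, 100.0, 5000.0])) == pytest.approx([1, 1, 1])


def test_edge_multiplier_regression_recovers_decay_length_exactly():
    """Regressing log(1 - f(d)) on noiseless latent distances gives -1/lambda."""
    cfg = _quiet_config(edge_magnitude=0.2)
    d = np.linspace(10, 2000, 200)
    y = np.log(1.0 - cfg.edge_multiplier(d))
    slope = np.polyfit(d, y, 1)[0]
    assert slope == pytest.approx(-1.0 / cfg.edge_decay_length, rel=1e-12)


def test_no_edge_effect_means_flat_latent_profile():
    cfg = fe.SimulationConfig(grid_size=128, edge_magnitude=0.0, n_footprints=8000,
                              rh98_sd=0.5, smoothing_length_px=2.0, seed=9,
                              fire_events_per_year=0.0, logging_events_per_year=0.0,
                              n_water_blobs=0, n_savannah_blobs=0,
                              contamination=clean_contamination())
    stack, aux, truth = fe.simulate_landscape(cfg)
    fe.simulate_footprints(stack, truth, cfg)
    tt = truth.footprint_truth
    forest = np.isin(tt["class"], codes.FOREST_CLASSES)
    sub = tt[forest & (tt["dist_edge"] > 0)]
    slope = np.polyfit(sub["dist_edge"], sub["latent_rh98"], 1)[0]
    # slope of latent height vs distance indistinguishable from zero
    assert abs(slope) < 5e-5  # m per m


def test_clean_contamination_passes_full_qc_chain():
    cfg = qc_fixture_config(seed=2, n_footprints=3000)
    cfg.contamination = clean_contamination()
    stack, aux, truth = fe.simulate_landscape(cfg)
    fp = fe.simulate_footprints(stack, truth, cfg)
    retained, counts = fe.apply_quality_filters(fp, "other")
    # metadata rules never fire; only footprints whose latent canopy sits at
    # the 5 m floor can dip below the forest-definition height through
    # measurement noise (a fraction of a percent)
    assert all(counts[r] == 0 for r in counts if r != "height")
    assert counts["height"] <= 0.005 * len(fp)
    assert len(retained) >= 0.995 * len(fp)


def test_configuration_errors():
    with pytest.raises(ConfigurationError):
        fe.SimulationConfig(grid_size=64, edge_depth_d95=2000.0)  # > half extent
    with pytest.raises(ConfigurationError):
        fe.SimulationConfig(edge_magnitude=0.03)  # below resolvable magnitude
    with pytest.raises(ConfigurationError):
        fe.SimulationConfig(se_fraction=(0.0, 0.5))
    # requesting more footprints than the transects can host
    stack, aux, truth = fe.simulate_landscape(_quiet_config())
    with pytest.raises(ConfigurationError):
        fe.simulate_footprints(stack, truth, _quiet_config(n_footprints=10**7))


def test_risk_outcomes_follow_logistic_truth(small_world):
    cfg, stack, aux, truth = small_world
    fp = fe.simulate_footprints(stack, truth, cfg)
    tt = truth.footprint_truth
    merged = fp.merge(tt[["id", "deforestation_probability"]], on="id")
    # calibration: mean outcome tracks mean probability in probability bins
    bins = pd.qcut(merged["deforestation_probability"], 5, duplicates="drop")
    g = merged.groupby(bins, observed=True).agg(
        p=("deforestation_probability", "mean"), y=("deforested_followup", "mean"),
        n=("id", "size"))
    for _, r in g.iterrows():
        assert abs(r["y"] - r["p"]) < 4 * np.sqrt(r["p"] * (1 - r["p"]) / r["n"]) + 0.02
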