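"""Distance-band profiles and the two edge-penetration criteria."""

import numpy as np
import pandas as pd
import pytest

import forestedge as fe
from forestedge.edges import EdgeProfile, penetration_depth_95
from forestedge.strata import DistanceBandScheme


def _profile(band_index, band_mean, intact_mean, n=100):
    band_index = np.asarray(band_index, int)
    band_mean = np.asarray(band_mean, float)
    return EdgeProfile(
        scope="test", metric="rh98", scheme=DistanceBandScheme(),
        band_index=band_index, band_mean=band_mean,
        band_sd=np.full(band_index.size, 1.0),
        band_n=np.full(band_index.size, n), intact_mean=intact_mean,
        intact_sd=1.0, intact_n=n, qualifying=True,
    )


def _sample(values_by_band, intact_values, cell="0_0"):
    rows = []
    for band, vals in values_by_band.items():
        for v in vals:
            rows.append({"stratum": "excluded", "band": band, "rh98": v,
                         "undisturbed": True, "far_from_degraded": True,
                         "cell_id": cell, "agbd": v, "agbd_se": 1.0})
    for v in intact_values:
        rows.append({"stratum": "intact", "band": -1, "rh98": v,
                     "undisturbed": True, "far_from_degraded": True,
                     "cell_id": cell, "agbd": v, "agbd_se": 1.0})
    return pd.DataFrame(rows)


def test_profile_means_match_bruteforce_aggregation(rng):
    bands = {b: rng.normal(20 + b, 2, 50) for b in range(4)}
    intact = rng.normal(30, 2, 80)
    sample = _sample(bands, intact)
    prof = fe.profile_by_distance(sample, "rh98")
    for i, b in enumerate(prof.band_index):
        assert prof.band_mean[i] == pytest.approx(np.mean(bands[b]))
        assert prof.band_n[i] == 50
    assert prof.intact_mean == pytest.approx(np.mean(intact))
    assert not prof.qualifying  # 200 band samples sit below the 600 minimum


def test_sample_thresholds_drive_qualification(rng):
    # bands of n=29 are absent and the scope does not qualify
    bands = {b: rng.normal(25, 1, 29) for b in range(5)}
    sample = _sample(bands, rng.normal(30, 1, 40))
    prof = fe.profile_by_distance(sample, "rh98")
    assert prof.band_index.size == 0 and not prof.qualifying
    # 600 total band samples + intact reference qualify
    bands = {b: rng.normal(25, 1, 120) for b in range(5)}
    sample = _sample(bands, rng.normal(30, 1, 40))
    prof = fe.profile_by_distance(sample, "rh98")
    assert prof.qualifying


def test_penetration95_hand_interpolation_example():
    """Band means 24.0 (band 120-240 m, midpoint 180) and 27.5 (band
    240-420 m, midpoint 330), intact 28.6: the 95% level (27.17) is crossed
    between the midpoints at 180 + (27.17-24)/(27.5-24) * 150 ~ 315.9 m."""
    prof = _profile([2, 3], [24.0, 27.5], 28.6)
    d = penetration_depth_95(prof)
    target = 0.95 * 28.6
    expected = 180.0 + (target - 24.0) / (27.5 - 24.0) * (330.0 - 180.0)
    assert d == pytest.approx(expected, rel=1e-12)
    assert d == pytest.approx(315.9, abs=0.1)


def test_penetration95_limits():
    # already above 95% everywhere -> 0 m
    assert penetration_depth_95(_profile([0, 1], [28.0, 28.2], 28.6)) == 0.0
    # never attained -> unresolved (NaN)
    assert np.isnan(penetration_depth_95(_profile([0, 1, 2], [20.0, 21.0, 22.0], 28.6)))
    # non-monotone profile still returns the first crossing
    d = penetration_depth_95(_profile([0, 1, 2, 3], [25.0, 27.5, 26.0, 28.0], 28.6))
    assert 30 < d < 90


def test_penetration_statistics_invariant_to_rescaling(rng):
    bands = {b: rng.normal(24 + 2 * b, 1.5, 80) for b in range(5)}
    intact = rng.normal(30, 1.5, 100)
    sample = _sample(bands, intact)
    prof1 = fe.profile_by_distance(sample, "rh98")
    d1 = penetration_depth_95(prof1)
    a1, F1, _, _ = fe.penetration_depth_anova(sample, "rh98")
    scaled = sample.copy()
    scaled["rh98"] *= 3.7
    prof2 = fe.profile_by_distance(scaled, "rh98")
    d2 = penetration_depth_95(prof2)
    a2, F2, _, _ = fe.penetration_depth_anova(scaled, "rh98")
    assert d1 == pytest.approx(d2, rel=1e-9)
    assert a1 == a2 and F1 == pytest.approx(F2, rel=1e-9)


def test_anova_criterion_constructed_two_band_effect(rng):
    """First two bands shifted by 5 SDs, the rest null: the criterion
    returns the upper bound of the second band (120 m)."""
    bands = {}
    for b in range(6):
        shift = -5.0 if b < 2 else 0.0
        bands[b] = rng.normal(30 + shift, 1.0, 80)
    sample = _sample(bands, rng.normal(30, 1.0, 120))
    depth, F, p, table = fe.penetration_depth_anova(sample, "rh98")
    assert depth == 120.0
    assert p < 1e-6


def test_anova_criterion_null_mostly_zero(rng):
    hits = 0
    for i in range(12):
        bands = {b: rng.normal(30, 1.0, 60) for b in range(4)}
        sample = _sample(bands, rng.normal(30, 1.0, 80))
        depth, *_ = fe.penetration_depth_anova(sample, "rh98")
        hits += depth > 0
    assert hits <= 4  # expected familywise ~ alpha per comparison


def test_single_band_anova_reduces_to_t_squared(rng):
    bands = {0: rng.normal(28, 1.0, 60)}
    intact = rng.normal(30, 1.0, 60)
    sample = _sample(bands, intact)
    _, F, p, _ = fe.penetration_depth_anova(sample, "rh98")
    from scipy.stats import ttest_ind
    t, p_t = ttest_ind(bands[0], intact, equal_var=True)
    assert F == pytest.approx(t**2, rel=1e-9)


def test_edge_magnitude_recovered_within_003():
    """The first-band deficit estimates the edge magnitude within +-0.03 of
    truth at n=50,000.  A gentle gradient (D95 = 800 m) keeps the within-
    band decay of f(d) over the 60 m band small against that tolerance."""
    from forestedge.experiments import edge_penetration_experiment

    out = edge_penetration_experiment(seed=1, edge_depth_d95=800.0)
    assert abs(out["edge_magnitude_hat"] - 0.20) <= 0.03


def test_empty_sample_errors():
    with pytest.raises(ValueError):
        fe.profile_by_distance(pd.DataFrame(columns=["band", "stratum", "rh98"]))
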