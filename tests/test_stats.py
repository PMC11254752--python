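"""Statistical kernel: ANOVA, Tukey HSD, Welch, Monte-Carlo propagation,
per-cell resampling."""

import numpy as np
import pytest
from scipy import stats as sps

import forestedge as fe
from forestedge.stats import mc_propagated_anova, resampled_cell_stats


def test_anova_two_groups_equals_t_squared(rng):
    a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
    res = fe.one_way_anova([a, b])
    t, p = sps.ttest_ind(a, b, equal_var=True)
    assert res.F == pytest.approx(t**2, rel=1e-10)
    assert res.p == pytest.approx(p, rel=1e-10)


def test_anova_hand_arithmetic_example():
    """3 groups x 5 values checked against explicit sum-of-squares."""
    groups = [np.array([3.0, 5, 4, 6, 2]), np.array([7.0, 6, 8, 9, 5]),
              np.array([2.0, 3, 1, 4, 5])]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    F_hand = (ssb / 2) / (ssw / 12)
    res = fe.one_way_anova(groups)
    assert res.F == pytest.approx(F_hand, rel=1e-12)
    assert res.df_between == 2 and res.df_within == 12
    F_scipy, p_scipy = sps.f_oneway(*groups)
    assert res.F == pytest.approx(F_scipy) and res.p == pytest.approx(p_scipy)


def test_anova_null_rejection_rate(rng):
    rejections = sum(
        fe.one_way_anova([rng.normal(0, 1, 15) for _ in range(4)]).p < 0.05
        for _ in range(400)
    )
    assert 0.02 < rejections / 400 < 0.08


def test_anova_degenerate_input_errors():
    with pytest.raises(ValueError):
        fe.one_way_anova([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
    with pytest.raises(ValueError):
        fe.one_way_anova([np.array([1.0, 2.0])])


def test_anova_matches_permutation_oracle(rng):
    groups = [rng.normal(0, 1, 12), rng.normal(0.8, 1, 12), rng.normal(0.2, 1, 12)]
    res = fe.one_way_anova(groups)
    allv = np.concatenate(groups)
    n_perm, hits = 2000, 0
    for _ in range(n_perm):
        perm = rng.permutation(allv)
        pg = [perm[:12], perm[12:24], perm[24:]]
        if fe.one_way_anova(pg).F >= res.F:
            hits += 1
    p_perm = (hits + 1) / (n_perm + 1)
    assert abs(p_perm - res.p) < 0.03


def test_tukey_matches_scipy_and_reduces_to_t(rng):
    groups = [rng.normal(0, 1, 15), rng.normal(1.0, 1, 15), rng.normal(0.2, 1, 15)]
    table = fe.tukey_hsd(groups)
    ref = sps.tukey_hsd(*groups)
    for _, row in table.iterrows():
        i, j = int(row["group_a"]), int(row["group_b"])
        assert row["p"] == pytest.approx(ref.pvalue[i, j], abs=1e-6)
    # two groups: Tukey p equals the pooled t-test p
    two = fe.tukey_hsd(groups[:2])
    _, p_t = sps.ttest_ind(groups[0], groups[1], equal_var=True)
    assert two["p"].iloc[0] == pytest.approx(p_t, abs=1e-8)


def test_tukey_flags_exactly_the_shifted_group(rng):
    base = [rng.normal(0, 1, 30) for _ in range(3)] + [rng.normal(10, 1, 30)]
    table = fe.tukey_hsd(base, labels=["a", "b", "c", "shifted"])
    involves = table.apply(lambda r: "shifted" in (r["group_a"], r["group_b"]), axis=1)
    assert table.loc[involves, "significant"].all()
    assert not table.loc[~involves, "significant"].any()


def test_welch_identities(rng):
    a = rng.normal(0, 1, 30)
    t, p = fe.welch_test(a, a)
    assert t == pytest.approx(0.0)
    b = rng.normal(0.3, 1, 30)
    t_w, p_w = fe.welch_test(a, b)
    t_p, p_p = sps.ttest_ind(a, b, equal_var=True)
    # equal sizes and variances: Welch matches pooled closely
    assert t_w == pytest.approx(t_p, rel=1e-6)
    assert p_w == pytest.approx(p_p, rel=1e-2)
    with pytest.raises(ValueError):
        fe.welch_test(np.ones(5), np.ones(5))


def test_mc_anova_zero_noise_reproduces_baseline_exactly(rng):
    groups = [rng.normal(0, 1, 10) for _ in range(3)]
    ses = [np.zeros(10)] * 3
    res = mc_propagated_anova(groups, ses, n_iter=500, seed=9)
    assert res.n_iter == 500 and len(res.f_values) == 500
    assert (res.f_values == res.baseline_F).all()
    assert res.baseline_F == pytest.approx(fe.one_way_anova(groups).F, rel=1e-12)


def test_mc_anova_f_spread_grows_with_noise_scale(rng):
    """While the measurement SE is small against the within-group spread,
    inflating it widens the propagated F distribution monotonically (at
    very large SE the distribution collapses toward the null instead)."""
    groups = [rng.normal(3.0 * i, 1, 25) for i in range(3)]
    sds = []
    for mult in (0.05, 0.1, 0.2, 0.4):
        ses = [np.full(25, mult)] * 3
        r = mc_propagated_anova(groups, ses, n_iter=400, seed=5)
        sds.append(np.std(r.f_values))
    assert sds == sorted(sds)


def test_mc_anova_deterministic_and_validates(rng):
    groups = [rng.normal(0, 1, 8) for _ in range(3)]
    ses = [np.full(8, 0.5)] * 3
    r1 = mc_propagated_anova(groups, ses, seed=3)
    r2 = mc_propagated_anova(groups, ses, seed=3)
    assert np.array_equal(r1.f_values, r2.f_values)
    with pytest.raises(ValueError):
        mc_propagated_anova(groups, [np.full(8, -1.0)] * 3, seed=3)
    with pytest.raises(ValueError):
        mc_propagated_anova(groups, ses[:2], seed=3)


def test_resampled_stats_constant_input_and_determinism():
    v = np.full(1000, 7.0)
    m, sd = resampled_cell_stats(v, seed=1)
    assert m == pytest.approx(7.0) and sd == pytest.approx(0.0)
    w = np.random.default_rng(0).normal(0, 1, 1000)
    assert resampled_cell_stats(w, seed=2) == resampled_cell_stats(w, seed=2)
    with pytest.raises(ValueError):
        resampled_cell_stats(np.arange(100.0), m=300, seed=0)
    # bootstrap variant is allowed when n < m
    m_b, sd_b = resampled_cell_stats(np.arange(100.0), m=300, seed=0, replace=True)
    assert np.isfinite(sd_b)


def test_resampled_stats_finite_population_closed_form(rng):
    v = rng.normal(50, 12, 5000)
    _, sd = resampled_cell_stats(v, n_iter=500, m=300, seed=4)
    s = v.std(ddof=1)
    expected = s / np.sqrt(300) * np.sqrt((5000 - 300) / (5000 - 1))
    assert sd == pytest.approx(expected, rel=0.10)
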