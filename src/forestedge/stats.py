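"""Statistical kernel: one-way ANOVA, Tukey HSD, Welch tests, Monte-Carlo
error-propagated ANOVA and the 500x300 per-cell resampling summary.

The ANOVA decomposition is computed directly from sums of squares so the
same code path serves the scalar test and the vectorised Monte-Carlo
propagation (guaranteeing that the zero-noise propagation reproduces the
baseline F exactly); p-values come from scipy's F and studentized-range
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import substream

__all__ = [
    "one_way_anova",
    "tukey_hsd",
    "welch_test",
    "mc_propagated_anova",
    "resampled_cell_stats",
    "AnovaResult",
    "McAnovaResult",
]


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


def _check_groups(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    return groups


def _anova_from_matrix(x: np.ndarray, starts: np.ndarray, sizes: np.ndarray):
    """Vectorised one-way ANOVA over the rows of ``x``.

    ``x`` has shape (n_iter, N) with group j occupying columns
    starts[j]:starts[j]+sizes[j].  Returns (F, p) arrays of length n_iter.
    """
    N = x.shape[1]
    k = len(sizes)
    grand = x.mean(axis=1, keepdims=True)
    group_sums = np.add.reduceat(x, starts, axis=1)
    group_means = group_sums / sizes
    ssb = ((group_means - grand) ** 2 * sizes).sum(axis=1)
    sst = ((x - grand) ** 2).sum(axis=1)
    ssw = sst - ssb
    df_b, df_w = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    p = sps.f.sf(F, df_b, df_w)
    return F, p, ssw / df_w


def one_way_anova(groups) -> AnovaResult:
    """Standard one-way fixed-effects ANOVA across the given groups."""
    groups = _check_groups(groups)
    sizes = np.array([g.size for g in groups])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    x = np.concatenate(groups)[None, :]
    F, p, msw = _anova_from_matrix(x, starts, sizes)
    if msw[0] == 0:
        raise ValueError("zero within-group variance everywhere; F undefined")
    N, k = int(sizes.sum()), len(groups)
    return AnovaResult(F=float(F[0]), p=float(p[0]), df_between=k - 1, df_within=N - k)


def tukey_hsd(groups, alpha: float = 0.05, labels=None,
              comparisons: str = "all_pairs") -> pd.DataFrame:
    """Tukey honest-significant-difference post hoc comparisons.

    p-values use the studentized range with k groups and the pooled
    within-group degrees of freedom.  ``comparisons`` may be "all_pairs" or
    "vs_last" (each group against the final group, e.g. bands vs the intact
    reference).
    """
    groups = _check_groups(groups)
    k = len(groups)
    labels = list(labels) if labels is not None else list(range(k))
    sizes = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    df_w = int(sizes.sum()) - k
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msw = ssw / df_w
    if msw == 0:
        raise ValueError("zero within-group variance; Tukey HSD undefined")

    pairs = ([(i, j) for i in range(k) for j in range(i + 1, k)]
             if comparisons == "all_pairs"
             else [(i, k - 1) for i in range(k - 1)])
    rows = []
    for i, j in pairs:
        diff = means[i] - means[j]
        se = np.sqrt(msw / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_w))
        rows.append({
            "group_a": labels[i], "group_b": labels[j], "diff": diff,
            "q": q, "p": p, "significant": p < alpha,
        })
    return pd.DataFrame(rows)


def welch_test(a, b) -> tuple[float, float]:
    """Welch two-sided t-test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class McAnovaResult:
    """Monte-Carlo error-propagated ANOVA output."""

    f_values: np.ndarray
    p_values: np.ndarray
    baseline_F: float
    baseline_p: float
    seed: int
    n_iter: int
    alpha: float = 0.05
    mean_F: float = field(init=False)
    significant_fraction: float = field(init=False)

    def __post_init__(self):
        self.mean_F = float(np.mean(self.f_values))
        self.significant_fraction = float(np.mean(self.p_values < self.alpha))


def mc_propagated_anova(groups, ses, n_iter: int = 500, seed: int = 0,
                        alpha: float = 0.05) -> McAnovaResult:
    """One-way ANOVA with per-value measurement uncertainty propagated by
    Monte Carlo: each iteration perturbs every value j by noise drawn from
    N(0, se_j^2), recomputes the ANOVA, and the F distribution across the
    iterations is summarised.

    ``groups`` and ``ses`` are parallel sequences of equal-length arrays.
    Deterministic under a fixed seed; the zero-SE limit reproduces the
    baseline F in every iteration exactly.
    """
    groups = _check_groups(groups)
    ses = [np.asarray(s, dtype=float) for s in ses]
    if len(ses) != len(groups) or any(s.size != g.size for s, g in zip(ses, groups)):
        raise ValueError("ses must align with groups")
    if any(np.any(s < 0) for s in ses):
        raise ValueError("SEs must be non-negative")

    sizes = np.array([g.size for g in groups])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    values = np.concatenate(groups)
    se_all = np.concatenate(ses)

    F0, p0, msw0 = _anova_from_matrix(values[None, :], starts, sizes)
    if msw0[0] == 0:
        raise ValueError("zero within-group variance in the baseline")

    rng = substream(seed, "mc_propagated_anova")
    noise = rng.standard_normal((n_iter, values.size)) * se_all
    F, p, _ = _anova_from_matrix(values[None, :] + noise, starts, sizes)
    return McAnovaResult(f_values=F, p_values=p, baseline_F=float(F0[0]),
                         baseline_p=float(p0[0]), seed=seed, n_iter=n_iter, alpha=alpha)


def resampled_cell_stats(values, n_iter: int = 500, m: int = 300, seed: int = 0,
                         replace: bool = False) -> tuple[float, float]:
    """Repeatedly draw m observations from a cell and summarise the means.

    Draws are without replacement by default (a resample of the cell, not a
    bootstrap); returns (mean of the resampled means, SD of the resampled
    means, ddof=1).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if not replace and n < m:
        raise ValueError(
            f"cell has n={n} < m={m} observations; sampling without replacement "
            "impossible (pass replace=True to bootstrap instead)"
        )
    rng = substream(seed, "resampled_cell_stats")
    if replace:
        idx = rng.integers(0, n, size=(n_iter, m))
    else:
        keys = rng.random((n_iter, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    means = values[idx].mean(axis=1)
    return float(means.mean()), float(means.std(ddof=1))
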