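"""Group comparisons, repeatability machinery and sensitivity analysis.

Connectivity values (effective coherence, or percentage coupling time) are
compared between groups with non-parametric tests; consistency across
repeated 3-minute segments is assessed with Friedman and Kruskal-Wallis
tests; the segment-shuffle procedure guards against the timing of a
segment acting as a confound; Cohen's d quantifies effect sizes, and
``sensitivity_mdes`` computes the minimum effect size detectable at the
study's sample sizes.

Tables follow a tidy convention ("cohort table"): one row per
(subject, group, segment, pair[, direction]) with a ``value`` column.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "rank_sum",
    "friedman_repeats",
    "kruskal_wallis_per_subject",
    "cohens_d",
    "shuffled_segment_test",
    "sensitivity_mdes",
    "age_regression",
    "ARE_FACTORS",
]

#: Asymptotic relative efficiency of the Wilcoxon rank-sum test vs the
#: t-test, by parent distribution (the G*Power "A.R.E. method" factors).
#: ``min`` is the worst-case bound 0.864, G*Power's default.
ARE_FACTORS = {
    "min": 0.864,
    "normal": 3.0 / np.pi,
    "uniform": 1.0,
    "logistic": np.pi ** 2 / 9.0,
    "laplace": 1.5,
}


def rank_sum(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P-value.

    Exact when the smaller group has <= 10 observations and there are no
    ties; otherwise the normal approximation with midrank tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def friedman_repeats(blocks: np.ndarray | pd.DataFrame) -> float:
    """Friedman repeated-measures P-value over (subjects x segments) blocks.

    Rows with missing entries are dropped with a warning (the test needs
    complete blocks).  P > 0.05 supports treating segments as repeated
    measures of a stable quantity.
    """
    arr = blocks.to_numpy(dtype=float) if isinstance(blocks, pd.DataFrame) else np.asarray(
        blocks, dtype=float
    )
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise ValueError("need a 2-D (subjects x >=3 segments) table")
    complete = ~np.isnan(arr).any(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {np.count_nonzero(~complete)} incomplete block(s)",
            UserWarning,
            stacklevel=2,
        )
    arr = arr[complete]
    if arr.shape[0] < 2:
        raise ValueError("fewer than 2 complete blocks")
    if np.all(arr == arr[:, :1]):  # constant within every block: no evidence of trend
        return 1.0
    return float(stats.friedmanchisquare(*arr.T).pvalue)


def kruskal_wallis_per_subject(groups: Sequence[Sequence[float]]) -> float:
    """Kruskal-Wallis P-value across one subject's repeat groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.kruskal(*arrays).pvalue)


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d with the pooled-variance convention.

    d = (mean_a - mean_b) / s_pooled, where s_pooled uses n - 1 weights.
    Returns NaN (with a warning) when the pooled SD is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        warnings.warn("zero pooled standard deviation; effect size undefined",
                      UserWarning, stacklevel=2)
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def shuffled_segment_test(
    table: pd.DataFrame,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Percentage of segment-shuffled group comparisons that are significant.

    Per shuffle, one uniformly random segment value is drawn for every
    subject and a rank-sum test compares the groups; the statistic is
    100 * (#shuffles with P < alpha) / n_shuffles.  Subjects with no
    segments are excluded with a warning.

    ``table`` needs columns subject, group, segment, value and exactly two
    group labels.
    """
    required = {"subject", "group", "segment", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError("table must contain exactly two groups")

    # per-subject value arrays, in a stable subject order
    subj_values: dict[str, np.ndarray] = {}
    subj_group: dict[str, str] = {}
    for (subj, grp), sub in table.groupby(["subject", "group"], sort=True):
        v = sub.sort_values("segment")["value"].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            warnings.warn(f"subject {subj} has no segments; excluded", UserWarning,
                          stacklevel=2)
            continue
        subj_values[subj] = v
        subj_group[subj] = grp

    subjects = list(subj_values)
    ga = [s for s in subjects if subj_group[s] == groups[0]]
    gb = [s for s in subjects if subj_group[s] == groups[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 subjects with segments")

    n_sig = 0
    for _ in range(n_shuffles):
        draw = {s: v[rng.integers(v.size)] for s, v in subj_values.items()}
        p = rank_sum([draw[s] for s in ga], [draw[s] for s in gb])
        n_sig += p < alpha
    return 100.0 * n_sig / n_shuffles


def sensitivity_mdes(
    n1: int,
    n2: int,
    alpha: float = 0.05,
    power: float = 0.80,
    parent: str = "min",
    test: str = "wilcoxon",
) -> float:
    """Minimum detectable effect size (Cohen's d), two-sided two-sample design.

    Noncentral-t root finding; for ``test='wilcoxon'`` the sample sizes are
    first multiplied by the asymptotic-relative-efficiency factor of the
    rank-sum test for the chosen ``parent`` distribution (the G*Power
    A.R.E. method; ``'min'`` is the distribution-free worst case 0.864 and
    the G*Power default).  ``test='t'`` skips the correction.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if test == "wilcoxon":
        try:
            are = ARE_FACTORS[parent]
        except KeyError:
            raise ValueError(f"unknown parent {parent!r}; choose from {sorted(ARE_FACTORS)}")
    elif test == "t":
        are = 1.0
    else:
        raise ValueError("test must be 'wilcoxon' or 't'")
    m1, m2 = n1 * are, n2 * are
    df = m1 + m2 - 2
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    scale = np.sqrt(m1 * m2 / (m1 + m2))

    def achieved_power(d: float) -> float:
        ncp = d * scale
        p = float(stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp))
        if np.isnan(p):  # large-df regime where scipy's nct loses accuracy
            p = float(stats.norm.sf(t_crit - ncp) + stats.norm.cdf(-t_crit - ncp))
        return p

    lo, hi = 1e-9, 1.0
    while achieved_power(hi) < power:
        hi *= 2
        if hi > 1e3:
            raise RuntimeError("could not bracket the effect-size root")
    return float(optimize.brentq(lambda d: achieved_power(d) - power, lo, hi, xtol=1e-10))


class RegressionResult(NamedTuple):
    slope: float
    r: float
    pvalue: float


def age_regression(values: Sequence[float], ages: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares regression of connectivity values on age.

    Returns the slope, the Pearson correlation r and its two-sided P-value.
    Constant values give r = 0, P = 1 by convention.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(ages, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need matching arrays of length >= 3")
    if np.all(y == y[0]):
        return RegressionResult(0.0, 0.0, 1.0)
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.rvalue), float(res.pvalue))
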