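"""Univariate statistics battery for metabolite relative integrals.

Routing convention: a comparison runs parametric (t/ANOVA family, means)
only when Shapiro-Wilk does not reject normality in any group and Levene
does not reject equal variances, both at alpha = 0.05; otherwise it runs
nonparametric (Kruskal-Wallis family, medians).

Longitudinal two-timepoint comparisons are dropout-aware: with fewer than
3 dropouts the unpaired observations are discarded and a paired t-test is
used; with 3 or more, a paired t-test on the complete pairs and a Welch
t-test on the unpaired remainders are combined with Fisher's p-value
pooling (the "partially paired" test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("rheumet.unistats")

ALPHA = 0.05

__all__ = [
    "ALPHA", "UnivariateResult", "CorrelationScreen",
    "normality_check", "variance_check", "correlation_screen",
    "paired_timepoint_test", "fisher_pool", "bh_adjust",
    "multigroup_compare", "percent_difference",
]


@dataclass
class UnivariateResult:
    metabolite: str
    comparison: str
    test_used: str
    p: float
    q: float = np.nan
    central_tendency: dict = field(default_factory=dict)
    ct_kind: str = "mean"          # mean (parametric) or median
    percent_difference: float = np.nan
    routing: dict = field(default_factory=dict)


@dataclass
class CorrelationScreen:
    rho: pd.DataFrame
    p: pd.DataFrame


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def variance_check(groups) -> float:
    """Levene's test (center = mean) p-value for equality of variances."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    return float(stats.levene(*gs, center="mean").pvalue)


def correlation_screen(features) -> CorrelationScreen:
    """Pairwise Pearson rho and two-sided p over all metabolite columns."""
    values = features.values if hasattr(features, "values") and hasattr(
        features, "metabolites") else pd.DataFrame(features)
    n = len(values)
    if n < 3:
        raise ValueError("need >= 3 samples")
    cols = list(values.columns)
    sd = values.std(ddof=1)
    dead = [c for c in cols if sd[c] == 0]
    if dead:
        log.warning("zero-variance columns marked undefined: %s", dead)
    rho = values.corr()
    np.fill_diagonal(rho.values, 1.0)
    # two-sided p via the exact t transform
    r = rho.to_numpy(copy=True)
    np.clip(r, -0.999999999, 0.999999999, out=r)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = pd.DataFrame(2 * stats.t.sf(np.abs(t), df=n - 2),
                     index=cols, columns=cols)
    np.fill_diagonal(p.values, 0.0)
    for c in dead:
        rho.loc[c, :] = rho.loc[:, c] = np.nan
        p.loc[c, :] = p.loc[:, c] = np.nan
        rho.loc[c, c] = 1.0
    return CorrelationScreen(rho, p)


def fisher_pool(p_list) -> float:
    """Fisher's method: X = -2 sum(ln p), p = chi2 survival at 2k df."""
    p_arr = np.asarray(list(p_list), dtype=float)
    if p_arr.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p_arr).sum()
    return float(stats.chi2.sf(x, df=2 * p_arr.size))


def paired_timepoint_test(x_a, x_b) -> tuple[float, str]:
    """Dropout-aware two-timepoint comparison.

    ``x_a`` and ``x_b`` map subject -> value at timepoint A / B (mappings or
    pandas Series; missing subjects are the dropouts).  Returns (p,
    test_used) with test_used in {"paired_t", "partially_paired_t"}.
    """
    a = pd.Series(dict(x_a), dtype=float).dropna()
    b = pd.Series(dict(x_b), dtype=float).dropna()
    both = a.index.intersection(b.index)
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(both) < 4:
        raise ValueError("need >= 4 complete pairs")
    n_drop = len(only_a) + len(only_b)
    p_paired = float(stats.ttest_rel(a[both], b[both]).pvalue)
    if n_drop < 3:
        return p_paired, "paired_t"
    if len(only_a) < 2 or len(only_b) < 2:
        log.warning("unpaired remainder too small on one side; "
                    "falling back to complete-pairs paired t-test")
        return p_paired, "paired_t"
    p_unpaired = float(stats.ttest_ind(a[only_a], b[only_b],
                                       equal_var=False).pvalue)
    return fisher_pool([p_paired, p_unpaired]), "partially_paired_t"


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _dunn_sidak(groups: list[np.ndarray], labels) -> dict:
    """Dunn's pairwise rank z-tests with Sidak-adjusted two-sided p."""
    allv = np.concatenate(groups)
    ranks = stats.rankdata(allv)
    n_tot = allv.size
    # tie correction
    _, counts = np.unique(allv, return_counts=True)
    ties = ((counts ** 3 - counts).sum()) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - ties
    means, sizes = [], []
    start = 0
    for g in groups:
        means.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    k = len(groups)
    m = k * (k - 1) // 2
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (means[i] - means[j]) / se
            p_raw = 2 * stats.norm.sf(abs(z))
            out[(labels[i], labels[j])] = float(
                min(1.0, 1.0 - (1.0 - p_raw) ** m))
    return out


def sidak_adjust(p_raw: float, m: int) -> float:
    """Sidak family-wise adjustment 1 - (1 - p)^m."""
    return float(min(1.0, 1.0 - (1.0 - p_raw) ** m))


def multigroup_compare(values, groups) -> tuple[float, dict, str]:
    """Omnibus + post-hoc comparison of >= 3 unpaired groups.

    Runs ANOVA + Tukey HSD when every group passes Shapiro-Wilk and Levene
    passes (all p >= 0.05), else Kruskal-Wallis + Dunn pairwise z-tests with
    Sidak correction.  Returns (omnibus p, {pair: adjusted p}, route).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    gs = [values[groups == g] for g in labels]
    if any(g.size < 3 for g in gs):
        raise ValueError("every group needs n >= 3")
    shapiro_ps = [normality_check(g)[1] for g in gs]
    levene_p = variance_check(gs)
    parametric = all(p >= ALPHA for p in shapiro_ps) and levene_p >= ALPHA
    if parametric:
        omnibus = float(stats.f_oneway(*gs).pvalue)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        tk = pairwise_tukeyhsd(values, groups, alpha=ALPHA)
        posthoc = {}
        for row in tk.summary().data[1:]:
            posthoc[(str(row[0]), str(row[1]))] = float(row[3])
        return omnibus, posthoc, "parametric"
    omnibus = float(stats.kruskal(*gs).pvalue)
    return omnibus, _dunn_sidak(gs, labels), "nonparametric"


def percent_difference(group_a, group_b, route: str = "parametric") -> float:
    """100 * (CT_b - CT_a) / CT_a with CT = mean (parametric) or median."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    ct = np.mean if route == "parametric" else np.median
    ct_a, ct_b = ct(a), ct(b)
    if ct_a == 0:
        return float("nan")
    return float(100.0 * (ct_b - ct_a) / ct_a)
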