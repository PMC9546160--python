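"""Group-comparison statistics.

The layer mirrors a conventional neuropathology analysis plan:
normality is assessed per endpoint (Shapiro-Wilk plus a Q-Q summary);
approximately normal endpoints are compared with a one-way linear model
and all pairwise least-square-mean contrasts with Tukey family-wise
adjustment; non-normal endpoints use Kruskal-Wallis with Dunn's post
hoc (Holm-adjusted by default) or the Mann-Whitney U test for two
groups; ordered binary outcomes (e.g. sex by group) use the
Cochran-Armitage chi-square test for trend. Alpha is 0.05, two-sided,
throughout.

Dunn's test and the Cochran-Armitage statistic are computed here from
their rank/score formulas (with tie corrections); the surrounding
machinery (Shapiro-Wilk, Kruskal-Wallis H, Mann-Whitney U, OLS, Holm)
comes from scipy and statsmodels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ModelError

ALPHA = 0.05


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalityResult:
    """Shapiro-Wilk outcome plus a machine-readable Q-Q summary."""

    w: float
    p: float
    n: int
    #: Pearson correlation of sample vs theoretical normal quantiles
    qq_correlation: float
    #: largest absolute deviation of standardised sample quantiles
    #: from the theoretical normal quantiles
    qq_max_deviation: float

    @property
    def normal_at_alpha(self) -> bool:
        return self.p >= ALPHA


def check_normality(values) -> NormalityResult:
    """Shapiro-Wilk test with a Q-Q plot summary.

    Requires n >= 3 and nonzero spread; a constant sample is degenerate
    and raises :class:`InputError`.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise InputError(f"normality check needs n >= 3, got n = {v.size}")
    if np.ptp(v) == 0:
        raise InputError("normality check is degenerate for a constant sample")
    w, p = sps.shapiro(v)
    order = np.sort(v)
    z = (order - order.mean()) / order.std(ddof=1)
    theo = sps.norm.ppf((np.arange(1, v.size + 1) - 0.375) / (v.size + 0.25))
    r = float(np.corrcoef(z, theo)[0, 1])
    return NormalityResult(
        w=float(w), p=float(p), n=int(v.size),
        qq_correlation=r,
        qq_max_deviation=float(np.max(np.abs(z - theo))),
    )


# ---------------------------------------------------------------------------
# linear model + Tukey least-square-mean contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparisonResult:
    """One pairwise contrast from a group-comparison procedure."""

    contrast: tuple[str, str]
    estimate: float
    p_unadjusted: float
    p_adjusted: float
    method: str
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_adjusted < self.alpha


def _group_arrays(table: pd.DataFrame, response: str, group: str):
    if response not in table.columns or group not in table.columns:
        raise InputError(
            f"table lacks column {response!r} or {group!r}")
    sub = table[[response, group]].dropna()
    levels = list(dict.fromkeys(sub[group]))  # first-appearance order
    arrays = {g: sub.loc[sub[group] == g, response].to_numpy(dtype=float)
              for g in levels}
    return levels, arrays


def compare_groups_lm(
    table: pd.DataFrame,
    response: str,
    group: str = "group",
) -> list[GroupComparisonResult]:
    """One-way linear model with Tukey-adjusted pairwise contrasts.

    Fits ``response ~ group`` by OLS and compares least-square (group)
    means for every pair, with family-wise adjustment from the
    studentized-range distribution (Tukey-Kramer for unbalanced
    groups). Unadjusted p-values come from the pooled-error t
    statistic of each contrast.
    """
    levels, arrays = _group_arrays(table, response, group)
    if len(levels) < 2:
        raise ModelError(f"need >= 2 groups, got {len(levels)}")
    ns = {g: a.size for g, a in arrays.items()}
    if any(n < 2 for n in ns.values()):
        raise ModelError("need >= 2 observations per group")
    k = len(levels)
    n_total = sum(ns.values())
    df_resid = n_total - k
    means = {g: a.mean() for g, a in arrays.items()}
    sse = sum(((a - means[g]) ** 2).sum() for g, a in arrays.items())
    mse = sse / df_resid
    if mse == 0:
        raise ModelError("residual variance is zero; contrasts undefined")
    results = []
    for a, b in itertools.combinations(levels, 2):
        diff = means[a] - means[b]
        se_t = np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
        t = diff / se_t
        p_unadj = float(2 * sps.t.sf(abs(t), df_resid))
        # Tukey-Kramer: q statistic against the studentized range
        q = abs(diff) / np.sqrt(mse / 2 * (1 / ns[a] + 1 / ns[b]))
        p_adj = float(np.clip(sps.studentized_range.sf(q, k, df_resid), 0, 1))
        results.append(GroupComparisonResult(
            contrast=(a, b), estimate=float(diff),
            p_unadjusted=p_unadj, p_adjusted=max(p_adj, p_unadj),
            method="lm_lsmeans_tukey"))
    return results


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KruskalDunnResult:
    """Kruskal-Wallis omnibus outcome with Dunn pairwise contrasts."""

    h: float
    p: float
    pairwise: pd.DataFrame  # contrast_a, contrast_b, z, p_unadjusted, p_adjusted
    adjust: str


def kruskal_dunn(
    table: pd.DataFrame,
    response: str,
    group: str = "group",
    adjust: str = "holm",
) -> KruskalDunnResult:
    """Kruskal-Wallis test with Dunn's post hoc comparisons.

    The omnibus H (tie-corrected) comes from scipy; Dunn z statistics
    are computed from mean ranks over the pooled sample with the tie
    correction to the rank variance, and adjusted with the configured
    family-wise method (Holm by default).
    """
    levels, arrays = _group_arrays(table, response, group)
    if len(levels) < 2:
        raise InputError(f"need >= 2 groups, got {len(levels)}")
    pooled = np.concatenate([arrays[g] for g in levels])
    if np.ptp(pooled) == 0:
        # no variation anywhere: H = 0, everything ties
        pairwise = pd.DataFrame(
            [(a, b, 0.0, 1.0, 1.0)
             for a, b in itertools.combinations(levels, 2)],
            columns=["contrast_a", "contrast_b", "z",
                     "p_unadjusted", "p_adjusted"])
        return KruskalDunnResult(h=0.0, p=1.0, pairwise=pairwise,
                                 adjust=adjust)
    h, p = sps.kruskal(*[arrays[g] for g in levels])

    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + [arrays[g].size for g in levels])
    mean_ranks = {g: ranks[bounds[i]:bounds[i + 1]].mean()
                  for i, g in enumerate(levels)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1))
    rank_var = n_total * (n_total + 1) / 12 - tie_term
    rows = []
    for a, b in itertools.combinations(levels, 2):
        se = np.sqrt(rank_var * (1 / arrays[a].size + 1 / arrays[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append((a, b, float(z), float(2 * sps.norm.sf(abs(z)))))
    p_unadj = [r[3] for r in rows]
    p_adj = multipletests(p_unadj, method=adjust)[1]
    pairwise = pd.DataFrame(
        [(a, b, z, pu, pa) for (a, b, z, pu), pa in zip(rows, p_adj)],
        columns=["contrast_a", "contrast_b", "z",
                 "p_unadjusted", "p_adjusted"])
    return KruskalDunnResult(h=float(h), p=float(p), pairwise=pairwise,
                             adjust=adjust)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration for small tie-free samples, normal
    approximation with tie correction otherwise (scipy's ``auto``
    policy). Returns ``(U, p)`` with U the statistic of the first
    sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("Mann-Whitney requires two non-empty samples")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# chi-square test for trend
# ---------------------------------------------------------------------------

def chi2_trend(
    successes,
    totals,
    scores=None,
) -> tuple[float, float]:
    """Cochran-Armitage chi-square test for trend in proportions.

    Parameters
    ----------
    successes, totals
        Per ordered group: number of positive outcomes and group total.
    scores
        Group scores; equally spaced integers by default.

    Returns
    -------
    (statistic, p)
        The one-degree-of-freedom trend chi-square and its p-value.
    """
    r = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if r.shape != n.shape or r.ndim != 1 or r.size < 2:
        raise InputError("need matched 1-D successes/totals for >= 2 groups")
    if np.any(n <= 0):
        raise InputError("every group must have a positive total")
    if np.any(r < 0) or np.any(r > n):
        raise InputError("successes must lie in [0, total] per group")
    x = (np.arange(r.size, dtype=float) if scores is None
         else np.asarray(scores, dtype=float))
    n_total = n.sum()
    p_bar = r.sum() / n_total
    if p_bar in (0.0, 1.0):
        return 0.0, 1.0  # all outcomes identical: no trend testable
    num = (x * (r - n * p_bar)).sum() ** 2
    den = p_bar * (1 - p_bar) * ((n * x**2).sum() - (n * x).sum() ** 2 / n_total)
    stat = num / den
    return float(stat), float(sps.chi2.sf(stat, df=1))
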