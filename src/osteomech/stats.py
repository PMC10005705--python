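"""Exact small-sample nonparametric statistics.

Group comparisons use the Mann-Whitney U test with the null distribution
enumerated over every assignment of the pooled observations to the two
groups (C(n1+n2, n1) labelings), which is feasible for the cohort sizes
of a rodent study (n = 6 per group gives 924 labelings).  Ties are
handled with mid-ranks and enumeration over the observed multiset.  The
two-sided p-value doubles the smaller tail and is capped at 1, matching
the exact two-sided convention of the major statistics packages; at
n = 6 + 6 the smallest attainable two-sided p is therefore
2/924 ~ 0.00216, printed as 0.002.

Longitudinal designs are compared week by week with pairwise exact tests,
with a Kruskal-Wallis omnibus across weeks within each group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "LongitudinalComparison",
    "mann_whitney_exact",
    "kruskal_wallis",
    "summarize",
    "table4_report",
]

#: Exact enumeration is used when C(n1+n2, n1) does not exceed this.
DEFAULT_ENUMERATION_BUDGET = 200_000


@dataclass(frozen=True)
class GroupComparison:
    """One two-sample rank comparison."""

    statistic: float  # U of the first sample
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact" or "normal-approx"
    has_ties: bool

    @property
    def u_prime(self) -> float:
        return self.n1 * self.n2 - self.statistic

    @property
    def p_rounded(self) -> float:
        """p to 3 decimal places, the convention of printed tables."""
        return round(self.p_two_sided, 3)


@dataclass
class LongitudinalComparison:
    """Week-by-week pairwise p-values plus within-group omnibus tests."""

    pairwise: pd.DataFrame  # week, measure, pair, U, p, significant
    omnibus: pd.DataFrame  # group, measure, H, p
    alpha: float = 0.05
    posthoc: pd.DataFrame | None = None


@lru_cache(maxsize=512)
def _null_distribution(pooled_ranks: tuple[float, ...], n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of U1 over all labelings of the pooled ranks.

    Returns (support, counts).  Cached: the distribution depends only on
    the pooled rank multiset and n1, so repeated tests on untied data of
    the same sizes reuse one enumeration.
    """
    ranks = np.asarray(pooled_ranks)
    idx = range(len(pooled_ranks))
    offset = n1 * (n1 + 1) / 2.0
    u_values = np.fromiter(
        (ranks[list(c)].sum() - offset for c in combinations(idx, n1)),
        dtype=float,
        count=math.comb(len(pooled_ranks), n1),
    )
    support, counts = np.unique(u_values, return_counts=True)
    return support, counts


def _exact_p(u_obs: float, support: np.ndarray, counts: np.ndarray, n1: int, n2: int) -> float:
    total = counts.sum()
    lower = counts[support <= u_obs + 1e-9].sum() / total
    upper = counts[support >= u_obs - 1e-9].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def mann_whitney_exact(
    x: np.ndarray,
    y: np.ndarray,
    enumeration_budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> GroupComparison:
    """Two-sided Mann-Whitney U test with an exact permutation null.

    U is computed from mid-rank sums; the null is enumerated in full
    whenever C(n1+n2, n1) fits the budget (always true for two groups of
    up to 7 at the default), otherwise the tie-corrected normal
    approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    has_ties = np.unique(pooled).size < pooled.size
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if math.comb(n1 + n2, n1) <= enumeration_budget:
        support, counts = _null_distribution(tuple(np.sort(ranks)), n1)
        p = _exact_p(u1, support, counts, n1, n2)
        method = "exact"
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
        method = "normal-approx"
    return GroupComparison(
        statistic=u1, n1=n1, n2=n2, p_two_sided=p, method=method, has_ties=has_ties
    )


def kruskal_wallis(
    groups: list[np.ndarray],
) -> tuple[float, float, dict[tuple[int, int], GroupComparison]]:
    """Kruskal-Wallis omnibus with post hoc pairwise exact tests.

    Returns (H, p, posthoc) where H carries the tie correction and p is
    the chi-squared reference p-value; post hoc comparisons are
    unadjusted exact Mann-Whitney tests per group pair (a multiplicity
    adjustment, if desired, is the caller's choice).
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if np.ptp(np.concatenate(arrays)) == 0:
        h, p = 0.0, 1.0  # scipy rejects all-identical data; H is 0 by definition
    else:
        h, p = sps.kruskal(*arrays)
    posthoc = {
        (i, j): mann_whitney_exact(arrays[i], arrays[j])
        for i, j in combinations(range(len(arrays)), 2)
    }
    return float(h), float(p), posthoc


def summarize(sample: np.ndarray) -> tuple[float, float | None]:
    """Arithmetic mean and standard error sd/sqrt(n); SE missing for n=1."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    mean = float(sample.mean())
    if sample.size < 2:
        return mean, None
    return mean, float(sample.std(ddof=1) / math.sqrt(sample.size))


def table4_report(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    weeks: range | None = None,
    include_posthoc: bool = False,
) -> LongitudinalComparison:
    """Week-by-week pairwise comparison of body weight and weight gain.

    ``cohort`` is a tidy table (animal_id, group, week, body_weight_g,
    ...) with three groups and study weeks 1..12 (week 0, the starting
    measurement, supplies the week-1 weight gain when present; otherwise
    weight gain starts at week 2).  For every week and group pair an
    exact Mann-Whitney test is run on body weight (BW) and on the
    week-over-week weight gain (WG); p < alpha is starred.  A
    Kruskal-Wallis omnibus across weeks within each group is reported,
    optionally with all-pairs post hoc tests.
    """
    groups = sorted(cohort["group"].unique())
    if len(groups) != 3:
        raise ValueError(f"expected 3 groups, found {len(groups)}")
    if weeks is None:
        weeks = range(1, 13)
    present = set(cohort["week"].unique())
    missing = [w for w in weeks if w not in present]
    if missing:
        raise ValueError(f"missing study weeks: {missing}")
    wide = cohort.pivot_table(
        index=["group", "animal_id"], columns="week", values="body_weight_g"
    )
    rows = []
    for week in weeks:
        for ga, gb in combinations(groups, 2):
            bw_a = wide.loc[ga][week].to_numpy()
            bw_b = wide.loc[gb][week].to_numpy()
            cmp_bw = mann_whitney_exact(bw_a, bw_b)
            rows.append(
                {
                    "week": week, "measure": "BW", "pair": f"{ga} vs {gb}",
                    "U": cmp_bw.statistic, "p": cmp_bw.p_rounded,
                    "significant": cmp_bw.p_two_sided < alpha,
                }
            )
            prev = week - 1
            if prev in present:
                wg_a = bw_a - wide.loc[ga][prev].to_numpy()
                wg_b = bw_b - wide.loc[gb][prev].to_numpy()
                cmp_wg = mann_whitney_exact(wg_a, wg_b)
                rows.append(
                    {
                        "week": week, "measure": "WG", "pair": f"{ga} vs {gb}",
                        "U": cmp_wg.statistic, "p": cmp_wg.p_rounded,
                        "significant": cmp_wg.p_two_sided < alpha,
                    }
                )
    omnibus_rows = []
    posthoc_rows: list[dict] = []
    for g in groups:
        samples = [wide.loc[g][w].to_numpy() for w in weeks]
        h, p, post = kruskal_wallis(samples)
        omnibus_rows.append({"group": g, "measure": "BW", "H": h, "p": p})
        if include_posthoc:
            wk = list(weeks)
            for (i, j), c in post.items():
                posthoc_rows.append(
                    {
                        "group": g, "week_a": wk[i], "week_b": wk[j],
                        "U": c.statistic, "p": c.p_rounded,
                        "significant": c.p_two_sided < alpha,
                    }
                )
    return LongitudinalComparison(
        pairwise=pd.DataFrame(rows),
        omnibus=pd.DataFrame(omnibus_rows),
        alpha=alpha,
        posthoc=pd.DataFrame(posthoc_rows) if include_posthoc else None,
    )
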