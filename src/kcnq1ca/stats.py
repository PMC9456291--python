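"""Group-comparison test selection for cohort summary metrics.

Normality of every group is checked with Shapiro-Wilk at alpha = 0.05; if
all groups pass, parametric tests are used (two-tailed t-test for two
groups, one-way ANOVA with Bonferroni-corrected pairwise t-tests for
more), otherwise their rank-based counterparts (Mann-Whitney U, or
Kruskal-Wallis with Dunn's post hoc test).  Significance is reported with
the usual star convention (* p<0.05, ** p<0.01, *** p<0.001).

Only the selection logic and reporting live here; the test statistics are
scipy.stats'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


class StatsError(ValueError):
    """Raised for group data the decision tree cannot handle."""


@dataclass(frozen=True)
class GroupData:
    groups: dict  # name -> 1-D array of observations
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise StatsError("need at least 2 groups")
        for name, vals in self.groups.items():
            if len(vals) < 3:
                raise StatsError(
                    f"group {name!r} has {len(vals)} observations; "
                    "Shapiro-Wilk needs at least 3"
                )

    def arrays(self) -> list[np.ndarray]:
        return [np.asarray(v, dtype=float) for v in self.groups.values()]


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    stars: str
    normality_p: dict
    posthoc: dict = field(default_factory=dict)


def significance_stars(p: float) -> str:
    """Star string as a pure function of p."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _dunn_posthoc(arrays, names, alpha):
    """Dunn's z-tests on mean ranks with Bonferroni correction."""
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    # tie correction for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n - 1))
    idx = np.cumsum([0] + [len(a) for a in arrays])
    mean_ranks = [ranks[idx[i] : idx[i + 1]].mean() for i in range(len(arrays))]
    m = len(list(combinations(range(len(arrays)), 2)))
    out = {}
    for i, j in combinations(range(len(arrays)), 2):
        se = np.sqrt((n * (n + 1) / 12 - tie_term) * (1 / len(arrays[i]) + 1 / len(arrays[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2 * sps.norm.sf(abs(z)) * m)
        out[(names[i], names[j])] = {"z": float(z), "p": float(p),
                                     "stars": significance_stars(p)}
    return out


def compare_groups(data: GroupData) -> ComparisonResult:
    """Shapiro-Wilk-gated two-or-more group comparison."""
    names = list(data.groups)
    arrays = data.arrays()
    norm_p = {}
    for name, arr in zip(names, arrays):
        if np.ptp(arr) == 0:
            norm_p[name] = 0.0  # a constant group is degenerate, go nonparametric
        else:
            norm_p[name] = float(sps.shapiro(arr).pvalue)
    all_normal = all(p >= data.alpha for p in norm_p.values())

    posthoc = {}
    if len(arrays) == 2:
        if all_normal:
            res = sps.ttest_ind(arrays[0], arrays[1])
            name = "t-test"
        else:
            res = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
            name = "Mann-Whitney"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if all_normal:
            res = sps.f_oneway(*arrays)
            name = "ANOVA"
            m = len(list(combinations(range(len(arrays)), 2)))
            for i, j in combinations(range(len(arrays)), 2):
                r = sps.ttest_ind(arrays[i], arrays[j])
                p_adj = min(1.0, float(r.pvalue) * m)
                posthoc[(names[i], names[j])] = {
                    "t": float(r.statistic), "p": p_adj,
                    "stars": significance_stars(p_adj),
                }
        else:
            res = sps.kruskal(*arrays)
            name = "Kruskal-Wallis"
            posthoc = _dunn_posthoc(arrays, names, data.alpha)
        stat, p = float(res.statistic), float(res.pvalue)

    return ComparisonResult(name, stat, p, significance_stars(p), norm_p, posthoc)


def compare_frame(df, group_col: str = "group", value_col: str = "value") -> ComparisonResult:
    """Convenience wrapper for a tidy two-column DataFrame."""
    groups = {str(g): sub[value_col].to_numpy() for g, sub in df.groupby(group_col)}
    return compare_groups(GroupData(groups))
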