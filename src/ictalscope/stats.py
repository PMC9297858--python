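"""Nonparametric group statistics used throughout the analyses.

Rank-sum (Mann-Whitney), signed-rank, and two-sample Kolmogorov-Smirnov tests
delegate to scipy.stats with the conventions fixed here (two-sided, normal
approximation with continuity correction for larger samples, exact
enumeration for small tie-free samples).  The Dunn post hoc test after a
Kruskal-Wallis omnibus, with Benjamini-Hochberg adjustment across the
pairwise family, is implemented directly.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_sum_test",
    "signed_rank_test",
    "ks_test",
    "dunn_kw_bh",
]


def _clean(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError(f"group {name!r} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"group {name!r} contains non-finite values")
    return arr


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration when both samples have at most 10 observations and no
    ties cross the groups; otherwise the normal approximation with continuity
    correction.  Returns (U statistic of the first sample, p).
    """
    a = _clean(a, "a")
    b = _clean(b, "b")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) else "asymptotic"
    res = sst.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(paired_diffs) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Exact for up to 15 nonzero tie-free differences, asymptotic with
    continuity correction otherwise.  Zero differences are discarded; an
    all-zero input is degenerate and returns (0, 1).
    """
    d = np.asarray(paired_diffs, dtype=float)
    if d.size == 0:
        raise ValueError("no paired differences")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return 0.0, 1.0  # degenerate: no signal either way
    no_ties = np.unique(np.abs(nonzero)).size == nonzero.size
    method = "exact" if (nonzero.size <= 15 and no_ties) else "approx"
    res = sst.wilcoxon(nonzero, alternative="two-sided", method=method,
                       correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def ks_test(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_a − ECDF_b|, asymptotic p."""
    a = _clean(a, "a")
    b = _clean(b, "b")
    res = sst.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def dunn_kw_bh(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Dunn's pairwise post hoc test after Kruskal-Wallis, BH-adjusted.

    Observations are pooled and mid-ranked; for groups i, j the Dunn statistic
    is

        z = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − T] · (1/n_i + 1/n_j)),

    with the tie correction T = Σ(t³ − t) / [12(N − 1)] over tie groups of
    size t.  Two-sided normal p-values are Benjamini-Hochberg adjusted across
    the pairwise family.  Returns a tidy DataFrame with one row per pair and
    the omnibus H and p attached as ``.attrs``.
    """
    if len(groups) < 3:
        raise ValueError("Dunn post hoc requires at least 3 groups")
    labels = list(groups)
    data = {k: _clean(v, k) for k, v in groups.items()}
    H, p_omnibus = sst.kruskal(*data.values())

    pooled = np.concatenate([data[k] for k in labels])
    ranks = sst.rankdata(pooled)
    N = pooled.size
    mean_rank: dict[str, float] = {}
    i = 0
    for k in labels:
        n = data[k].size
        mean_rank[k] = float(ranks[i : i + n].mean())
        i += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for gi, gj in itertools.combinations(labels, 2):
        ni, nj = data[gi].size, data[gj].size
        se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
        z = (mean_rank[gi] - mean_rank[gj]) / se
        p = 2.0 * sst.norm.sf(abs(z))
        rows.append({"group_a": gi, "group_b": gj, "z": z, "p_raw": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    table.attrs["kruskal_H"] = float(H)
    table.attrs["kruskal_p"] = float(p_omnibus)
    return table
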