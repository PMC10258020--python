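"""Statistical kernel used by every analysis stage.

Wilcoxon rank-sum (Mann-Whitney U) with an exact enumeration mode for
small samples, Pearson correlation with its t-based p-value, one-way ANOVA
with Tukey HSD (Tukey-Kramer for unbalanced groups), Benjamini-Hochberg
FDR, and a hypergeometric over-representation test.

The exact Wilcoxon mode enumerates all C(n1+n2, n1) group assignments of
the midranks, which is the null permutation distribution of U; it is the
default whenever n1+n2 <= 12.  Two-sided p-values for discrete statistics
are min(1, 2*min(P(U <= u), P(U >= u))).
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.libqsturng import qsturng
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    q_value: float | None = None
    n1: int | None = None
    n2: int | None = None


DEFAULT_EXACT_LIMIT = 12


@functools.lru_cache(maxsize=64)
def _studentized_range_grid(k: int, df: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Quantiles q(P) of the studentized range on a cumulative-P grid."""
    ps = np.concatenate([np.linspace(0.10, 0.90, 81), np.linspace(0.905, 0.999, 95)])
    qs = np.array([float(qsturng(p, k, df)) for p in ps])
    return tuple(ps), tuple(qs)


def _studentized_range_p(q: float, k: int, df: int) -> float:
    """Two-sided Tukey p-value 1 - P(Q <= q) by monotone interpolation.

    Clipped to the tabulated range [0.001, 0.9], as the underlying
    studentized-range tables are.
    """
    if not math.isfinite(q):
        return 0.001
    ps, qs = _studentized_range_grid(k, int(df))
    cum = float(np.interp(q, np.asarray(qs), np.asarray(ps)))
    return float(min(max(1.0 - cum, 0.001), 0.9))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # midranks for ties
    n1 = len(x)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return u1, ranks


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    # work in half-rank integer units so tied midranks compare exactly
    r2 = np.rint(2 * ranks).astype(np.int64)
    base = n1 * (n1 + 1)  # 2 * n1(n1+1)/2
    u2_obs = int(round(2 * u_obs))
    total = 0
    n_le = 0
    n_ge = 0
    for combo in itertools.combinations(range(len(r2)), n1):
        u2 = int(r2[list(combo)].sum()) - base
        total += 1
        if u2 <= u2_obs:
            n_le += 1
        if u2 >= u2_obs:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return min(1.0, p)


def wilcoxon_rank_sum(
    x,
    y,
    mode: str = "auto",
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    mode 'exact' enumerates the permutation null of U (midrank ties
    handled exactly); 'normal' uses the tie-corrected normal approximation
    with continuity correction; 'auto' picks exact when n1+n2 <= exact_limit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        mode = "exact" if x.size + y.size <= exact_limit else "normal"
    u1, ranks = _u_statistic(x, y)
    if mode == "exact":
        p = _exact_p(ranks, x.size, u1)
        method = "wilcoxon-exact"
    elif mode == "normal":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        method = "wilcoxon-normal"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(statistic=float(u1), p_value=p, method=method, n1=x.size, n2=y.size)


def pearson(x, y) -> TestResult:
    """Pearson r with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("first vector has zero variance")
    if np.ptp(y) == 0:
        raise ValueError("second vector has zero variance")
    r, p = sps.pearsonr(x, y)
    return TestResult(statistic=float(r), p_value=float(p), method="pearson", n1=x.size)


def anova_tukey(values, groups) -> tuple[TestResult, dict[tuple[str, str], float]]:
    """One-way ANOVA F test plus Tukey HSD pairwise p-values.

    ``groups`` holds a label per observation; levels are ordered by first
    appearance.  Unbalanced designs use the Tukey-Kramer studentized-range
    comparison.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups differ in length")
    levels = list(dict.fromkeys(groups.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least two group levels")
    samples = [values[groups == lv] for lv in levels]
    for lv, s in zip(levels, samples):
        if s.size < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 observations")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance")
    f, p = sps.f_oneway(*samples)
    k = len(levels)
    n_total = values.size
    df_within = n_total - k
    ms_within = sum(((s - s.mean()) ** 2).sum() for s in samples) / df_within
    # Tukey-Kramer studentized-range comparisons; p interpolated from the
    # tabulated studentized-range quantiles (resolution ~1e-3, the table's
    # supported tail range [0.001, 0.9])
    pairwise: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        si, sj = samples[i], samples[j]
        se = math.sqrt(ms_within / 2.0 * (1.0 / si.size + 1.0 / sj.size))
        q = abs(si.mean() - sj.mean()) / se if se > 0 else math.inf
        pairwise[(levels[i], levels[j])] = _studentized_range_p(q, k, df_within)
    result = TestResult(
        statistic=float(f), p_value=float(p), method="anova", n1=int(values.size)
    )
    return result, pairwise


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_ora(query: set, gene_set: set, universe: set) -> TestResult:
    """Over-representation p = P(overlap >= observed) under hypergeometric sampling."""
    query, gene_set, universe = set(query), set(gene_set), set(universe)
    if not query <= universe:
        raise ValueError("query is not a subset of the universe")
    if not gene_set <= universe:
        raise ValueError("gene_set is not a subset of the universe")
    k = len(query & gene_set)
    p = float(sps.hypergeom.sf(k - 1, len(universe), len(gene_set), len(query)))
    return TestResult(
        statistic=float(k),
        p_value=min(1.0, p),
        method="hypergeometric",
        n1=len(query),
        n2=len(gene_set),
    )


def batch_bh(table, p_col: str = "p", family_col: str | None = "family_id"):
    """Add a BH q column to a test table, per family when a family column exists."""
    import pandas as pd

    df = table.copy()
    if family_col and family_col in df.columns:
        df["q"] = df.groupby(family_col)[p_col].transform(lambda s: bh_fdr(s.to_numpy()))
    else:
        df["q"] = bh_fdr(df[p_col].to_numpy())
    return df
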