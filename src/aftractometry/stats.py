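"""Small-sample nonparametric statistics.

Cohorts of this kind are tiny (here 4 low-grade vs 5 high-grade tumor
patients), so the Mann-Whitney test uses the exact permutation null —
every C(n1+n2, n1) assignment of the observed pooled values to the two
groups — rather than the normal approximation.  Ties are handled with
mid-ranks throughout.  Multiple comparisons are controlled with the
Benjamini–Hochberg step-up procedure; correlations use Spearman's rank
coefficient with an exact permutation p-value at very small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "MannWhitneyResult",
    "mann_whitney_exact",
    "bh_adjust",
    "SpearmanResult",
    "spearman_rho",
    "group_compare",
    "correlate_with_li",
]

_EXACT_MWU_LIMIT = 25
_EXACT_SPEARMAN_LIMIT = 9


@dataclass
class MannWhitneyResult:
    u: float          # U statistic of the first sample
    p: float          # two-sided
    method: str       # 'exact' | 'normal'


def _rank_sum_distribution(int_ranks: np.ndarray, n1: int) -> np.ndarray:
    """Counts of subsets of size n1 by integer rank sum (tie-safe DP).

    ``counts[s]`` is the number of ways to pick n1 of the pooled
    (doubled, hence integer) mid-ranks with sum s.  This is exactly the
    enumeration of all C(n, n1) group assignments, computed by dynamic
    programming instead of explicit listing.
    """
    total = int(int_ranks.sum())
    # dp[j, s] = #subsets of size j with rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in int_ranks:
        r = int(r)
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    return dp[n1]


def mann_whitney_exact(x, y, mode: str = "auto") -> MannWhitneyResult:
    """Mann-Whitney U with an exact (permutation) two-sided p-value.

    U is computed from mid-ranks for the first sample.  In exact mode
    the two-sided p is ``min(1, 2 min(P(U <= u), P(U >= u)))`` under the
    permutation null conditioned on the observed pooled values; ties are
    handled exactly.  For combined n beyond 25 (or ``mode='normal'``)
    the tie-corrected normal approximation is used and recorded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    exact = mode == "exact" or (mode == "auto" and n <= _EXACT_MWU_LIMIT)
    if exact:
        int_ranks = np.rint(2 * ranks).astype(np.int64)  # mid-ranks are halves
        counts = _rank_sum_distribution(int_ranks, n1)
        total = comb(n, n1)
        s_obs = int(np.rint(2 * r1))
        p_le = counts[: s_obs + 1].sum() / total
        p_ge = counts[s_obs:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u=float(u1), p=float(p), method="exact")

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u=float(u1), p=1.0, method="normal")
    z = (u1 - mu) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return MannWhitneyResult(u=float(u1), p=float(p), method="normal")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the
    input order.  Thresholding q < alpha reproduces the classic step-up
    rejection set at FDR level alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class SpearmanResult:
    rho: float
    p: float
    method: str  # 'exact' | 't-approx'


def spearman_rho(x, y, method: str = "auto") -> SpearmanResult:
    """Spearman rank correlation with exact or t-approximate two-sided p.

    rho is the Pearson correlation of mid-ranks.  ``method='exact'``
    enumerates all n! pairings (feasible for n <= 9, the default switch
    point); otherwise the usual t approximation with n - 2 degrees of
    freedom is used — this matches what commercial statistics packages
    report at these sample sizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return SpearmanResult(rho=float("nan"), p=float("nan"), method="undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    exact = method == "exact" or (method == "auto" and n <= _EXACT_SPEARMAN_LIMIT)
    if exact:
        rxc = (rx - rx.mean()) / (sx * n)  # so rho_perm = rxc . ry_perm - const
        perms = np.array(list(permutations(ry)))
        rhos = (perms - ry.mean()) / sy @ rxc
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return SpearmanResult(rho=rho, p=p, method="exact")

    if abs(rho) >= 1.0:
        return SpearmanResult(rho=rho, p=0.0, method="t-approx")
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(min(1.0, 2.0 * t_dist.sf(abs(t), df=n - 2)))
    return SpearmanResult(rho=rho, p=p, method="t-approx")


def group_compare(
    metrics: pd.DataFrame,
    group_col: str,
    groups: tuple[str, str],
    measures: list[str],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Exact Mann-Whitney per measure between two groups, BH across measures.

    Returns one row per measure: group medians with (min, max) ranges,
    the U statistic of the first group, the exact two-sided p and the
    BH-adjusted q, flagged significant at q < ``fdr``.
    """
    a_name, b_name = groups
    unknown = [m for m in measures if m not in metrics.columns]
    if unknown:
        raise ValueError(f"unknown measures: {unknown}")
    a = metrics[metrics[group_col] == a_name]
    b = metrics[metrics[group_col] == b_name]
    if a.empty or b.empty:
        raise ValueError(f"both groups must be non-empty ({a_name}: {len(a)}, {b_name}: {len(b)})")
    rows = []
    for m in measures:
        xa = a[m].dropna().to_numpy(dtype=float)
        xb = b[m].dropna().to_numpy(dtype=float)
        res = mann_whitney_exact(xa, xb)
        rows.append(
            {
                "measure": m,
                f"{a_name}_median": np.median(xa),
                f"{a_name}_min": xa.min(),
                f"{a_name}_max": xa.max(),
                f"{b_name}_median": np.median(xb),
                f"{b_name}_min": xb.min(),
                f"{b_name}_max": xb.max(),
                "U": res.u,
                "p": res.p,
                "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def correlate_with_li(
    metrics: pd.DataFrame,
    li_table: pd.DataFrame,
    measures: list[str],
    li_measures: list[str],
    fdr: float = 0.1,
    method: str = "auto",
) -> pd.DataFrame:
    """Spearman correlations over the measure x LI grid, BH over the grid.

    Both tables are joined on their (subject) index; a subject present
    in one but not the other is an error rather than a silent drop.
    """
    if set(metrics.index) != set(li_table.index):
        raise ValueError(
            "subject mismatch between metrics and LI tables: "
            f"{sorted(set(metrics.index) ^ set(li_table.index))}"
        )
    li_aligned = li_table.loc[metrics.index]
    rows = []
    for m in measures:
        if m not in metrics.columns:
            raise ValueError(f"unknown measure {m!r}")
        for li in li_measures:
            if li not in li_table.columns:
                raise ValueError(f"unknown LI measure {li!r}")
            res = spearman_rho(
                metrics[m].to_numpy(dtype=float),
                li_aligned[li].to_numpy(dtype=float),
                method=method,
            )
            rows.append(
                {"measure": m, "li": li, "rho": res.rho, "p": res.p, "method": res.method}
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out
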