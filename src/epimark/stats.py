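"""Statistical primitives shared by every analysis layer.

Conventions chosen to match the common behaviour of statistical
environments used in methylation studies:

* two-sided Fisher exact tests use the probability-mass definition
  (sum of the probabilities of all tables, with the observed margins,
  that are no more probable than the observed table);
* the 2x2 chi-square applies the Yates continuity correction by default;
* rank tests fall back to exact enumeration at small sample sizes and
  use tie/continuity-corrected normal or chi-square approximations
  otherwise.

Only distribution tails (hypergeometric mass, chi-square / t / normal
survival functions) come from scipy; the statistics, enumerations and
two-sided conventions are implemented here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "bh_adjust",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "chi_square",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "spearman",
]

#: relative tolerance on the "no more probable" comparison in the
#: two-sided Fisher tests, guarding against floating-point cliffs
FISHER_REL_TOL = 1e-7

_P_FLOOR = 1e-300


@dataclass
class ContingencyTable:
    """A labelled r x c table of nonnegative integer counts."""

    counts: np.ndarray
    row_labels: Sequence[str] = field(default_factory=list)
    col_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (self.counts < 0).any():
            raise ValueError("contingency table entries must be nonnegative")
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(self.counts.shape[1])]


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    arr = np.asarray(table)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise ValueError("contingency counts must be integers")
        arr = rounded
    arr = arr.astype(np.int64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D count table")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return arr


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact test on a 2x2 table (probability-mass rule).

    Returns 1.0 when any margin is zero (no evidence either way).
    """
    t = _as_counts(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(c1, r1)
    support = np.arange(lo, hi + 1)
    pmf = _sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    keep = pmf <= p_obs * (1.0 + FISHER_REL_TOL)
    return float(min(1.0, pmf[keep].sum()))


def _log_table_prob(t: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - gammaln(t + 1).sum()


def _enumerate_tables(row_sums, col_sums):
    """Yield every nonnegative integer matrix with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(row_idx, remaining_cols, rows):
        if row_idx == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all() and last.sum() == row_sums[-1]:
                yield rows + [last]
            return
        target = row_sums[row_idx]

        def fill(col_idx, left, current):
            if col_idx == c - 1:
                v = left
                if 0 <= v <= remaining_cols[col_idx]:
                    yield current + [v]
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                yield from fill(col_idx + 1, left - v, current + [v])

        for row in fill(0, target, []):
            row_arr = np.asarray(row)
            yield from rec(
                row_idx + 1,
                [rc - rv for rc, rv in zip(remaining_cols, row_arr)],
                rows + [row_arr],
            )

    yield from (np.vstack(rows) for rows in rec(0, list(col_sums), []))


def fisher_exact_rxc(
    table,
    *,
    enumeration_limit: int = 200,
    monte_carlo: bool = False,
    n_draws: int = 100_000,
    seed: int | None = None,
) -> float:
    """Two-sided Fisher exact test on an r x c table by complete
    enumeration over all tables with the observed margins.

    Totals above ``enumeration_limit`` raise unless ``monte_carlo`` is
    set, in which case a seeded permutation estimate (approximate) is
    returned.
    """
    t = _as_counts(table)
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        return 1.0
    # drop empty rows/columns: they carry no probability mass
    t = t[row_sums > 0][:, col_sums > 0]
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    log_margin_const = (
        gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1)
    )
    logp_obs = _log_table_prob(t, log_margin_const)
    cutoff = logp_obs + math.log1p(FISHER_REL_TOL)

    if n > enumeration_limit:
        if not monte_carlo:
            raise ValueError(
                f"table total {n} exceeds enumeration limit {enumeration_limit}; "
                "pass monte_carlo=True for a seeded approximate p-value"
            )
        rng = np.random.default_rng(seed)
        row_labels = np.repeat(np.arange(len(row_sums)), row_sums)
        col_labels = np.repeat(np.arange(len(col_sums)), col_sums)
        hits = 0
        for _ in range(n_draws):
            perm = rng.permutation(col_labels)
            sim = np.zeros_like(t)
            np.add.at(sim, (row_labels, perm), 1)
            if _log_table_prob(sim, log_margin_const) <= cutoff:
                hits += 1
        return max((hits + 1) / (n_draws + 1), _P_FLOOR)

    total = 0.0
    for cand in _enumerate_tables(list(row_sums), list(col_sums)):
        lp = _log_table_prob(cand, log_margin_const)
        if lp <= cutoff:
            total += math.exp(lp)
    return float(min(1.0, max(total, _P_FLOOR)))


def chi_square(table, *, yates: bool | None = None):
    """Pearson chi-square test of independence.

    The Yates continuity correction is applied by default on 2x2 tables
    (``yates=None``); pass ``yates=False`` to disable.

    Returns (statistic, df, p).
    """
    t = _as_counts(table).astype(float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    n = t.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi_square: zero margin")
    expected = row @ col / n
    correction = 0.0
    if (yates or (yates is None and t.shape == (2, 2))) and t.shape == (2, 2):
        correction = 0.5
    dev = np.maximum(np.abs(t - expected) - correction, 0.0)
    stat = float((dev**2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(_sps.chi2.sf(stat, df))
    return stat, df, max(p, _P_FLOOR)


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration (no ties)."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)
    w_obs = ranks[:nx].sum()
    all_idx = range(nx + ny)
    total = math.comb(nx + ny, nx)
    lo_count = 0
    hi_count = 0
    for combo in itertools.combinations(all_idx, nx):
        w = ranks[list(combo)].sum()
        if w <= w_obs + 1e-9:
            lo_count += 1
        if w >= w_obs - 1e-9:
            hi_count += 1
    p = 2.0 * min(lo_count, hi_count) / total
    return min(1.0, max(p, _P_FLOOR))


def wilcoxon_rank_sum(x, y, *, exact_max_n: int = 8) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both samples have at most ``exact_max_n``
    observations and there are no ties; otherwise the tie-corrected
    normal approximation with continuity correction, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size <= exact_max_n and y.size <= exact_max_n and not has_ties:
        return _rank_sum_exact_p(x, y)
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = _sps.rankdata(pooled)
    w = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * float(_sps.norm.sf(z))
    return min(1.0, max(p, _P_FLOOR))


def kruskal_wallis(groups):
    """Kruskal-Wallis H test across two or more groups.

    Returns (H, df, p). With all observations tied the tie-corrected H
    is taken as 0 and p as 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n = pooled.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = _sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if tie_corr <= 0:
        return 0.0, len(groups) - 1, 1.0
    h /= tie_corr
    df = len(groups) - 1
    p = float(_sps.chi2.sf(h, df))
    return float(h), df, min(1.0, max(p, _P_FLOOR))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValueError("zero variance in ranks; correlation undefined")
    return float((a * b).sum() / denom)


def spearman(x, y, *, exact_below_n: int = 10):
    """Spearman rank correlation with mid-rank ties.

    p-value by the t approximation for n >= ``exact_below_n`` and by
    exact permutation enumeration below it. Returns (r, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    r = _pearson(rx, ry)
    if n < exact_below_n:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rp = _pearson(rx, ry[list(perm)])
            total += 1
            if abs(rp) >= abs(r) - 1e-12:
                count += 1
        p = count / total
    else:
        r_c = min(max(r, -1.0), 1.0)
        if abs(r_c) >= 1.0:
            p = _P_FLOOR
        else:
            t = r_c * math.sqrt((n - 2) / (1.0 - r_c**2))
            p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return r, min(1.0, max(p, _P_FLOOR))
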