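"""Statistical primitives behind the caller: the binomial tail test and the
bias tests (rank-sum, Fisher exact).

The binomial tail P(X >= k | n, e) is evaluated through the regularized
incomplete beta function, which is exact and stable for n up to 1e5; when the
tail underflows double precision the log-probability is recovered by
log-space summation of the leading pmf terms so the Phred-scaled score
-10*log10(P) stays finite and correct.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, inf, log10, sqrt

import numpy as np
from scipy import special
from scipy.stats import fisher_exact as _fisher_exact
from scipy.stats import norm


def error_rate_from_quality(q: int | float) -> float:
    """Phred quality -> error probability 10^(-q/10)."""
    if q < 0:
        raise ValueError(f"Phred quality must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def binomial_tail_pvalue(n: int, k: int, e: float) -> float:
    """Upper-tail probability P(X >= k) for X ~ Binomial(n, e).

    Returns exactly 1.0 for k == 0.  May underflow to 0.0 for extreme
    tails; use :func:`binomial_tail_log10` when the score is needed.
    """
    _check_tail_args(n, k, e)
    if k == 0:
        return 1.0
    # sf(k-1) = I_e(k, n-k+1)
    return float(special.betainc(k, n - k + 1, e))


def binomial_tail_log10(n: int, k: int, e: float) -> float:
    """log10 of the upper-tail probability, finite even when the tail
    underflows double precision."""
    _check_tail_args(n, k, e)
    if k == 0:
        return 0.0
    p = float(special.betainc(k, n - k + 1, e))
    if p > 0.0:
        return log10(p)
    # underflow: log-space sum of pmf terms from k; the tail decays
    # geometrically, 400 terms bound the truncation error far below 1 ulp
    j = np.arange(k, min(n, k + 400) + 1)
    logpmf = (special.gammaln(n + 1) - special.gammaln(j + 1)
              - special.gammaln(n - j + 1)
              + j * np.log(e) + (n - j) * np.log1p(-e))
    return float(special.logsumexp(logpmf) / np.log(10.0))


def phred_score(n: int, k: int, e: float) -> float:
    """Variant score -10*log10 P(X >= k); 0 when k == 0."""
    return -10.0 * binomial_tail_log10(n, k, e)


def _check_tail_args(n: int, k: int, e: float) -> None:
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < e < 1.0:
        raise ValueError(f"error rate must be in (0, 1), got {e}")


# ---------------------------------------------------------------------------
# Rank-sum (Wilcoxon / Mann-Whitney) two-sided test
# ---------------------------------------------------------------------------

_EXACT_ENUM_LIMIT = 200_000  # max C(n1+n2, n1) for exhaustive enumeration


def rank_sum_test(x, y) -> float:
    """Two-sided rank-sum p-value comparing samples ``x`` and ``y``.

    Exhaustive enumeration of the permutation null when the number of group
    assignments is small enough to enumerate; otherwise the tie-corrected
    normal approximation.  Fewer than two observations in total, or an empty
    side, returns 1.0 (test not applicable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0 or n1 + n2 < 2:
        return 1.0
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())  # rank sum of x

    if comb(n1 + n2, n1) <= _EXACT_ENUM_LIMIT:
        mean_w = n1 * (n1 + n2 + 1) / 2.0
        dev = abs(w - mean_w)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            total += 1
            ws = ranks[list(idx)].sum()
            if abs(ws - mean_w) >= dev - 1e-9:
                count += 1
        return count / total

    # normal approximation with tie correction
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return 1.0  # all values identical
    z = (abs(w - mean_w) - 0.5) / sqrt(var_w)  # continuity-corrected
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    ranks[order] = np.arange(1, len(values) + 1)
    # average ranks over ties
    for v, c in zip(*np.unique(values, return_counts=True)):
        if c > 1:
            mask = values == v
            ranks[mask] = ranks[mask].mean()
    return ranks


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table; degenerate tables -> 1.0."""
    t = np.asarray(table, dtype=int)
    if t.min() < 0:
        raise ValueError("negative cell count")
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(_fisher_exact(t, alternative="two-sided")[1])


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
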