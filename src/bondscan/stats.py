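"""Statistical tests used by the comparative pipeline.

Mann-Whitney U, chi-square independence and Spearman correlation are
implemented here (with exact small-sample paths) so that their behavior is
fully pinned down; the test suite cross-checks them against independent
reference implementations. Normality checks delegate to statsmodels; the
Ryan-Joiner test is proprietary and is replaced by Anderson-Darling and a
Lilliefors-corrected Kolmogorov-Smirnov test (recorded in the method string).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata
from statsmodels.stats.diagnostic import lilliefors, normal_ad

_ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int = 0
    alternative: str = "two_sided"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| > 1: {self.rho}")


@dataclass(frozen=True)
class ChiSquareResult:
    result: TestResult
    observed: np.ndarray
    expected: np.ndarray
    deviations: np.ndarray          # observed - expected, per cell
    use_rate_delta: np.ndarray      # percentage-point difference of column proportions
    df: int


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of rank arrangements with U = u, for u = 0..n1*n2.

    Classic recurrence: f(u; n1, n2) = f(u - n2; n1 - 1, n2) + f(u; n1, n2 - 1).
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_counts(n1 - 1, n2)
    b = _u_counts(n1, n2 - 1)
    size = n1 * n2 + 1
    out = [0] * size
    for u in range(size):
        if u - n2 >= 0 and u - n2 < len(a):
            out[u] += a[u - n2]
        if u < len(b):
            out[u] += b[u]
    return tuple(out)


def _exact_u_cdf(u: float, n1: int, n2: int) -> float:
    counts = _u_counts(n1, n2)
    total = math.comb(n1 + n2, n1)
    return sum(counts[: int(math.floor(u)) + 1]) / total


def mann_whitney_u(x, y, alternative: str = "two_sided") -> TestResult:
    """Mann-Whitney U from midranks.

    Exact p by enumeration when n1 + n2 <= 20 and the pooled sample has no
    ties; otherwise the normal approximation with tie correction and a 0.5
    continuity correction. ``alternative='greater'`` asks whether x tends to
    exceed y. The returned statistic is U for sample x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if n1 + n2 <= 20 and not has_ties:
        method = "mann-whitney-u/exact"
        p_less = _exact_u_cdf(u1, n1, n2)
        p_greater = _exact_u_cdf(n1 * n2 - u1, n1, n2)
        if alternative == "less":
            p = p_less
        elif alternative == "greater":
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        method = "mann-whitney-u/normal-approx"
        n = n1 + n2
        mean = n1 * n2 / 2.0
        tie_term = ((tie_counts**3 - tie_counts).sum() / (n * (n - 1))
                    if n > 1 else 0.0)
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            sd = math.sqrt(var)
            z_greater = (u1 - mean - 0.5) / sd
            z_less = (u1 - mean + 0.5) / sd
            if alternative == "greater":
                p = sps.norm.sf(z_greater)
            elif alternative == "less":
                p = sps.norm.cdf(z_less)
            else:
                p = min(1.0, 2.0 * min(sps.norm.sf(z_greater),
                                       sps.norm.cdf(z_less)))
    return TestResult(statistic=float(u1), p_value=float(p), method=method,
                      n1=n1, n2=n2, alternative=alternative)


def chi_square_independence(observed) -> ChiSquareResult:
    """Chi-square test of independence on an r x c count matrix.

    Expected counts are the usual margin products E[i,j] = row_i * col_j / N.
    All-zero rows or columns are dropped before testing. Returns per-cell
    deviations (O - E) and the percentage-point difference of column-wise
    proportions (first column minus second, when c == 2).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2:
        raise ValueError("observed must be a 2-D matrix")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if obs.sum() <= 0:
        raise ValueError("total count must be positive")

    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    obs = obs[row_ok][:, col_ok]

    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    expected = row @ col / total
    mask = expected > 0
    stat = float((((obs - expected) ** 2)[mask] / expected[mask]).sum())
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0

    col_props = obs / col
    if c == 2:
        use_rate_delta = 100.0 * (col_props[:, 0] - col_props[:, 1])
    else:
        use_rate_delta = 100.0 * (col_props - col_props.mean(axis=1, keepdims=True))

    res = TestResult(statistic=stat, p_value=p,
                     method=f"chi-square-independence/df={df}",
                     n1=int(col.flat[0]) if c >= 1 else 0,
                     n2=int(col.flat[1]) if c >= 2 else 0)
    return ChiSquareResult(result=res, observed=obs, expected=expected,
                           deviations=obs - expected,
                           use_rate_delta=use_rate_delta, df=df)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((a @ b) / denom)


def spearman_rho(x, y) -> CorrelationResult:
    """Midrank-based Spearman correlation (Pearson on ranks).

    p-value by t-approximation for n >= 10 and by exact permutation of the
    rank vector for n < 10 (two-sided in both cases).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = _pearson(rx, ry)

    if n >= 10:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
    else:
        # exact permutation distribution of rho under independence
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            r = _pearson(rx, np.array(perm))
            if abs(r) >= target:
                count += 1
            total += 1
        p = count / total
    return CorrelationResult(rho=rho, p_value=min(1.0, p), n=n)


def normality_check(x) -> list[TestResult]:
    """Anderson-Darling (estimated parameters) and Lilliefors-corrected KS.

    Requires n >= 8. Both are substitutes for the Ryan-Joiner test, which has
    no published open implementation.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("normality checks need n >= 8")
    ad_stat, ad_p = normal_ad(x)
    ks_stat, ks_p = lilliefors(x, dist="norm")
    return [
        TestResult(statistic=float(ad_stat), p_value=float(min(1.0, ad_p)),
                   method="anderson-darling/estimated-params", n1=int(x.size)),
        TestResult(statistic=float(ks_stat), p_value=float(min(1.0, ks_p)),
                   method="kolmogorov-smirnov/lilliefors (ryan-joiner substitute)",
                   n1=int(x.size)),
    ]


def recommend_nonparametric(x, alpha: float = 0.05) -> bool:
    """True when any normality check rejects at ``alpha`` (gates a log hint)."""
    return any(r.p_value < alpha for r in normality_check(x))
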