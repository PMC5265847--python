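"""Statistical kernel for the modality screens.

The rank tests carry their own exact null distributions: the Wilcoxon
signed-rank test enumerates sign assignments (as a subset-sum DP over doubled
midranks) when the number of non-zero differences is small, and the rank-sum
test enumerates group labelings the same way when the combined sample is small
and tie-free.  Larger samples fall back to the classic normal approximations
with tie-corrected variance and a continuity correction.  Fisher's exact test
and the Welch t-test delegate to scipy.

Degenerate inputs (all-zero differences, zero-variance groups, complete ties)
return flagged p-values in {0, 1} rather than raising, so genome-wide screens
never abort on constant features.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_N = 20


@dataclass(frozen=True)
class TestOutcome:
    statistic: float
    p_value: float
    method_note: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) = case event / no-event, (c, d) = comparison group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.a + self.b == 0:
            raise ValueError("case margin a+b must be positive")
        if self.c + self.d == 0:
            raise ValueError("comparison margin c+d must be positive")


def _as_finite_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Midranks scaled by 2 so tied ranks are exact integers."""
    ranks = _sps.rankdata(values)
    doubled = np.rint(ranks * 2).astype(np.int64)
    return doubled


def _signed_rank_exact_p(ranks2: np.ndarray, w2: int) -> float:
    """Two-sided exact p for the signed-rank statistic.

    Enumerates all 2**n sign assignments via a subset-sum DP over the doubled
    ranks; the null distribution of W+ is symmetric about S/2.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in ranks2:
        counts[r:] += counts[: total + 1 - r]
    denom = float(2 ** len(ranks2))
    lo = min(w2, total - w2)
    hi = max(w2, total - w2)
    p = (counts[: lo + 1].sum() + counts[hi:].sum()) / denom
    return min(1.0, float(p))


def wilcoxon_signed_rank(differences, method: str = "auto") -> TestOutcome:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (classic Wilcoxon
    convention); an all-zero input yields a degenerate p of 1.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    d = _as_finite_array(differences, "differences")
    nz = d[d != 0.0]
    if nz.size == 0:
        return TestOutcome(0.0, 1.0, "degenerate: all differences zero", True)
    n = nz.size
    ranks = _sps.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    use_exact = method == "exact" or (method == "auto" and n <= EXACT_SIGNED_RANK_MAX_N)
    if use_exact:
        ranks2 = _doubled_midranks(np.abs(nz))
        p = _signed_rank_exact_p(ranks2, int(round(2 * w_pos)))
        return TestOutcome(w_pos, p, f"exact sign enumeration (n={n})")
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return TestOutcome(w_pos, 1.0, "degenerate: zero variance", True)
    diff = w_pos - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * float(_sps.norm.sf(abs(z))))
    return TestOutcome(w_pos, p, f"normal approximation, continuity corrected (n={n})")


def _rank_sum_exact_p(nx: int, n_total: int, w: float) -> float:
    """Two-sided exact p for the rank-sum W of group x, tie-free ranks 1..N.

    Counts subsets of size nx of {1..N} by rank sum (DP); the null is
    symmetric about nx*(N+1)/2.
    """
    total = n_total * (n_total + 1) // 2
    dp = np.zeros((nx + 1, total + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, n_total + 1):
        for k in range(min(nx, r), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[nx]
    denom = float(math.comb(n_total, nx))
    w = int(round(w))
    mirror = nx * (n_total + 1) - w
    lo, hi = min(w, mirror), max(w, mirror)
    p = (counts[: lo + 1].sum() + counts[hi:].sum()) / denom
    return min(1.0, float(p))


def wilcoxon_rank_sum(x, y, method: str = "auto") -> TestOutcome:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact by enumeration of group labelings when the combined sample is at
    most ``EXACT_RANK_SUM_MAX_N`` and tie-free; otherwise normal approximation
    with tie-corrected variance and continuity correction.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    x = _as_finite_array(x, "x")
    y = _as_finite_array(y, "y")
    nx, ny = x.size, y.size
    n = nx + ny
    combined = np.concatenate([x, y])
    ranks = _sps.rankdata(combined)
    w = float(ranks[:nx].sum())
    uniq, tie_counts = np.unique(combined, return_counts=True)
    has_ties = uniq.size < n
    if method == "exact" and has_ties:
        raise ValueError("exact rank-sum path requires tie-free data")
    use_exact = method == "exact" or (
        method == "auto" and n <= EXACT_RANK_SUM_MAX_N and not has_ties
    )
    if use_exact:
        p = _rank_sum_exact_p(nx, n, w)
        return TestOutcome(w, p, f"exact labeling enumeration (n={nx}+{ny})")
    mu = nx * (n + 1) / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestOutcome(w, 1.0, "degenerate: all values tied", True)
    diff = w - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * float(_sps.norm.sf(abs(z))))
    return TestOutcome(
        w, p, f"normal approximation, tie-corrected, continuity corrected (n={nx}+{ny})"
    )


def two_sample_t(x, y, variant: str = "welch") -> TestOutcome:
    """Two-sided two-sample t-test (Welch by default)."""
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t variant {variant!r}")
    x = _as_finite_array(x, "x")
    y = _as_finite_array(y, "y")
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vx == 0.0 and vy == 0.0:
        if float(np.mean(x)) == float(np.mean(y)):
            return TestOutcome(0.0, 1.0, "degenerate: both groups constant, equal", True)
        sign = math.copysign(1.0, float(np.mean(x)) - float(np.mean(y)))
        return TestOutcome(
            sign * math.inf, 0.0, "degenerate: both groups constant, unequal", True
        )
    res = _sps.ttest_ind(x, y, equal_var=(variant == "student"))
    return TestOutcome(float(res.statistic), float(res.pvalue), f"{variant} t-test")


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, TestOutcome]:
    """Two-sided Fisher exact test with the sample odds ratio.

    Returns ``(odds_ratio, outcome)``; the odds ratio is a*d/(b*c), +inf when
    b*c = 0 with a*d > 0, and NaN when both products vanish.  The p-value sums
    hypergeometric point probabilities no larger than the observed one
    (point-probability rule).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    num, den = a * d, b * c
    if den == 0:
        odds = math.inf if num > 0 else math.nan
    else:
        odds = num / den
    p = float(_sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    p = min(1.0, p)
    return odds, TestOutcome(
        odds if math.isfinite(odds) else math.nan,
        p,
        "exact hypergeometric, point-probability rule",
        degenerate=not math.isfinite(odds),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Input order is preserved; NaN entries propagate as NaN and are excluded
    from the number of tests m.  q_i = min_{j: p_(j) >= p_(i)} p_(j)*m/j,
    capped at 1, so q >= p elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    finite = p[~np.isnan(p)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    m = int(mask.sum())
    if m == 0:
        return q
    idx = np.where(mask)[0]
    order = idx[np.argsort(p[idx], kind="stable")]
    ranked = p[order] * m / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    q[order] = np.minimum(qs, 1.0)
    return q


def hypergeometric_overlap(
    universe_size: int, set_size: int, query_size: int, overlap: int
) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeometric(universe, set, query)."""
    if min(universe_size, set_size, query_size, overlap) < 0:
        raise ValueError("sizes must be non-negative")
    if set_size > universe_size or query_size > universe_size:
        raise ValueError("set and query sizes must not exceed the universe")
    if overlap > min(set_size, query_size):
        raise ValueError("overlap exceeds the smaller of set and query")
    return float(_sps.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))
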