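"""Hypothesis tests used throughout the pipeline.

Self-contained implementations of the four tests the analysis relies on:
paired Wilcoxon signed-rank, Mann–Whitney U, Fisher's exact test on a 2x2
table, and Welch's unequal-variance t test. The rank tests use exact
small-sample null distributions whenever the input permits (tie-free data
below an enumeration cutoff); otherwise a normal approximation with tie and
continuity corrections is applied. Exactness matters here because the
temporal-stability filter retains probes with p > 0.8, a region where the
discreteness of small-n rank tests is pronounced.

scipy is used only for distribution functions (normal/t CDFs, hypergeometric
pmf), never for the test logic itself.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "welch_t",
    "results_table",
]

#: largest n for which the signed-rank null is enumerated exactly
SIGNED_RANK_EXACT_CUTOFF = 20
#: largest combined n_a + n_b for which the rank-sum null is enumerated exactly
RANK_SUM_EXACT_CUTOFF = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test.

    ``statistic`` is W+ for the signed-rank test, U (of the first group) for
    the rank-sum test, the sample odds ratio for Fisher's test, and t for
    Welch's test. ``n_effective`` is the number of pairs after zero removal
    for the signed-rank test, and the per-group sizes otherwise.
    """

    statistic: float
    p_two_sided: float
    n_effective: int | tuple[int, int]
    method: str  # "exact" or "normal_approx"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError(f"p-value {self.p_two_sided} outside [0, 1]")


def _as_finite_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError(f"{name}: empty input")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite values present")
    return arr


def _midranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their average rank."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(x: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(x, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


@lru_cache(maxsize=64)
def _signed_rank_null_counts(n: int) -> tuple[int, ...]:
    """Counts of sign assignments per W+ value for tie-free ranks 1..n.

    Equivalent to full enumeration of the 2^n sign patterns: the count
    polynomial is the product over ranks r of (1 + z^r).
    """
    total = n * (n + 1) // 2
    counts = [0] * (total + 1)
    counts[0] = 1
    for r in range(1, n + 1):
        for w in range(total, r - 1, -1):
            counts[w] += counts[w - r]
    return tuple(counts)


def wilcoxon_signed_rank(paired_differences, *, method: str = "auto") -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped before ranking (the classic convention);
    an all-zero input carries no evidence of a shift and returns p = 1.
    ``method="auto"`` uses the exact null (full enumeration of sign
    assignments) for tie-free |d| with at most 20 pairs, otherwise a normal
    approximation with tie and continuity corrections; ``method="approx"``
    forces the approximation.
    """
    if method not in ("auto", "approx"):
        raise ValueError(f"unknown method {method!r}")
    d = _as_finite_array(paired_differences, "paired_differences")
    d = d[d != 0.0]
    n = int(d.size)
    if n == 0:
        return TestResult(0.0, 1.0, 0, "exact")

    absd = np.abs(d)
    ranks = _midranks(absd)
    w_plus = float(np.sum(ranks[d > 0]))
    has_ties = len(np.unique(absd)) < n

    if method == "auto" and n <= SIGNED_RANK_EXACT_CUTOFF and not has_ties:
        counts = _signed_rank_null_counts(n)
        total = n * (n + 1) // 2
        denom = 2**n
        w = int(round(w_plus))
        p_le = sum(counts[: w + 1]) / denom
        p_ge = sum(counts[w:]) / denom
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(w_plus, p, n, "exact")

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(absd) / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, n, "normal_approx")
    z = max(0.0, abs(w_plus - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(_sps.norm.sf(z)))
    return TestResult(w_plus, p, n, "normal_approx")


def mann_whitney_u(group_a, group_b, *, method: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test (U reported for ``group_a``).

    Exact p by enumeration of all rank labelings when the pooled sample is
    tie-free with at most 12 observations; otherwise normal approximation
    with tie and continuity corrections (``method="approx"`` forces it).
    """
    if method not in ("auto", "approx"):
        raise ValueError(f"unknown method {method!r}")
    a = _as_finite_array(group_a, "group_a")
    b = _as_finite_array(group_b, "group_b")
    na, nb = int(a.size), int(b.size)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r_a = float(np.sum(ranks[:na]))
    u_a = r_a - na * (na + 1) / 2.0

    n = na + nb
    has_ties = len(np.unique(pooled)) < n
    if method == "auto" and n <= RANK_SUM_EXACT_CUTOFF and not has_ties:
        # enumerate all C(n, na) assignments of ranks to group a
        u_obs = int(round(u_a))
        all_ranks = range(1, n + 1)
        offset = na * (na + 1) // 2
        us = [sum(c) - offset for c in itertools.combinations(all_ranks, na)]
        total = len(us)
        p_le = sum(1 for u in us if u <= u_obs) / total
        p_ge = sum(1 for u in us if u >= u_obs) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(u_a, p, (na, nb), "exact")

    mu = na * nb / 2.0
    var = na * nb / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:
        return TestResult(u_a, 1.0, (na, nb), "normal_approx")
    z = max(0.0, abs(u_a - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(_sps.norm.sf(z)))
    return TestResult(u_a, p, (na, nb), "normal_approx")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    The two-sided p-value sums the hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed that
    of the observed table (within relative tolerance 1e-7).
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError(f"counts must be nonnegative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all counts are zero")
    row1, col1 = a + b, a + c
    k_lo = max(0, col1 - (c + d))
    k_hi = min(col1, row1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = _sps.hypergeom.pmf(ks, n, row1, col1)
    p_obs = float(_sps.hypergeom.pmf(a, n, row1, col1))
    p = float(np.sum(pmf[pmf <= p_obs * (1.0 + 1e-7)]))
    p = min(1.0, p)
    odds = math.inf if b * c == 0 and a * d > 0 else (a * d / (b * c) if b * c else math.nan)
    return TestResult(odds, p, (a + b, c + d), "exact")


def welch_t(group_a, group_b) -> TestResult:
    """Welch's two-sample t test with Satterthwaite degrees of freedom."""
    a = _as_finite_array(group_a, "group_a")
    b = _as_finite_array(group_b, "group_b")
    na, nb = int(a.size), int(b.size)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    se2 = va / na + vb / nb
    diff = float(np.mean(a) - np.mean(b))
    if se2 == 0.0:
        # both groups constant: no variability to test against
        p = 1.0 if diff == 0.0 else 0.0
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        return TestResult(t, p, (na, nb), "exact")
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = min(1.0, 2.0 * float(_sps.t.sf(abs(t), df)))
    return TestResult(t, p, (na, nb), "exact")


def results_table(named_results):
    """Render ``[(name, TestResult), ...]`` as a tidy DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for name, r in named_results:
        n = r.n_effective
        rows.append(
            {
                "test": name,
                "statistic": r.statistic,
                "p_two_sided": r.p_two_sided,
                "n_effective": "+".join(map(str, n)) if isinstance(n, tuple) else n,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)
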