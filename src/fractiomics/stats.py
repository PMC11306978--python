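"""Statistical layer: exact tests, gene-set enrichment and multiple-testing control.

Fisher's exact test and the hypergeometric upper tail are delegated to scipy
(two-sided Fisher p-values use the minimum-likelihood convention, i.e. the sum
of probabilities of all tables no more likely than the observed one, which is
scipy's default). Benjamini–Hochberg is implemented directly (it is five lines)
and cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "fisher_exact_2x2",
    "hypergeom_enrichment",
    "rank_test",
    "bh_adjust",
    "bonferroni_adjust",
    "two_proportion_ztest",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]`` with optional row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name!r} must be a nonnegative integer, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero 2x2 table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one annotation set within a region."""

    set_id: str
    k: int  # hits in region
    n: int  # region size
    K: int  # hits in background
    N: int  # background size
    p: float
    q: float = np.nan

    @property
    def gene_ratio(self) -> str:
        return f"{self.k}/{self.n}"


def fisher_exact_2x2(table: ContingencyTable2x2 | np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``. The odds ratio is the sample odds ratio
    a*d / (b*c); a zero denominator with a nonzero numerator is reported as
    ``inf``, and 0/0 as ``nan``.
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=np.int64)
        if arr.shape != (2, 2):
            raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValueError("negative cell count")
        if arr.sum() == 0:
            raise ValueError("all-zero 2x2 table")
    res = sps.fisher_exact(arr, alternative="two-sided")
    a, b, c, d = arr.ravel()
    num, den = a * d, b * c
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = np.inf
    else:
        odds = np.nan
    return float(odds), float(res.pvalue)


def hypergeom_enrichment(
    region: set[str] | list[str],
    annotation_sets: dict[str, set[str] | list[str]],
    background: set[str] | list[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each annotation set in a region.

    For each set, tests P(X >= k) where X ~ Hypergeom(N, K, n) with N the
    background size, K the set size within the background, n the region size
    and k the observed overlap. BH q-values are computed across all tested
    sets; results are returned sorted by q then p.

    The background must be passed explicitly (whole-genome vs. window-restricted
    backgrounds give different answers and the choice is the caller's).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    reg = set(region)
    if not reg <= bg:
        extra = sorted(reg - bg)[:5]
        raise ValueError(f"region contains genes outside the background, e.g. {extra}")
    N, n = len(bg), len(reg)
    results: list[EnrichmentResult] = []
    for set_id, members in annotation_sets.items():
        mem = set(members) & bg
        K = len(mem)
        k = len(mem & reg)
        # survival function at k-1 gives P(X >= k), upper tail inclusive
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(set_id=set_id, k=k, n=n, K=K, N=N, p=min(p, 1.0)))
    qs = bh_adjust(np.array([r.p for r in results])) if results else np.array([])
    for r, q in zip(results, qs):
        r.q = float(q)
    results.sort(key=lambda r: (r.q, r.p, r.set_id))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (k, n, K, N, gene_ratio, p, q)."""
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "gene_ratio": [r.gene_ratio for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )


def rank_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney/Wilcoxon rank-sum test.

    Uses exact enumeration when both samples have <= 10 observations and no
    ties, and the tie-corrected normal approximation otherwise. Completely
    tied data (every value identical in both samples) returns p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    method = "exact" if (a.size <= 10 and b.size <= 10) else "asymptotic"
    try:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties; fall back to tie-corrected normal approx
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-proportion z-test with pooled variance.

    Returns ``(z, p)``. Used for comparisons of expressed-gene counts between
    subgenomes.
    """
    if min(n1, n2) <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * sps.norm.sf(abs(z)))
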