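"""Nonparametric tests used throughout the pipeline.

Thin, consistently-typed wrappers over scipy.stats / statsmodels: Shapiro–
Wilk normality, Mann–Whitney U (a.k.a. Wilcoxon rank-sum), Kruskal–Wallis,
Spearman correlation with strength labels, and Benjamini–Hochberg adjustment.

Small samples take the exact path where feasible (Mann–Whitney exact for
min(n, m) <= 8 with no ties) so p-values are reproducible bit-for-bit;
asymptotic paths use tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: |rho| bins for correlation strength labels (lower bound inclusive)
DEFAULT_STRENGTH_BINS = {"strong": 0.6, "moderate": 0.3, "weak": 0.0}


class StatTestError(ValueError):
    """Invalid input to a statistical test."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n: tuple[int, ...]
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise StatTestError(f"p out of [0,1]: {self.p}")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    strength: str
    method: str = "spearman"

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise StatTestError(f"|rho| > 1: {self.rho}")


def _asarray(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise StatTestError(f"{name}: empty group")
    return arr


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U / Wilcoxon rank-sum test.

    Exact p for min(n, m) <= 8 without ties; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    xa, ya = _asarray(x, "x"), _asarray(y, "y")
    pooled = np.concatenate([xa, ya])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = ("exact" if min(xa.size, ya.size) <= 8 and not has_ties
              else "asymptotic")
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      n=(xa.size, ya.size),
                      method=f"mann-whitney-{method}")


#: §2.3 names both Wilcoxon rank-sum and Mann–Whitney U; they are one test.
wilcoxon_rank_sum = mann_whitney


def kruskal_wallis(*groups: Sequence[float]) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected, chi-square p, df = k-1)."""
    if len(groups) < 2:
        raise StatTestError("kruskal_wallis needs >= 2 groups")
    arrays = [_asarray(g, f"group {i}") for i, g in enumerate(groups)]
    if sum(a.size for a in arrays) < 3:
        raise StatTestError("kruskal_wallis needs total n >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence of any difference
        return TestResult(statistic=0.0, p=1.0,
                          n=tuple(a.size for a in arrays),
                          method="kruskal-wallis")
    res = stats.kruskal(*arrays)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      n=tuple(a.size for a in arrays),
                      method="kruskal-wallis")


def spearman(
    x: Sequence[float], y: Sequence[float],
    strength_bins: Optional[dict[str, float]] = None,
) -> CorrelationResult:
    """Spearman rank correlation with a categorical strength label.

    rho is the Pearson correlation of mid-ranks (ties handled); p uses the
    t approximation. Zero rank variance yields rho = nan flagged as
    ``undefined``.
    """
    xa, ya = _asarray(x, "x"), _asarray(y, "y")
    if xa.size != ya.size:
        raise StatTestError("x and y must have equal length")
    if xa.size < 3:
        raise StatTestError("spearman needs n >= 3")
    bins = strength_bins or DEFAULT_STRENGTH_BINS
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return CorrelationResult(rho=float("nan"), p=float("nan"),
                                 n=xa.size, strength="undefined")
    res = stats.spearmanr(xa, ya)
    rho = float(res.statistic)
    label = next(name for name, lo in
                 sorted(bins.items(), key=lambda kv: -kv[1])
                 if abs(rho) >= lo)
    return CorrelationResult(rho=rho, p=float(res.pvalue), n=xa.size,
                             strength=label)


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro–Wilk normality test (3 <= n <= 5000)."""
    xa = _asarray(x, "x")
    if not 3 <= xa.size <= 5000:
        raise StatTestError("shapiro_wilk requires 3 <= n <= 5000")
    res = stats.shapiro(xa)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      n=(xa.size,), method="shapiro-wilk")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise StatTestError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
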