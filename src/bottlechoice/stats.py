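"""Two-sided nonparametric tests and multiplicity corrections.

The procedures are implemented explicitly so that every p-value path is
inspectable and testable against enumeration oracles:

* :func:`mann_whitney` — two-sided rank-sum test; exact U distribution (via
  the standard count recursion) for small tie-free samples (n₁·n₂ ≤ 400),
  normal approximation with tie and continuity corrections otherwise. The
  ``paired=True`` variant is the Wilcoxon signed-rank test (the standard
  reading of a "paired Mann-Whitney"), exact for n ≤ 25 without ties among
  the nonzero |differences|, zero differences dropped.
* :func:`friedman` — chi-squared-approximated Friedman statistic with tie
  correction, df = k − 1.
* :func:`holm_bonferroni` — sequentially rejective step-down adjustment
  with monotonicity enforcement, order-preserving.
* :func:`chi_squared_yates` — Pearson chi-squared on a 2×2 table with the
  continuity correction floored at zero, df = 1.

Only distribution tail functions (normal, chi-squared) come from scipy;
statistics and exact distributions are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "friedman",
    "holm_bonferroni",
    "chi_squared_yates",
    "family_report",
]

EXACT_U_LIMIT = 400  # exact unpaired distribution for n1*n2 up to this, no ties
EXACT_W_LIMIT = 25  # exact signed-rank distribution for n up to this, no ties


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    n: tuple | int | None = None
    df: int | None = None
    method: str = ""
    p_adjusted: float | None = None
    family: str | None = None
    note: str = ""


def _rankdata(a: np.ndarray) -> np.ndarray:
    """Average ranks (midranks for ties)."""
    return sps.rankdata(a, method="average")


def _tie_term(values: np.ndarray) -> float:
    """Σ (t³ − t) over tied groups."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements giving each U value, for tie-free samples.

    Uses the recursion c(u; m, n) = c(u−n; m−1, n) + c(u; m, n−1) with
    c(u; 0, n) = c(u; m, 0) = [u = 0]; the result sums to C(n1+n2, n1).
    """
    umax = n1 * n2
    cur = np.zeros((n1 + 1, umax + 1), dtype=float)
    cur[:, 0] = 1.0  # n = 0
    for n in range(1, n2 + 1):
        nxt = np.zeros_like(cur)
        nxt[0, 0] = 1.0
        for m in range(1, n1 + 1):
            nxt[m] = cur[m]
            nxt[m, n:] = nxt[m, n:] + nxt[m - 1, : umax + 1 - n]
        cur = nxt
    return cur[n1]


def mann_whitney(x, y, *, paired: bool = False) -> TestResult:
    """Two-sided Mann-Whitney U test (or Wilcoxon signed-rank when paired)."""
    if paired:
        return wilcoxon_signed_rank(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("each sample needs at least one observation")
    combined = np.concatenate([x, y])
    ranks = _rankdata(combined)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(combined)) < n1 + n2

    if not has_ties and n1 * n2 <= EXACT_U_LIMIT:
        counts = _u_counts(n1, n2)
        total = comb(n1 + n2, n1)
        u_lo = min(u1, n1 * n2 - u1)
        p = min(1.0, 2.0 * float(counts[: int(u_lo) + 1].sum()) / total)
        method = "exact"
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie = _tie_term(combined)
        var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if var <= 0:
            p, method = 1.0, "normal approximation (degenerate)"
        else:
            z = u1 - mu
            z = (z - 0.5 * np.sign(z)) / np.sqrt(var) if z != 0 else 0.0
            p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
            method = "normal approximation, tie-corrected"
    return TestResult("mann_whitney", float(u1), p, n=(n1, n2), method=method)


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on pairs (or on one difference sample).

    Zero differences are dropped; exact null distribution (subset-sum
    convolution over ranks) when n ≤ 25 with untied |differences|, else
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("paired samples must have equal lengths")
        d = x - y
    else:
        d = x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, n=0,
                          method="all differences zero")
    absd = np.abs(d)
    ranks = _rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    w_minus = n * (n + 1) / 2.0 - w_plus
    has_ties = len(np.unique(absd)) < n

    if not has_ties and n <= EXACT_W_LIMIT:
        # counts of achievable signed-rank sums: conv of (1 + q^r), r = 1..n
        counts = np.zeros(int(n * (n + 1) / 2) + 1)
        counts[0] = 1.0
        for r in range(1, n + 1):
            counts[r:] = counts[r:] + counts[:-r]
        total = 2.0**n
        w_lo = min(w_plus, w_minus)
        p = min(1.0, 2.0 * float(counts[: int(w_lo) + 1].sum()) / total)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(absd) / 48.0
        if var <= 0:
            p, method = 1.0, "normal approximation (degenerate)"
        else:
            z = w_plus - mu
            z = (z - 0.5 * np.sign(z)) / np.sqrt(var) if z != 0 else 0.0
            p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
            method = "normal approximation, tie-corrected"
    return TestResult("wilcoxon_signed_rank", w_plus, p, n=n, method=method)


def friedman(matrix) -> TestResult:
    """Friedman test on a subjects × conditions matrix (no missing cells).

    Chi-squared approximation with tie correction; df = k − 1. A fully tied
    matrix (every subject constant) gives statistic 0, p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 conditions")
    if not np.isfinite(m).all():
        raise ValueError("missing cells are not allowed (no imputation)")
    n, k = m.shape
    ranks = np.apply_along_axis(_rankdata, 1, m)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(rj**2)) - 3.0 * n * (k + 1)
    correction = 1.0 - sum(_tie_term(row) for row in m) / (n * k * (k**2 - 1))
    if correction <= 0:
        return TestResult("friedman", 0.0, 1.0, n=n, df=k - 1,
                          method="degenerate (all tied)")
    stat /= correction
    p = float(sps.chi2.sf(stat, k - 1))
    return TestResult("friedman", float(stat), p, n=n, df=k - 1,
                      method="chi-squared approximation, tie-corrected")


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    Sorted ascending, each p is multiplied by its step factor (m, m−1, …, 1),
    a running maximum enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def chi_squared_yates(table) -> TestResult:
    """Pearson chi-squared with Yates continuity correction on a 2×2 table.

    χ² = Σ (max(|O−E| − 0.5, 0))² / E with df = 1; the correction is floored
    so near-balanced tables cannot be over-corrected past zero. Symmetric
    under transposition and row/column swaps. Zero margins raise.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin in contingency table")
    expected = np.outer(rows, cols) / t.sum()
    diff = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    p = float(sps.chi2.sf(stat, 1))
    return TestResult("chi_squared_yates", stat, p, n=int(t.sum()), df=1,
                      method="Yates continuity correction, floored")


def family_report(tests: pd.DataFrame, *, p_col: str = "p",
                  family_col: str = "family") -> pd.DataFrame:
    """Holm-Bonferroni adjustment applied within each declared test family.

    Input: a tidy table with one row per test and a family label mirroring
    the per-panel correction families; output adds ``p_adjusted``.
    """
    out = tests.copy()
    if len(out) == 0:
        out["p_adjusted"] = pd.Series(dtype=float)
        return out
    out["p_adjusted"] = np.nan
    for _, idx in out.groupby(family_col, sort=False).groups.items():
        out.loc[idx, "p_adjusted"] = holm_bonferroni(out.loc[idx, p_col].to_numpy())
    return out
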