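"""Inferential statistics: t-tests, Pearson correlation tests, and the
Bonferroni-Holm step-down correction for families of comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p: float
    label: str = ""
    p_adjusted: float | None = None
    reject: bool | None = None
    note: str = ""


def one_sample_t(values: np.ndarray, mu0: float = 0.0, label: str = "") -> TestResult:
    """Two-sided one-sample t-test of ``mean(values) == mu0``."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.std(v, ddof=1) == 0:
        return TestResult("one_sample_t", np.nan, v.size - 1, np.nan, label, note="zero variance")
    t, p = sps.ttest_1samp(v, mu0)
    return TestResult("one_sample_t", float(t), v.size - 1, float(p), label)


def paired_t(a: np.ndarray, b: np.ndarray, label: str = "") -> TestResult:
    """Two-sided paired t-test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        stat = np.nan if d[0] != 0 else 0.0
        p = np.nan if d[0] != 0 else 1.0
        return TestResult("paired_t", stat, a.size - 1, p, label, note="zero variance")
    t, p = sps.ttest_rel(a, b)
    return TestResult("paired_t", float(t), a.size - 1, float(p), label)


def pearson_test(x: np.ndarray, y: np.ndarray, label: str = "") -> TestResult:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        return TestResult("pearson", np.nan, x.size - 2, np.nan, label, note="zero variance")
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson", float(r), x.size - 2, float(p), label)


def holm_correction(pvals, alpha: float = 0.05):
    """Bonferroni-Holm step-down correction.

    Sorted ascending, ``p_(i)`` is compared with ``alpha / (m - i + 1)``;
    testing stops at the first failure.  Adjusted p-values are
    ``p_adj_(i) = min(1, max_{j<=i} (m - j + 1) * p_(j))``, which makes them
    non-decreasing in sorted order.  Returns ``(p_adjusted, reject)`` in the
    input order.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.empty(0), np.empty(0, bool)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate((m - np.arange(m)) * p[order])
    adj_sorted = np.minimum(adj_sorted, 1.0)
    reject_sorted = np.zeros(m, bool)
    for i in range(m):
        if p[order][i] <= alpha / (m - i):
            reject_sorted[i] = True
        else:
            break
    p_adj = np.empty(m)
    reject = np.empty(m, bool)
    p_adj[order] = adj_sorted
    reject[order] = reject_sorted
    return p_adj, reject


def apply_holm(results: list, alpha: float = 0.05) -> list:
    """Correct a family of TestResults in place; NaN p-values pass through."""
    ps = np.array([r.p for r in results], float)
    ok = np.isfinite(ps)
    if ok.any():
        adj, rej = holm_correction(ps[ok], alpha)
        j = 0
        for i, r in enumerate(results):
            if ok[i]:
                r.p_adjusted = float(adj[j])
                r.reject = bool(rej[j])
                j += 1
    return results
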