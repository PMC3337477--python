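"""Statistical primitives: pooled t-test, Kruskal-Wallis, Fisher's method, BH.

Thin, total wrappers around scipy/statsmodels: every degenerate input
(zero variance, identical samples, single p-value) maps to a defined
result instead of NaN so the calling pipelines never branch on missing
statistics.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    degenerate: bool = False


def student_t(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided two-sample Student t-test with pooled (equal) variance.

    Degenerate cases are total: if either group has <2 values, or both
    groups are constant, the result is flagged degenerate with p=1 (p=0
    when both are constant at different values).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    df = a.size + b.size - 2
    if a.size < 2 or b.size < 2:
        return TestResult(0.0, max(df, 0), 1.0, degenerate=True)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return TestResult(0.0, df, 1.0, degenerate=True)
        return TestResult(math.inf if a[0] > b[0] else -math.inf, df, 0.0, degenerate=True)
    with warnings.catch_warnings():
        # scipy warns about precision loss on near-identical groups; the
        # pooled-t result is still well defined there
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(t), float(df), float(p))


def _kw_statistic(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with midrank tie correction (explicit formula)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    offsets = np.cumsum([0] + [g.size for g in groups])
    h = 12.0 / (n * (n + 1)) * sum(
        g.size * (ranks[offsets[i]:offsets[i + 1]].mean() - (n + 1) / 2.0) ** 2
        for i, g in enumerate(groups)
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(groups: Sequence[Sequence[float]], exact: bool = False) -> TestResult:
    """Kruskal-Wallis rank test across >=2 groups.

    p comes from the chi-square survival function with df = k-1; with
    ``exact=True`` (tiny samples only) the p-value is instead the full
    permutation tail probability of H.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    n = sum(a.size for a in arrs)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    dof = len(arrs) - 1
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, dof, 1.0, degenerate=True)
    h = _kw_statistic(arrs)
    if exact:
        if n > 10:
            raise ValueError("exact permutation mode is for tiny samples (N <= 10)")
        sizes = [a.size for a in arrs]
        count = total = 0
        for perm in itertools.permutations(range(n)):
            shuffled = pooled[list(perm)]
            parts, off = [], 0
            for s in sizes:
                parts.append(shuffled[off:off + s])
                off += s
            total += 1
            if _kw_statistic(parts) >= h - 1e-12:
                count += 1
        return TestResult(float(h), dof, count / total)
    return TestResult(float(h), dof, float(sps.chi2.sf(h, dof)))


def fisher_combine(pvals: Sequence[float]) -> TestResult:
    """Fisher's method: X^2 = -2 sum(ln p) ~ chi-square with 2k df."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("clamping %d zero p-value(s) for Fisher combination", int((p == 0).sum()))
        p = np.maximum(p, np.finfo(float).tiny)
    x2 = -2.0 * np.log(p).sum()
    dof = 2 * p.size
    return TestResult(float(x2), dof, float(sps.chi2.sf(x2, dof)))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
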