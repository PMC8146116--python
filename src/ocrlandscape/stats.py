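"""Shared statistical primitives.

Thin, explicitly-contracted wrappers around scipy/statsmodels for the tests
used throughout the pipeline: Wilcoxon rank-sum (exact when feasible),
Fisher's exact test, Spearman correlation and Benjamini–Hochberg FDR.

The exact/approximate switch for the rank-sum test is made explicit here
(exact enumeration when the pooled sample is small and tie-free, otherwise
a tie- and continuity-corrected normal approximation) so that downstream
summaries can report which method produced each p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _ss
from statsmodels.stats.multitest import multipletests

Side = Literal["two", "greater", "less"]

_SCIPY_SIDE = {"two": "two-sided", "greater": "greater", "less": "less"}

#: pooled-sample-size ceiling for exact rank-sum enumeration
EXACT_N_MAX = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample (or 2x2) hypothesis test."""

    statistic: float
    p: float
    method: Literal["exact", "normal_approx"]
    side: Side
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside (0, 1]")


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float], side: Side = "two") -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test of two independent samples.

    Uses the exact null distribution when ``len(x) + len(y) <= 25`` and the
    pooled data contain no ties; otherwise the normal approximation with
    midranks, tie correction and continuity correction.

    The reported statistic is the rank sum of ``x`` (midranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (pooled.size <= EXACT_N_MAX) and not has_ties
    res = _ss.mannwhitneyu(
        x, y, alternative=_SCIPY_SIDE[side], method="exact" if exact else "asymptotic"
    )
    # rank sum of x = U statistic of x + n1(n1+1)/2
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    p = min(float(res.pvalue), 1.0)
    p = max(p, np.nextafter(0.0, 1.0))
    return TestResult(w, p, "exact" if exact else "normal_approx", side, x.size, y.size)


def fisher_exact(table: Sequence[Sequence[int]], side: Side = "two") -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    Two-sided p is the sum of hypergeometric probabilities no larger than
    that of the observed table at fixed margins. Any zero margin gives p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    odds, p = _ss.fisher_exact(t, alternative=_SCIPY_SIDE[side])
    p = max(min(float(p), 1.0), np.nextafter(0.0, 1.0))
    return TestResult(float(odds), p, "exact", side, int(t[0].sum()), int(t[1].sum()))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of midranks).

    Raises ``ValueError`` for constant input, where rho is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation undefined for constant input")
    rho = _ss.spearmanr(x, y).statistic
    return float(rho)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_i >= p_i elementwise and the adjusted values are monotone in the
    order of the raw p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
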