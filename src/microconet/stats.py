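"""Nonparametric tests and multiple-testing correction.

Thin, contract-pinned wrappers around scipy/statsmodels: two-sided p-values,
exact enumeration for small tie-free samples and the tie-corrected normal
approximation otherwise, average ranks for ties throughout, and
Benjamini-Hochberg FDR q-values.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["mann_whitney_u", "wilcoxon_signed_rank", "bh_fdr", "spearman"]

#: largest combined sample size at which the exact null distribution is used
EXACT_N_MAX = 12


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for two independent samples.

    Uses the exact permutation distribution when the combined sample size is
    at most 12 and there are no ties, and the tie-corrected normal
    approximation (with continuity correction) otherwise.

    Returns
    -------
    (U, p) : float, float
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    exact = (x.size + y.size) <= EXACT_N_MAX and not _has_ties(x, y)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_signed_rank(diffs) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (and reported via a warning). Exact null
    distribution for at most 12 nonzero tie-free differences, tie-corrected
    normal approximation otherwise.

    Returns
    -------
    (W, p) : float, float
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one paired difference")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise ValueError("no nonzero pairs: all paired differences are zero")
    n_dropped = d.size - nonzero.size
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero difference(s)", stacklevel=2)
    exact = nonzero.size <= EXACT_N_MAX and not _has_ties(np.abs(nonzero))
    res = sps.wilcoxon(
        nonzero,
        alternative="two-sided",
        zero_method="wilcox",
        correction=False,
        method="exact" if exact else "approx",
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average-ranked data.

    Returns NaN (with a warning) when either input has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero rank variance: Spearman correlation undefined", stacklevel=2)
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
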