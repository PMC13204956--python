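"""Statistical tests used in the evaluation protocol.

Thin, explicitly specified wrappers: exact McNemar for paired classifier
comparison, the Friedman rank test for band comparisons (midranks, no
tie-correction denominator — flagged when ties occur), Benjamini–Hochberg
FDR for the pairwise follow-ups, and the Mann–Whitney U test for
attention-allocation group differences (exact for small tie-free samples,
normal approximation with tie correction otherwise).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["mcnemar_exact", "chi2_sf", "friedman_test", "bh_fdr", "mann_whitney_u"]


def mcnemar_exact(b: int, c: int) -> float:
    """Two-sided exact McNemar p-value from the discordant-pair counts.

    ``b`` and ``c`` count the subjects the two classifiers disagree on in
    the two directions.  Under the null the smaller count is
    Binomial(b + c, 1/2): p = min(1, 2·P(X ≤ min(b, c))); p = 1 when
    there are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n, 0.5)))


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("x must be >= 0")
    return float(sps.chi2.sf(x, df))


def friedman_test(blocks: np.ndarray) -> tuple[float, float]:
    """Friedman rank test on a (subjects × conditions) block matrix.

    Within-block midranks; χ² = 12n/(k(k+1)) Σ_j (R̄_j − (k+1)/2)² with
    df = k − 1.  Ties are midranked without the tie-correction
    denominator (a warning is emitted when ties occur, making the test
    slightly conservative).  A constant matrix yields (0, 1).
    """
    x = np.asarray(blocks, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 blocks and 2 conditions")
    n, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    if np.any([len(np.unique(row)) < k for row in x]):
        warnings.warn("ties present; statistic computed without tie correction", stacklevel=2)
    rbar = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * float(np.sum((rbar - (k + 1) / 2.0) ** 2))
    return chi2, chi2_sf(chi2, k - 1)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_u(
    x, y, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test (U statistic of the first sample).

    Exact null distribution when both samples have at most
    ``exact_max_n`` observations and the pooled data is tie-free;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= exact_max_n and y.size <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
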