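"""Statistical primitives for marker detection.

The two-sample Wilcoxon rank-sum test is implemented here natively because
it is the marker statistic of the pipeline: exact by enumeration of group
assignments for small samples, tie-corrected normal approximation with
continuity correction otherwise.  Multiple-testing adjustment and rank
correlation delegate to statsmodels and scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_sum_test",
    "benjamini_hochberg",
    "spearman",
    "SpearmanResult",
]

#: combined sample size at or below which the exact null is enumerated
EXACT_MAX_N = 20


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(x, y, exact_max_n: int = EXACT_MAX_N) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    Returns ``(W, p)`` where W is the sum of the (mid)ranks of ``x`` in the
    pooled sample.  For combined n <= ``exact_max_n`` the p-value is exact:
    all C(n, n_x) assignments of the pooled ranks to the first group are
    enumerated and ``p = P(|W - E[W]| >= |w_obs - E[W]|)`` with
    ``E[W] = n_x (n+1) / 2`` (the deviation form handles tied midranks,
    whose null is not symmetric).  Otherwise the tie-corrected normal
    approximation with a 0.5 continuity correction is used.

    Degenerate groups (either empty) raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires two non-empty groups")
    n = n1 + n2
    ranks = _midranks(np.concatenate([x, y]))
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0

    if n <= exact_max_n:
        idx = np.array(list(combinations(range(n), n1)))
        w_all = ranks[idx].sum(axis=1)
        dev = abs(w_obs - mu)
        # small slack absorbs float noise in midrank sums
        p = float(np.mean(np.abs(w_all - mu) >= dev - 1e-9))
        return w_obs, p

    # tie-corrected variance of W
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all observations tied
        return w_obs, 1.0
    dev = abs(w_obs - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return w_obs, p


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    defined: bool


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties, two-sided p.

    A zero-variance input leaves rho undefined; the result is flagged
    rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("spearman requires equal-length vectors")
    if x.size < 3:
        raise ValueError("spearman requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), defined=False)
    res = sps.spearmanr(x, y)
    return SpearmanResult(float(res.statistic), float(res.pvalue), defined=True)
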