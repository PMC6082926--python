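"""Behavioral contrasts: response-time cleaning and Mann-Whitney tests.

Response times are cleaned with two rules applied in a single pass over
the raw values: anything at or beyond 3 standard deviations from the
mean goes (mean and SD computed once, on the full input — the rule is
deliberately not iterated, since iterating changes the sample the
cutoffs were computed on), and anything under 200 ms goes as a likely
anticipation.  Group contrasts (like ratings of shared vs not-shared
videos, decision times) use the two-tailed Mann-Whitney U test with the
midrank tie convention and the rank-biserial-style effect size
r = Z / sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata

__all__ = ["BehaviorTestResult", "exclude_rt_outliers", "mann_whitney"]

#: Largest n1*n2 for which the exact permutation distribution of U is
#: enumerated instead of the normal approximation.
EXACT_LIMIT = 400


@dataclass
class BehaviorTestResult:
    """Mann-Whitney U with two-tailed p and signed effect size."""

    U: float
    p: float
    r: float       # Z / sqrt(n1 + n2); negative when x ranks above y
    n1: int
    n2: int
    method: str    # "exact" or "normal"


def exclude_rt_outliers(rts: np.ndarray
                        ) -> tuple[np.ndarray, list[dict]]:
    """Single-pass response-time exclusion: |x - mean| >= 3 SD, or x < 0.2 s.

    Mean and SD (ddof=1) are computed once on the full input.  When the
    SD is zero (all values identical) only the 200 ms rule can fire.
    Returns the kept values and a log of ``{"index", "value", "reason"}``
    entries for each exclusion.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        raise ValueError("need at least 2 response times")
    mean = rts.mean()
    sd = rts.std(ddof=1)
    log = []
    keep = np.ones(rts.size, dtype=bool)
    for i, v in enumerate(rts):
        if sd > 0 and abs(v - mean) >= 3 * sd:
            keep[i] = False
            log.append({"index": i, "value": float(v), "reason": "3sd"})
        elif v < 0.2:
            keep[i] = False
            log.append({"index": i, "value": float(v), "reason": "min_rt"})
    return rts[keep], log


def _u_from_ranksum(rank_sum_x: float, n1: int, n2: int) -> float:
    # rank sum of x -> U counting pairs where x > y (midranks halve ties)
    return rank_sum_x - n1 * (n1 + 1) / 2.0


def mann_whitney(x: np.ndarray, y: np.ndarray) -> BehaviorTestResult:
    """Two-tailed Mann-Whitney U test with midrank ties.

    U counts pairs with x_i > y_j plus half the tied pairs, so U = 0
    means every x value sits below every y value.  The p-value comes
    from exact enumeration of the rank-sum distribution when
    n1*n2 <= 400 and from the tie-corrected normal approximation
    otherwise.  The effect size is r = Z / sqrt(N), positive when x
    ranks above y and negative when below.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = _u_from_ranksum(ranks[:n1].sum(), n1, n2)
    mu = n1 * n2 / 2.0

    # tie-corrected normal approximation (always computed: it supplies Z for r)
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1.0)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    z = (u - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0

    if n1 * n2 <= EXACT_LIMIT:
        # exhaustive: every choice of which pooled ranks belong to group x
        obs_dev = abs(u - mu)
        hits = 0
        total = comb(n, n1)
        for idx in combinations(range(n), n1):
            u_perm = _u_from_ranksum(ranks[list(idx)].sum(), n1, n2)
            if abs(u_perm - mu) >= obs_dev - 1e-9:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        from scipy.stats import norm
        p = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "normal"

    # x above y -> U large -> positive Z and r
    r = float(z / np.sqrt(n))
    return BehaviorTestResult(U=float(u), p=float(p), r=r,
                              n1=n1, n2=n2, method=method)
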