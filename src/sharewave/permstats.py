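"""Cluster-based permutation statistics over channel-frequency grids.

The test follows the standard nonparametric recipe for controlling the
family-wise error of mass-univariate sensor statistics: compute a pooled
two-sample t per grid point, keep points beyond the Student-t critical
value (two-tailed at the cluster-forming alpha by default), group the
surviving points into sign-homogeneous connected components — where
(channel, freq) touches (channel, freq +/- 1) and (neighbor-channel,
freq) under the montage adjacency — and score each cluster by its summed
t ("cluster mass").  Significance comes from a Monte-Carlo null of the
maximum absolute cluster mass under random condition relabelings that
preserve the group sizes; the reported p uses the +1/+1 correction so it
is always in (0, 1].  Small designs can be enumerated exhaustively
instead of sampled.

A scalar variant of the same permutation logic serves the frontal alpha
asymmetry contrast and per-electrode post-hoc tests; the post-hoc family
correction is max-|t| across the tested electrode set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .montage import Montage

__all__ = [
    "TMap",
    "Cluster",
    "ClusterTestResult",
    "indep_tmap",
    "threshold_mask",
    "form_clusters",
    "permutation_null",
    "scalar_permutation_test",
    "posthoc_electrode_tests",
]


@dataclass
class TMap:
    """Pooled-variance two-sample t statistic per grid point."""

    t: np.ndarray
    n1: int
    n2: int

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2


@dataclass
class Cluster:
    """One sign-homogeneous connected component of suprathreshold points."""

    members: tuple[tuple[int, int], ...]   # (channel index, freq index)
    mass: float                            # summed t over members
    p: float | None = None                 # Monte-Carlo probability


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    null_max: np.ndarray         # max |cluster mass| per permutation
    n_perm: int
    threshold: float             # t cutoff used for cluster forming
    tail: str
    tmap: TMap | None = None
    seed: int | None = None
    exact: bool = False

    @property
    def p_values(self) -> list[float]:
        return [c.p for c in self.clusters]

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p is not None and c.p < alpha]


# ---------------------------------------------------------------------------
# pointwise statistics
# ---------------------------------------------------------------------------

def _pooled_t(sum1, sumsq1, n1, sum2, sumsq2, n2):
    """Pooled t from per-group sums and sums of squares (vectorized)."""
    m1, m2 = sum1 / n1, sum2 / n2
    ss1 = sumsq1 - n1 * m1 ** 2
    ss2 = sumsq2 - n2 * m2 ** 2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom == 0, 0.0, t)   # both groups constant -> t = 0


def indep_tmap(group1: np.ndarray, group2: np.ndarray) -> TMap:
    """Independent-samples pooled-variance t at every grid point.

    ``group1``/``group2`` are (n_trials, *grid) arrays.  Points where
    both groups are constant and equal get t = 0 by convention.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 trials")
    t = _pooled_t(g1.sum(0), (g1 ** 2).sum(0), n1,
                  g2.sum(0), (g2 ** 2).sum(0), n2)
    return TMap(t=t, n1=n1, n2=n2)


def t_critical(df: int, alpha: float, tail: str = "two") -> float:
    """Student-t critical value for the cluster-forming threshold."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = 1 - alpha / 2 if tail == "two" else 1 - alpha
    return float(stats.t.ppf(q, df))


def threshold_mask(tmap: TMap, alpha: float = 0.05, tail: str = "two"
                   ) -> np.ndarray:
    """Boolean grid of points beyond the Student-t critical value.

    Two-tailed: |t| > t_crit(alpha/2).  One-tailed "pos"/"neg": signed
    comparison against t_crit(alpha).
    """
    crit = t_critical(tmap.df, alpha, "two" if tail == "two" else "one")
    if tail == "two":
        return np.abs(tmap.t) > crit
    if tail == "pos":
        return tmap.t > crit
    if tail == "neg":
        return tmap.t < -crit
    raise ValueError("tail must be 'two', 'pos' or 'neg'")


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

def _point_graph(mask: np.ndarray, adj: np.ndarray,
                 sign: np.ndarray | None) -> tuple[np.ndarray, sparse.coo_matrix]:
    """Sparse graph over the masked (channel, freq) points."""
    n_ch, n_f = mask.shape
    idx = -np.ones((n_ch, n_f), dtype=int)
    pts = np.argwhere(mask)
    idx[pts[:, 0], pts[:, 1]] = np.arange(len(pts))
    rows, cols = [], []
    for k, (c, f) in enumerate(pts):
        if f + 1 < n_f and mask[c, f + 1] and \
                (sign is None or sign[c, f + 1] == sign[c, f]):
            rows.append(k)
            cols.append(idx[c, f + 1])
        for c2 in np.flatnonzero(adj[c]):
            if mask[c2, f] and (sign is None or sign[c2, f] == sign[c, f]):
                j = idx[c2, f]
                if j > k:
                    rows.append(k)
                    cols.append(j)
    graph = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)),
                              shape=(len(pts), len(pts)))
    return pts, graph


def form_clusters(mask: np.ndarray, montage: Montage,
                  t: np.ndarray | None = None) -> list[Cluster]:
    """Sign-homogeneous connected components of a suprathreshold mask.

    ``mask`` is (n_analysis_channels, n_freqs) in the montage's analysis
    channel order.  Point (c, f) neighbors (c, f±1) and (c', f) for
    spatially adjacent channels c'.  When ``t`` is given, positive and
    negative points never merge and each cluster's mass is its summed t;
    otherwise mass is the member count.
    """
    adj = montage.adjacency_matrix()
    if mask.shape[0] != adj.shape[0]:
        raise ValueError(
            f"mask has {mask.shape[0]} channels but montage has "
            f"{adj.shape[0]} analysis channels")
    if not mask.any():
        return []
    sign = np.sign(t) if t is not None else None
    pts, graph = _point_graph(mask, adj, sign)
    n_comp, labels = connected_components(graph, directed=False)
    clusters = []
    for comp in range(n_comp):
        members = tuple(map(tuple, pts[labels == comp]))
        if t is not None:
            mass = float(sum(t[c, f] for c, f in members))
        else:
            mass = float(len(members))
        clusters.append(Cluster(members=members, mass=mass))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _max_cluster_mass(t: np.ndarray, crit: float, tail: str,
                      montage: Montage) -> float:
    if tail == "two":
        mask = np.abs(t) > crit
    elif tail == "pos":
        mask = t > crit
    else:
        mask = t < -crit
    if not mask.any():
        return 0.0
    clusters = form_clusters(mask, montage, t=t)
    return max(abs(c.mass) for c in clusters)


def _group_splits(n: int, n1: int, n_perm: int, seed, exact: bool):
    """Yield boolean group-1 membership vectors for each relabeling."""
    if exact:
        for combo in combinations(range(n), n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            yield sel
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            sel = np.zeros(n, dtype=bool)
            sel[rng.permutation(n)[:n1]] = True
            yield sel


def permutation_null(data: np.ndarray, labels: np.ndarray, montage: Montage,
                     n_perm: int = 2000, alpha: float = 0.05,
                     tail: str = "two", seed: int | None = 0,
                     exact: bool = False) -> ClusterTestResult:
    """Cluster-based permutation test of a two-condition difference.

    ``data`` is (n_trials, n_channels, n_freqs) — typically log band or
    per-frequency power — and ``labels`` the per-trial condition.  The
    observed clusters come from the t-map of the true labeling; the null
    is the maximum absolute cluster mass over ``n_perm`` random
    relabelings preserving group sizes (or over every C(n, n1) split when
    ``exact``).  Monte-Carlo p per cluster is
    ``(1 + #{null >= |mass|}) / (1 + n_perm)``; in exact mode it is the
    plain enumeration fraction.  Ties count toward the null (>=).
    """
    labels = np.asarray(labels)
    conds = np.unique(labels)
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {list(conds)}")
    sel1 = labels == conds[0]
    n1, n2 = int(sel1.sum()), int((~sel1).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each condition needs at least 2 trials")

    flat = np.asarray(data, dtype=float).reshape(len(labels), -1)
    grid_shape = data.shape[1:]
    obs = indep_tmap(data[sel1], data[~sel1])
    crit = t_critical(obs.df, alpha, "two" if tail == "two" else "one")
    if tail == "two":
        mask = np.abs(obs.t) > crit
    elif tail == "pos":
        mask = obs.t > crit
    else:
        mask = obs.t < -crit
    clusters = form_clusters(mask, montage, t=obs.t)

    total = flat.sum(axis=0)
    total_sq = (flat ** 2).sum(axis=0)
    null_max = []
    for sel in _group_splits(len(labels), n1, n_perm, seed, exact):
        s1 = flat[sel].sum(axis=0)
        q1 = (flat[sel] ** 2).sum(axis=0)
        t_perm = _pooled_t(s1, q1, n1, total - s1, total_sq - q1, n2)
        null_max.append(_max_cluster_mass(t_perm.reshape(grid_shape),
                                          crit, tail, montage))
    null_max = np.asarray(null_max)

    n_draws = len(null_max)
    for c in clusters:
        # tiny slack: observed and permuted masses come from differently
        # ordered summations, exact ties must count toward the null
        hits = int(np.sum(null_max >= abs(c.mass) - 1e-9))
        c.p = hits / n_draws if exact else (1 + hits) / (1 + n_draws)

    return ClusterTestResult(clusters=clusters, null_max=null_max,
                             n_perm=n_draws, threshold=crit, tail=tail,
                             tmap=obs, seed=seed, exact=exact)


def scalar_permutation_test(x: np.ndarray, y: np.ndarray, n_perm: int = 2000,
                            seed: int | None = 0, exact: bool = False
                            ) -> tuple[float, float]:
    """Two-tailed permutation test of a scalar two-sample t contrast.

    Returns ``(t_observed, p)`` with p from trial-label shuffling:
    ``(1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm)`` (plain fraction over
    all C(n, n1) splits when ``exact``).  Degenerate pooled variance in
    the observed split raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate data: all values identical")
    n1, n = len(x), len(pooled)
    total, total_sq = pooled.sum(), (pooled ** 2).sum()

    def t_of(sel: np.ndarray) -> float:
        s1 = pooled[sel].sum()
        q1 = (pooled[sel] ** 2).sum()
        return float(_pooled_t(s1, q1, n1, total - s1, total_sq - q1, n - n1))

    obs_sel = np.zeros(n, dtype=bool)
    obs_sel[:n1] = True
    t_obs = t_of(obs_sel)
    if exact and comb(n, n1) > 5_000_000:
        raise ValueError("design too large for exhaustive enumeration")
    t_null = np.array([t_of(sel) for sel in
                       _group_splits(n, n1, n_perm, seed, exact)])
    hits = int(np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12))
    p = hits / len(t_null) if exact else (1 + hits) / (1 + len(t_null))
    return t_obs, p


def posthoc_electrode_tests(data: np.ndarray, labels: np.ndarray,
                            channels: tuple[str, ...],
                            electrodes: tuple[str, ...],
                            n_perm: int = 2000, seed: int | None = 0
                            ) -> dict[str, tuple[float, float]]:
    """Per-electrode permutation t-tests with max-|t| family correction.

    For each named electrode the observed pooled t is compared with the
    permutation distribution of the *maximum* |t| across the whole
    electrode family, which controls the family-wise error over the set.
    Returns {electrode: (t, corrected p)}.
    """
    labels = np.asarray(labels)
    conds = np.unique(labels)
    if len(conds) != 2:
        raise ValueError("need exactly two conditions")
    cols = [channels.index(e) for e in electrodes]
    sub = np.asarray(data, dtype=float)[:, cols]
    sel1 = labels == conds[0]
    n1, n2 = int(sel1.sum()), int((~sel1).sum())
    obs = indep_tmap(sub[sel1], sub[~sel1]).t

    total, total_sq = sub.sum(0), (sub ** 2).sum(0)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for i in range(n_perm):
        sel = np.zeros(len(labels), dtype=bool)
        sel[rng.permutation(len(labels))[:n1]] = True
        s1, q1 = sub[sel].sum(0), (sub[sel] ** 2).sum(0)
        t_perm = _pooled_t(s1, q1, n1, total - s1, total_sq - q1, n2)
        max_null[i] = np.abs(t_perm).max()
    out = {}
    for e, t_e in zip(electrodes, obs):
        p = (1 + int(np.sum(max_null >= abs(t_e)))) / (1 + n_perm)
        out[e] = (float(t_e), float(p))
    return out
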