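"""Cluster-based permutation statistics: t-maps, clustering, null calibration."""

from itertools import combinations

import numpy as np
import pytest

from sharewave.montage import build_default_montage
from sharewave.permstats import (form_clusters, indep_tmap, permutation_null,
                                 scalar_permutation_test, threshold_mask,
                                 posthoc_electrode_tests, TMap)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def bfs_clusters(mask, adj, sign=None):
    """Brute-force connected components on the (channel, freq) point graph."""
    n_ch, n_f = mask.shape
    pts = {(c, f) for c in range(n_ch) for f in range(n_f) if mask[c, f]}
    seen, comps = set(), []
    for start in sorted(pts):
        if start in seen:
            continue
        comp, queue = set(), [start]
        seen.add(start)
        while queue:
            c, f = queue.pop()
            comp.add((c, f))
            cand = [(c, f - 1), (c, f + 1)]
            cand += [(c2, f) for c2 in range(n_ch) if adj[c, c2]]
            for q in cand:
                if q in pts and q not in seen:
                    if sign is None or sign[q] == sign[(c, f)]:
                        seen.add(q)
                        queue.append(q)
        comps.append(frozenset(comp))
    return set(comps)


def pooled_t_scalar(x, y):
    n1, n2 = len(x), len(y)
    sp2 = (np.sum((x - np.mean(x)) ** 2) + np.sum((y - np.mean(y)) ** 2)) \
        / (n1 + n2 - 2)
    return (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


# ---------------------------------------------------------------------------
# t-maps and thresholding
# ---------------------------------------------------------------------------

class TestTMap:
    def test_identical_groups_give_zero(self):
        g = np.random.default_rng(0).normal(size=(5, 3, 4))
        assert np.allclose(indep_tmap(g, g).t, 0.0)

    def test_hand_computed_value(self):
        tm = indep_tmap(np.array([[1.0], [2.0], [3.0]]),
                        np.array([[4.0], [5.0], [6.0]]))
        assert tm.t[0] == pytest.approx(-3.674, abs=5e-4)
        assert tm.df == 4

    def test_swapping_groups_negates(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(6, 4)), rng.normal(size=(9, 4))
        assert np.allclose(indep_tmap(a, b).t, -indep_tmap(b, a).t)

    def test_matches_scipy_ttest(self):
        from scipy.stats import ttest_ind
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(8, 5)), rng.normal(size=(12, 5))
        assert np.allclose(indep_tmap(a, b).t, ttest_ind(a, b).statistic)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            indep_tmap(np.ones((1, 3)), np.ones((5, 3)))


class TestThresholdMask:
    def test_zero_map_empty_mask(self):
        tm = TMap(t=np.zeros((3, 4)), n1=10, n2=10)
        assert not threshold_mask(tm).any()

    def test_two_tailed_cutoff_at_large_df(self):
        # df = 1413 ~ the study's trial counts; cutoff ~ 1.962
        tm = TMap(t=np.array([2.0, 1.9, -2.0]), n1=316, n2=1099)
        mask = threshold_mask(tm, alpha=0.05, tail="two")
        assert list(mask) == [True, False, True]

    def test_one_tailed_sign_semantics(self):
        tm = TMap(t=np.array([-10.0, 10.0]), n1=10, n2=10)
        assert list(threshold_mask(tm, 0.05, "pos")) == [False, True]
        assert list(threshold_mask(tm, 0.05, "neg")) == [True, False]


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

class TestFormClusters:
    def test_empty_mask_no_clusters(self, montage):
        mask = np.zeros((len(montage.analysis_channels), 5), dtype=bool)
        assert form_clusters(mask, montage) == []

    def test_adjacent_frequencies_merge(self, montage):
        mask = np.zeros((len(montage.analysis_channels), 5), dtype=bool)
        fz = montage.analysis_channels.index("Fz")
        mask[fz, 1] = mask[fz, 2] = True
        clusters = form_clusters(mask, montage)
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_non_adjacent_channels_stay_separate(self, montage):
        mask = np.zeros((len(montage.analysis_channels), 5), dtype=bool)
        mask[montage.analysis_channels.index("Fp1"), 2] = True
        mask[montage.analysis_channels.index("O2"), 2] = True
        assert len(form_clusters(mask, montage)) == 2

    def test_opposite_signs_never_merge(self, montage):
        n_ch = len(montage.analysis_channels)
        mask = np.zeros((n_ch, 3), dtype=bool)
        fz = montage.analysis_channels.index("Fz")
        mask[fz, 0] = mask[fz, 1] = True
        t = np.zeros((n_ch, 3))
        t[fz, 0], t[fz, 1] = 3.0, -3.0
        clusters = form_clusters(mask, montage, t=t)
        assert len(clusters) == 2

    def test_matches_bfs_oracle_on_random_masks(self, montage):
        adj = montage.adjacency_matrix()
        n_ch = len(montage.analysis_channels)
        rng = np.random.default_rng(3)
        for _ in range(20):
            mask = rng.random((n_ch, 29)) < 0.08
            got = {frozenset(c.members) for c in form_clusters(mask, montage)}
            assert got == bfs_clusters(mask, adj)

    def test_channel_relabeling_equivariance(self, montage):
        from dataclasses import replace
        rng = np.random.default_rng(4)
        n_ch = len(montage.analysis_channels)
        mask = rng.random((n_ch, 7)) < 0.15
        base = {frozenset((montage.analysis_channels[c], f)
                          for c, f in cl.members)
                for cl in form_clusters(mask, montage)}
        perm = rng.permutation(n_ch)
        permuted = replace(
            montage,
            analysis_channels=tuple(montage.analysis_channels[i] for i in perm))
        got = {frozenset((permuted.analysis_channels[c], f)
                         for c, f in cl.members)
               for cl in form_clusters(mask[perm], permuted)}
        assert got == base


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

class TestPermutationNull:
    def small_dataset(self, delta=8.0, seed=5):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(6, 3, 2))
        data[:3, 0, :] += delta
        labels = np.array(["share"] * 3 + ["noshare"] * 3)
        return data, labels

    def small_montage(self):
        from sharewave.montage import Montage
        return Montage(labels=("F3", "Fz", "F4"),
                       coords={"F3": (-1, 0), "Fz": (0, 0), "F4": (1, 0)},
                       adjacency={"F3": frozenset({"Fz"}),
                                  "Fz": frozenset({"F3", "F4"}),
                                  "F4": frozenset({"Fz"})},
                       analysis_channels=("F3", "Fz", "F4"))

    def enumeration_oracle(self, data, labels, montage, alpha=0.05):
        """Exhaustive max-cluster-mass null, built from first principles."""
        from scipy.stats import t as tdist
        n = len(labels)
        n1 = int(np.sum(labels == "share"))
        crit = tdist.ppf(1 - alpha / 2, n - 2)
        adj = montage.adjacency_matrix()

        def max_mass(idx1):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx1)] = True
            t = np.empty(data.shape[1:])
            for c in range(data.shape[1]):
                for f in range(data.shape[2]):
                    t[c, f] = pooled_t_scalar(data[sel, c, f],
                                              data[~sel, c, f])
            mask = np.abs(t) > crit
            comps = bfs_clusters(mask, adj, sign={(c, f): np.sign(t[c, f])
                                                  for c in range(t.shape[0])
                                                  for f in range(t.shape[1])})
            masses = [abs(sum(t[c, f] for c, f in comp)) for comp in comps]
            return max(masses, default=0.0)

        return [max_mass(idx) for idx in combinations(range(n), n1)]

    def test_exact_p_matches_enumeration_oracle(self):
        data, labels = self.small_dataset()
        montage = self.small_montage()
        res = permutation_null(data, labels, montage, exact=True)
        oracle_null = self.enumeration_oracle(data, labels, montage)
        assert res.n_perm == 20
        assert res.clusters, "the injected shift must form a cluster"
        for cl in res.clusters:
            expect = np.mean([m >= abs(cl.mass) - 1e-12 for m in oracle_null])
            assert cl.p == pytest.approx(expect)

    def test_no_suprathreshold_points_reports_no_clusters(self, montage):
        rng = np.random.default_rng(6)
        data = np.zeros((8, len(montage.analysis_channels), 2))
        data += rng.normal(scale=1e-3, size=data.shape)
        # huge threshold via tiny alpha: nothing survives
        res = permutation_null(data, np.array(["share"] * 4 + ["noshare"] * 4),
                               montage, n_perm=20, alpha=1e-9, seed=0)
        assert res.clusters == []
        assert res.p_values == []

    def test_deterministic_per_seed(self):
        data, labels = self.small_dataset(delta=1.0)
        montage = self.small_montage()
        a = permutation_null(data, labels, montage, n_perm=100, seed=42)
        b = permutation_null(data, labels, montage, n_perm=100, seed=42)
        assert np.allclose(a.null_max, b.null_max)
        assert a.p_values == b.p_values

    def test_p_never_zero_and_monotone_in_mass(self):
        data, labels = self.small_dataset()
        res = permutation_null(data, labels, self.small_montage(),
                               n_perm=200, seed=1)
        ps = [c.p for c in res.clusters]
        masses = [abs(c.mass) for c in res.clusters]
        assert all(p > 0 for p in ps)
        order = np.argsort(masses)[::-1]
        assert list(np.array(ps)[order]) == sorted(ps)

    def test_single_condition_rejected(self):
        data = np.zeros((4, 2, 2))
        with pytest.raises(ValueError):
            permutation_null(data, np.array(["share"] * 4),
                             self.small_montage())


class TestScalarPermutation:
    def test_identical_groups_give_p_one(self):
        t, p = scalar_permutation_test([1, 2, 3], [1, 2, 3], exact=True)
        assert t == pytest.approx(0.0)
        assert p == 1.0

    def test_full_enumeration_two_tailed_p(self):
        t, p = scalar_permutation_test([1, 2, 3], [101, 102, 103], exact=True)
        assert p == pytest.approx(2 / 20)
        assert t < 0

    def test_monte_carlo_matches_enumeration(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=4), rng.normal(loc=1.5, size=4)
        _, p_exact = scalar_permutation_test(x, y, exact=True)
        _, p_mc = scalar_permutation_test(x, y, n_perm=2000, seed=0)
        se = np.sqrt(p_exact * (1 - p_exact) / 2000)
        assert abs(p_mc - p_exact) < 3 * se + 1 / 2001

    def test_doubling_permutations_is_stable(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=20), rng.normal(loc=0.8, size=20)
        _, p1 = scalar_permutation_test(x, y, n_perm=1000, seed=3)
        _, p2 = scalar_permutation_test(x, y, n_perm=2000, seed=3)
        se = np.sqrt(p1 * (1 - p1) / 1000)
        assert abs(p2 - p1) <= 3 * se + 2e-3

    def test_same_seed_same_p(self):
        x, y = [1.0, 2, 3, 4], [2.0, 3, 4, 6]
        assert scalar_permutation_test(x, y, n_perm=500, seed=9) == \
            scalar_permutation_test(x, y, n_perm=500, seed=9)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            scalar_permutation_test([1.0, 1.0], [1.0, 1.0])


def test_posthoc_family_correction_orders_p_with_t(montage):
    rng = np.random.default_rng(10)
    data = rng.normal(size=(60, 4))
    data[:30, 0] += 1.5      # strong effect at the first electrode
    data[:30, 1] += 0.5      # weak effect at the second
    labels = np.array(["share"] * 30 + ["noshare"] * 30)
    res = posthoc_electrode_tests(data, labels, ("F3", "Fz", "F4", "O2"),
                                  ("F3", "Fz"), n_perm=500, seed=0)
    assert res["F3"][1] < res["Fz"][1]
    assert all(0 < p <= 1 for _t, p in res.values())
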