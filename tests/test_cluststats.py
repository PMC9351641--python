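import itertools

import numpy as np
import pytest
from scipy import stats

from speechcoh.cluststats import (ClusterResult, SubjectStatMap,
                                  one_sample_cluster_test, roi_average,
                                  roi_contrast)
from speechcoh.spectral import CoherenceMap


def grid_adj(n_rows, n_cols):
    n = n_rows * n_cols
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        r, c = divmod(i, n_cols)
        for j in range(n):
            r2, c2 = divmod(j, n_cols)
            if abs(r - r2) + abs(c - c2) == 1:
                adj[i, j] = True
    return adj


def make_maps(values, adj=None, freqs=None):
    n_ch, n_fr = values.shape[1:]
    if adj is None:
        adj = grid_adj(1, n_ch)
    if freqs is None:
        freqs = np.arange(2, 2 + n_fr, dtype=float)
    return SubjectStatMap(values, adjacency=adj, freqs=freqs)


# ---------------------------------------------------------------------------
# independent oracle: naive clustering + scipy t-tests + explicit sign flips
# ---------------------------------------------------------------------------

def naive_cluster_masses(t_map, cdt, adj):
    n_ch, n_fr = t_map.shape
    supra = {(c, f) for c in range(n_ch) for f in range(n_fr) if t_map[c, f] > cdt}
    seen, masses, clusters = set(), [], []
    for cell in supra:
        if cell in seen:
            continue
        stack, comp = [cell], set()
        while stack:
            c, f = stack.pop()
            if (c, f) in comp:
                continue
            comp.add((c, f))
            for c2 in range(n_ch):
                if adj[c, c2] and (c2, f) in supra and (c2, f) not in comp:
                    stack.append((c2, f))
            for f2 in (f - 1, f + 1):
                if (c, f2) in supra and (c, f2) not in comp:
                    stack.append((c, f2))
        seen |= comp
        clusters.append(comp)
        masses.append(sum(t_map[c, f] for c, f in comp))
    return clusters, masses


class TestClusterTest:
    def test_all_zero_maps_give_empty_cluster_list(self):
        with pytest.warns(UserWarning):
            res = one_sample_cluster_test(
                make_maps(np.zeros((8, 4, 3))), n_perm=20, seed=0)
        assert res.clusters == []

    def test_sign_flip_antisymmetry(self, rng):
        """Negating every subject's map negates every cell t exactly."""
        vals = rng.standard_normal((10, 5, 4))
        a = one_sample_cluster_test(make_maps(vals), n_perm=10, seed=0)
        b = one_sample_cluster_test(make_maps(-vals), n_perm=10, seed=0)
        assert np.allclose(a.t_map, -b.t_map)

    def test_channel_relabeling_permutes_clusters(self, rng):
        vals = rng.standard_normal((12, 6, 4))
        vals[:, 1:4, 1:3] += 1.2
        adj = grid_adj(2, 3)
        res = one_sample_cluster_test(make_maps(vals, adj), n_perm=50, seed=1)
        perm = np.array([3, 0, 5, 2, 4, 1])
        res_p = one_sample_cluster_test(
            make_maps(vals[:, perm, :], adj[np.ix_(perm, perm)]),
            n_perm=50, seed=1)
        # permuted channel j holds original channel perm[j]
        orig = {frozenset(cl) for cl in
                ([(int(perm[c]), f) for c, f in cl] for cl in res_p.clusters)}
        assert {frozenset(cl) for cl in res.clusters} == orig
        assert sorted(np.round(res.masses, 10)) == sorted(np.round(res_p.masses, 10))

    def test_stricter_threshold_never_enlarges_clusters(self, rng):
        vals = rng.standard_normal((14, 8, 5)) + 0.4
        adj = grid_adj(2, 4)
        loose = one_sample_cluster_test(make_maps(vals, adj), n_perm=10,
                                        cdt_p=0.05, seed=0)
        strict = one_sample_cluster_test(make_maps(vals, adj), n_perm=10,
                                         cdt_p=0.005, seed=0)
        loose_cells = set().union(*[set(c) for c in loose.clusters]) if loose.clusters else set()
        strict_cells = set().union(*[set(c) for c in strict.clusters]) if strict.clusters else set()
        assert strict_cells <= loose_cells

    def test_exhaustive_enumeration_matches_brute_force(self, rng):
        """p-values from n_perm='all' equal a from-scratch enumeration of
        all 2^n sign flips with naive clustering."""
        n_sub, n_ch, n_fr = 6, 3, 3
        vals = rng.standard_normal((n_sub, n_ch, n_fr))
        vals[:, :2, :2] += 1.0
        adj = grid_adj(1, 3)
        maps = make_maps(vals, adj)
        res = one_sample_cluster_test(maps, n_perm="all", cdt_p=0.1, seed=0)

        cdt = stats.t.ppf(0.9, df=n_sub - 1)
        null_max = []
        for signs in itertools.product((1, -1), repeat=n_sub):
            flipped = vals * np.array(signs)[:, None, None]
            t_map = stats.ttest_1samp(flipped, 0.0, axis=0).statistic
            _, masses = naive_cluster_masses(t_map, cdt, adj)
            null_max.append(max(masses) if masses else 0.0)
        null_max = np.asarray(null_max)

        t_obs = stats.ttest_1samp(vals, 0.0, axis=0).statistic
        clusters, masses = naive_cluster_masses(t_obs, cdt, adj)
        expect_p = sorted((np.sum(null_max >= m) + 1) / (null_max.size + 1)
                          for m in masses)
        assert sorted(np.round(res.masses, 9)) == sorted(np.round(masses, 9))
        assert np.allclose(sorted(res.p_values), expect_p)

    def test_injected_block_recovered(self, rng):
        """A contiguous channel x frequency effect is found with high cell
        coverage."""
        adj = grid_adj(3, 4)
        hits = 0
        reps = 10
        for s in range(reps):
            vals = rng.standard_normal((14, 12, 7))
            vals[:, 2:6, 2:5] += 1.0
            res = one_sample_cluster_test(make_maps(vals, adj), n_perm=200, seed=s)
            mask = res.mask((12, 7))
            block = np.zeros((12, 7), dtype=bool)
            block[2:6, 2:5] = True
            if mask[block].mean() >= 0.8:
                hits += 1
        assert hits >= 0.9 * reps

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            one_sample_cluster_test(make_maps(rng.standard_normal((3, 4, 3))),
                                    n_perm=10)


def test_matches_mne_observed_clusters(rng):
    """Observed supra-threshold clusters and masses agree with the MNE
    implementation of the same test."""
    mne_stats = pytest.importorskip("mne.stats")
    from scipy import sparse

    n_sub, n_ch, n_fr = 12, 6, 5
    vals = rng.standard_normal((n_sub, n_ch, n_fr))
    vals[:, 1:4, 1:4] += 0.9
    adj = grid_adj(2, 3)
    res = one_sample_cluster_test(make_maps(vals, adj), n_perm=100, seed=0)

    # mne expects (obs, tests...) with adjacency over the flattened space
    from mne.stats import combine_adjacency
    adjacency = combine_adjacency(sparse.coo_matrix(adj.astype(int)), n_fr)
    t_obs, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
        vals.reshape(n_sub, -1), threshold=res.cdt, n_permutations=50,
        adjacency=adjacency, tail=1, t_power=1, seed=0, out_type="mask",
        verbose="error")
    mne_masses = sorted(float(t_obs[m].sum()) for m in clusters)
    assert np.allclose(sorted(res.masses), mne_masses, atol=1e-8)


class TestROI:
    def test_single_channel_roi_is_band_mean(self):
        cm = CoherenceMap(np.arange(12).reshape(3, 4) / 20.0, freqs=[2, 4, 6, 8],
                          channel_names=["a", "b", "c"])
        # channel b, band 2-6 -> freqs 2,4,6 -> values .20,.25,.30
        assert roi_average(cm, ["b"], band=(2, 6), use_effect=False) == pytest.approx(0.25)

    def test_roi_mean_matches_brute_force_arithmetic(self):
        vals = np.array([[[1.0, 2.0, 3.0], [5.0, 7.0, 9.0]]])
        maps = SubjectStatMap(vals, adjacency=grid_adj(1, 2), freqs=[2, 4, 6],
                              channel_names=["x", "y"])
        out = roi_average(maps, ["x", "y"], band=(2, 6))
        assert out[0] == pytest.approx((1 + 2 + 3 + 5 + 7 + 9) / 6)

    def test_unknown_label_rejected(self):
        cm = CoherenceMap(np.ones((2, 3)), freqs=[2, 3, 4], channel_names=["a", "b"])
        with pytest.raises(KeyError):
            roi_average(cm, ["nope"])
        with pytest.raises(ValueError):
            roi_average(cm, [])

    def test_uses_effect_when_baseline_present(self):
        cm = CoherenceMap(np.full((1, 3), 0.5), freqs=[2, 4, 6],
                          channel_names=["a"], baseline=np.full((1, 3), 0.2))
        assert roi_average(cm, ["a"]) == pytest.approx(0.3)


class TestROIContrast:
    def test_equal_samples_give_t_zero_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p, mean = roi_contrast(a, a, tail="two")
        assert t == 0.0 and p == 1.0 and mean == 0.0

    def test_constant_nonzero_difference_flagged(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            roi_contrast(a, a - 2.0, tail="two")

    def test_constant_difference_with_jitter_highly_significant(self, rng):
        a = np.full(10, 5.0) + rng.normal(0, 1e-6, 10)
        t, p, _ = roi_contrast(a, np.zeros(10), tail="one")
        assert p < 1e-6

    def test_hand_computed_t(self):
        t, p, mean = roi_contrast(np.array([1.0, 2.0, 3.0, 4.0]), 0.0, tail="two")
        assert t == pytest.approx(3.873, abs=1e-3)
        assert mean == pytest.approx(2.5)

    def test_tail_convention(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t1, p1, _ = roi_contrast(a, 0.0, tail="one")
        t2, p2, _ = roi_contrast(a, 0.0, tail="two")
        assert p2 == pytest.approx(2 * p1)
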