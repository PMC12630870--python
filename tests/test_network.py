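"""Neighborhood deviation, spin/shuffle nulls and epicenter mapping."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from ndmap.containers import Connectome
from ndmap.network import (
    _greedy_assign,
    epicenter_map,
    neighborhood_deviation,
    node_vs_neighbor_coupling,
    shuffle_permute,
    spin_permute,
)


class TestNeighborhoodDeviation:
    def test_hand_path_graph(self):
        # 3-node path, C12=2, C23=4, p=(0.1,0.2,0.3)
        w = np.array([[0, 2, 0], [2, 0, 4], [0, 4, 0]], float)
        sc = Connectome(w, np.arange(3))
        pbar = neighborhood_deviation(np.array([0.1, 0.2, 0.3]), sc)
        assert np.allclose(pbar, [0.4, 0.7, 0.8])

    def test_binary_weights_collapse_to_neighbor_mean(self, rng):
        n = 12
        w = (rng.random((n, n)) < 0.4).astype(float)
        w = np.triu(w, 1)
        w = w + w.T
        w[0, 1] = w[1, 0] = 1.0   # ensure a neighbour somewhere
        sc = Connectome(w, np.arange(n))
        p = rng.random(n)
        pbar = neighborhood_deviation(p, sc)
        for i in range(n):
            nbrs = np.nonzero(w[i])[0]
            if nbrs.size:
                assert np.isclose(pbar[i], p[nbrs].mean())

    def test_uniform_map_constancy_binary(self):
        w = np.ones((6, 6)) - np.eye(6)
        sc = Connectome(w, np.arange(6))
        assert np.allclose(neighborhood_deviation(np.full(6, 0.3), sc), 0.3)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(25):
            n = 30
            w = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
            w = np.triu(w, 1)
            w = w + w.T
            sc = Connectome(w, np.arange(n))
            p = rng.random(n)
            got = neighborhood_deviation(p, sc)
            for i in range(n):
                acc, deg = 0.0, 0
                for j in range(n):
                    if i != j and w[i, j] > 0:
                        acc += p[j] * w[i, j]
                        deg += 1
                if deg == 0:
                    assert np.isnan(got[i])
                else:
                    assert abs(got[i] - acc / deg) < 1e-12

    def test_all_zero_connectome_rejected(self):
        sc = Connectome(np.zeros((5, 5)), np.arange(5))
        with pytest.raises(ValueError, match="no edges"):
            neighborhood_deviation(np.ones(5), sc)


class TestSpinPermute:
    def test_identity_rotation_recovers_identity(self, atlas26):
        sph = atlas26.sphere_coords[atlas26.cortical_mask & atlas26.hemisphere_mask("left")]
        dist = np.linalg.norm(sph[:, None] - sph[None, :], axis=-1)
        assert np.array_equal(_greedy_assign(dist), np.arange(len(sph)))

    def test_permutation_property_and_hemisphere_restriction(self, atlas26):
        null = spin_permute(atlas26, n_iter=50, seed=0)
        n = atlas26.n_regions
        left = np.nonzero(atlas26.hemisphere_mask("left") & atlas26.cortical_mask)[0]
        right = np.nonzero(atlas26.hemisphere_mask("right") & atlas26.cortical_mask)[0]
        for it in range(50):
            perm = null.perms[it]
            assert np.array_equal(np.sort(perm), np.arange(n))
            assert set(perm[left]) == set(left)
            assert set(perm[right]) == set(right)

    def test_null_maps_preserve_value_multiset(self, atlas26, rng):
        null = spin_permute(atlas26, n_iter=10, seed=1)
        v = rng.random(atlas26.n_regions)
        for nm in null.apply(v):
            assert np.allclose(np.sort(nm), np.sort(v))

    def test_spatial_autocorrelation_preserved(self, atlas26, rng):
        """Moran's I of spun maps stays within a factor 2 of the input's."""
        cort = atlas26.cortical_mask
        cen = atlas26.centroids
        # smooth map: linear gradient along y plus mild noise
        v = np.zeros(atlas26.n_regions)
        v[:] = cen[:, 1] / 70.0 + 0.2 * rng.standard_normal(atlas26.n_regions)

        d = np.linalg.norm(cen[cort][:, None] - cen[cort][None, :], axis=-1)
        W = 1.0 / np.maximum(d, 1e-9)
        np.fill_diagonal(W, 0.0)

        def morans(x):
            x = x - x.mean()
            return len(x) / W.sum() * (x @ W @ x) / (x @ x)

        base = morans(v[cort])
        null = spin_permute(atlas26, n_iter=100, seed=2, shuffle_subcortex=False)
        ratios = [morans(nm[cort]) / base for nm in null.apply(v)]
        assert 0.5 < np.median(ratios) < 2.0


class TestShufflePermute:
    def test_small_and_degenerate(self):
        with pytest.raises(ValueError):
            shuffle_permute(1, n_iter=10)
        null = shuffle_permute(6, n_iter=20, seed=3)
        for perm in null.perms:
            assert np.array_equal(np.sort(perm), np.arange(6))

    def test_pvalue_uniform_under_independence(self, rng):
        """Calibration oracle: shuffle p-values are ~uniform for random maps."""
        from scipy.stats import kstest
        n, n_iter = 12, 199
        pvals = []
        for b in range(150):
            x, y = rng.random((2, n))
            obs = spearmanr(x, y).statistic
            null = shuffle_permute(n, n_iter=n_iter, seed=1000 + b)
            nulls = np.array([spearmanr(xm, y).statistic for xm in null.apply(x)])
            pvals.append((1 + (nulls >= obs).sum()) / (1 + n_iter))
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestCouplingAndEpicenters:
    def test_assortative_map_detected(self, atlas26, connectome26):
        seed_idx = 4
        p = connectome26.weights[seed_idx] / connectome26.weights[seed_idx].max()
        p[seed_idx] = 1.0
        null = spin_permute(atlas26, n_iter=199, seed=5)
        rho, p_spin, pbar = node_vs_neighbor_coupling(p, connectome26, null)
        assert rho > 0.3
        assert p_spin < 0.05

    def test_constant_map_rejected(self, atlas26, connectome26):
        null = spin_permute(atlas26, n_iter=10, seed=6)
        with pytest.raises(ValueError, match="constant"):
            node_vs_neighbor_coupling(np.full(26, 0.2), connectome26, null)

    def test_self_match_profile_ranks_first(self, atlas26, connectome26):
        i = 7
        p = connectome26.weights[i].copy()
        null = spin_permute(atlas26, n_iter=199, seed=7)
        res = epicenter_map(p, connectome26, null)
        assert np.isclose(res.likelihood[i], 1.0)
        assert res.rank[i] == 1

    def test_spatial_correlation_detects_matched_maps(self, atlas26, connectome26, rng):
        from ndmap.network import spatial_correlation
        null = spin_permute(atlas26, n_iter=199, seed=12)
        b = atlas26.centroids[:, 1]          # smooth anterior-posterior gradient
        a = b + 2.0 * rng.standard_normal(26)
        rho, p = spatial_correlation(a, b, null)
        assert rho > 0.9 and p < 0.05
        rho0, p0 = spatial_correlation(rng.random(26), rng.random(26), null)
        assert p0 > 0.01

    def test_likelihood_monotone_invariant(self, atlas26, connectome26, rng):
        p = rng.random(26)
        null = spin_permute(atlas26, n_iter=49, seed=8)
        r1 = epicenter_map(p, connectome26, null)
        r2 = epicenter_map(np.exp(3 * p), connectome26, null)
        assert np.allclose(r1.likelihood, r2.likelihood, atol=1e-12)
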