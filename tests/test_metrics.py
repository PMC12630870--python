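"""Functional metric definitions, hand-computed oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndmap.atlas import Atlas
from ndmap.containers import VertexData
from ndmap.metrics import (
    global_signal_regress,
    kendall_w,
    node_strength,
    region_timeseries,
    reho_map,
    signal_variability,
)


class TestSignalVariability:
    def test_constant_series_is_zero(self):
        assert signal_variability(np.full(10, 3.0)) == 0.0

    def test_hand_value(self):
        # x=(0,1,0,1): three unit jumps, T=4 -> sqrt(3)/3
        assert np.isclose(signal_variability(np.array([0.0, 1, 0, 1])), np.sqrt(3) / 3)

    def test_rmssd_variant(self):
        x = np.array([0.0, 1, 0, 1])
        assert np.isclose(signal_variability(x, variant="rmssd"), 1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40),
           st.floats(0.1, 50), st.floats(-100, 100))
    def test_homogeneity_and_translation(self, xs, a, c):
        x = np.asarray(xs)
        sv = signal_variability(x)
        assert np.isclose(signal_variability(a * x), a * sv, rtol=1e-9, atol=1e-12)
        assert np.isclose(signal_variability(x + c), sv, rtol=1e-9, atol=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            signal_variability(np.array([1.0]))
        with pytest.raises(ValueError):
            signal_variability(np.array([1.0, np.nan, 2.0]))


class TestKendallW:
    def test_identical_series_full_concordance(self, rng):
        x = rng.normal(size=12)
        assert np.isclose(kendall_w(np.tile(x, (5, 1))), 1.0)

    def test_rank_reversal_k2_is_zero(self):
        # K=2: W = (1 + spearman) / 2, so a perfect rank reversal gives 0
        x = np.arange(8.0)
        assert np.isclose(kendall_w(np.vstack([x, x[::-1]])), 0.0, atol=1e-12)

    def test_k2_closed_form_matches_spearman(self, rng):
        from scipy.stats import spearmanr
        x, y = rng.normal(size=(2, 20))
        w = kendall_w(np.vstack([x, y]))
        rho = spearmanr(x, y).statistic
        assert np.isclose(w, (1 + rho) / 2, atol=1e-12)

    def test_independent_noise_mean_near_one_over_k(self):
        # Monte-Carlo oracle: E[W] = 1/K under independence
        rng = np.random.default_rng(5)
        K, T = 10, 20
        ws = [kendall_w(rng.normal(size=(K, T))) for _ in range(1000)]
        assert abs(np.mean(ws) - 1.0 / K) < 0.01

    def test_monotone_transform_invariance(self, rng):
        X = rng.normal(size=(4, 15))
        assert np.isclose(kendall_w(X), kendall_w(np.exp(X)), atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_w(np.vstack([np.ones(5), np.arange(5.0)]))


def _toy_vertex_data(rng, atlas, shared=False):
    V, T = 3, 30
    n = atlas.n_regions
    region = np.repeat(atlas.region_ids, V)
    neighbors = []
    for r in range(n):
        block = list(range(r * V, (r + 1) * V))
        neighbors.extend([[u for u in block if u != v] for v in block])
    if shared:
        base = rng.normal(size=(n, T))
        ts = np.repeat(base, V, axis=0) + 0.0
    else:
        ts = rng.normal(size=(n * V, T))
    return VertexData(ts, region, neighbors)


class TestRehoMap:
    def test_shared_series_gives_one(self, atlas26, rng):
        vd = _toy_vertex_data(rng, atlas26, shared=True)
        assert np.allclose(reho_map(vd, atlas26), 1.0)

    def test_independent_noise_near_one_over_k(self, atlas26):
        rng = np.random.default_rng(7)
        vals = np.vstack([reho_map(_toy_vertex_data(rng, atlas26), atlas26)
                          for _ in range(40)])
        # neighbourhood size K = 3 vertices per region
        assert abs(vals.mean() - 1.0 / 3) < 0.02

    def test_between_region_edges_ignored(self, atlas26, rng):
        vd = _toy_vertex_data(rng, atlas26)
        base = reho_map(vd, atlas26)
        nbrs = [list(x) for x in vd.vertex_neighbors]
        nbrs[0].append(5)   # vertex 5 lives in another region
        nbrs[5].append(0)
        vd2 = VertexData(vd.timeseries, vd.vertex_region, nbrs)
        assert np.allclose(reho_map(vd2, atlas26), base)


class TestNodeStrength:
    def test_identical_series_full_strength(self, atlas26, rng):
        n = atlas26.n_regions
        base = rng.normal(size=30)
        rts = np.tile(base, (n, 1)) * rng.uniform(0.5, 2.0, size=(n, 1))
        ns = node_strength(rts, atlas26, "full")
        assert np.allclose(ns, n - 1, atol=1e-8)

    def test_independent_series_near_zero(self, atlas26):
        rng = np.random.default_rng(3)
        ns = [node_strength(rng.normal(size=(26, 200)), atlas26, "full") for _ in range(20)]
        assert abs(np.mean(ns)) < 0.5

    def test_distance_split_conservation(self, atlas26, rng):
        rts = rng.normal(size=(26, 40))
        full = node_strength(rts, atlas26, "full")
        short = node_strength(rts, atlas26, "short")
        long_ = node_strength(rts, atlas26, "long")
        assert np.allclose(short + long_, full, atol=1e-12)

    def test_affine_invariance(self, atlas26, rng):
        rts = rng.normal(size=(26, 40))
        scaled = rts * rng.uniform(0.5, 3, size=(26, 1)) + rng.normal(size=(26, 1))
        assert np.allclose(node_strength(rts, atlas26, "full"),
                           node_strength(scaled, atlas26, "full"), atol=1e-9)

    def test_zero_variance_names_region(self, atlas26, rng):
        rts = rng.normal(size=(26, 40))
        rts[4] = 1.0
        with pytest.raises(ValueError, match=str(atlas26.region_ids[4])):
            node_strength(rts, atlas26, "full")


def test_global_signal_regression_removes_global_component(atlas26, rng):
    vd = _toy_vertex_data(rng, atlas26)
    g = rng.normal(size=vd.T)
    ts = vd.timeseries + 3.0 * g[None, :]
    vd2 = VertexData(ts, vd.vertex_region, vd.vertex_neighbors)
    out = global_signal_regress(vd2)
    before = ts.mean(axis=0).std()
    after = out.timeseries.mean(axis=0).std()
    assert after < 1e-8 * before   # global mean signal eliminated
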