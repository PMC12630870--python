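"""Synthetic-cohort generator: construction, determinism, designed effects."""

import numpy as np
import pytest

from ndmap.metrics import compute_metrics
from ndmap.normative import deviation_set
from ndmap.simulate import (
    SimulationConfig,
    simulate_atlas,
    simulate_cohort,
    simulate_connectome,
)


class TestSimulateAtlas:
    def test_pairing_and_mirroring(self):
        atlas = simulate_atlas(20, 6, seed=0)
        assert atlas.n_regions == 26
        h = atlas.homologue_index()
        assert np.array_equal(h[h], np.arange(26))
        assert (atlas.table["hemisphere"] != "midline").all()

    def test_odd_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_atlas(19, 6)
        with pytest.raises(ValueError):
            simulate_atlas(20, 5)

    def test_five_cortical_lobes_present(self):
        atlas = simulate_atlas(20, 6, seed=3)
        assert set(atlas.table.loc[atlas.cortical_mask, "lobe"]) == {
            "frontal", "parietal", "temporal", "occipital", "insula"}


def _bfs_connected(w: np.ndarray) -> bool:
    """Independent graph-search oracle for connectivity."""
    n = w.shape[0]
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in np.nonzero(w[i] > 0)[0]:
            if j not in seen:
                seen.add(int(j))
                stack.append(int(j))
    return len(seen) == n


class TestSimulateConnectome:
    @pytest.mark.parametrize("density", [0.05, 0.2, 0.6, 1.0])
    def test_connected_at_any_density(self, atlas26, density):
        sc = simulate_connectome(atlas26, density=density, seed=4)
        assert _bfs_connected(sc.weights)
        assert np.allclose(sc.weights, sc.weights.T)
        assert np.all(np.diag(sc.weights) == 0)

    def test_full_density_complete_graph(self, atlas26):
        sc = simulate_connectome(atlas26, density=1.0, seed=4)
        off = ~np.eye(26, dtype=bool)
        assert (sc.weights[off] > 0).all()


class TestSimulateCohort:
    def test_deterministic_under_seed(self, atlas26, connectome26):
        cfg = SimulationConfig(seed=9, n_hc_per_site=3, n_tle_per_site=3,
                               n_fcd_per_site=1, n_sites=1, T=40)
        a = simulate_cohort(cfg, atlas26, connectome26)
        b = simulate_cohort(cfg, atlas26, connectome26)
        assert a[0].equals(b[0])
        sid = a[0]["subject_id"].iloc[0]
        assert np.array_equal(a[1][sid].timeseries, b[1][sid].timeseries)
        assert np.array_equal(a[2]["CT"].values, b[2]["CT"].values)

    def test_effect_targets_designed_regions(self, atlas26, connectome26):
        eff = tuple(atlas26.region_ids[[2, 8]])
        cfg = SimulationConfig(seed=5, n_sites=1, n_hc_per_site=40,
                               n_tle_per_site=40, n_fcd_per_site=0,
                               effect_regions=eff, effect_size_w=3.0,
                               prop_left_focus=1.0, n_calibration=30)
        subjects, vd, struct, truth = simulate_cohort(cfg, atlas26, connectome26)
        mets = compute_metrics(vd, atlas26)
        pat, _ = deviation_set({m: mets[m] for m in ("SV", "ReHo", "NS")},
                               subjects, composite=False)
        mean_w = pat.w.mean(axis=(0, 2))
        idx = [atlas26.index_of(r) for r in eff]
        top2 = np.argsort(-mean_w)[:2]
        assert set(top2) == set(idx)
        # displacement roughly matches the designed W magnitude
        assert 1.5 < mean_w[idx].mean() < 4.5

    def test_epicenter_seed_requires_valid_region(self, atlas26, connectome26):
        cfg = SimulationConfig(seed=1, epicenter_seed_region=999, effect_size_w=2.0)
        with pytest.raises(ValueError, match="not in atlas"):
            simulate_cohort(cfg, atlas26, connectome26)

    def test_structural_metrics_carry_coupled_effects(self, atlas26, connectome26):
        eff = tuple(atlas26.region_ids[[4]])
        cfg = SimulationConfig(seed=6, n_sites=1, n_hc_per_site=60,
                               n_tle_per_site=60, n_fcd_per_site=0,
                               effect_regions=eff, effect_size_w=3.0,
                               prop_left_focus=1.0, n_calibration=20,
                               structure_coupling={"CT": 1.0, "FA": 0.0, "MD": 0.0})
        subjects, _, struct, _ = simulate_cohort(cfg, atlas26, connectome26)
        tle = (subjects["group"] == "TLE").to_numpy()
        hc = (subjects["group"] == "HC").to_numpy()
        i = atlas26.index_of(eff[0])
        gap_ct = struct["CT"].values[tle, i].mean() - struct["CT"].values[hc, i].mean()
        gap_fa = struct["FA"].values[tle, i].mean() - struct["FA"].values[hc, i].mean()
        assert gap_ct > 2.0 * 0.12    # ~3 residual SDs in CT
        assert abs(gap_fa) < 0.02     # FA uncoupled


def test_prevalence_monotone_in_effect_size(atlas26, connectome26):
    """Designed-effect monotonicity of extreme-deviation prevalence."""
    eff = tuple(atlas26.region_ids[[3, 10]])
    idx = [atlas26.index_of(r) for r in eff]
    prevs = []
    for w in (0.0, 1.0, 2.0, 3.0):
        cfg = SimulationConfig(seed=21, n_sites=1, n_hc_per_site=60,
                               n_tle_per_site=100, n_fcd_per_site=0,
                               effect_regions=eff, effect_size_w=w,
                               prop_left_focus=1.0, n_calibration=30)
        subjects, vd, _, _ = simulate_cohort(cfg, atlas26, connectome26)
        mets = compute_metrics(vd, atlas26)
        pat, _ = deviation_set({m: mets[m] for m in ("SV", "ReHo", "NS")},
                               subjects, composite=False)
        prev = pat.extreme.mean(axis=(0, 2))
        prevs.append(prev[idx].mean())
    assert prevs == sorted(prevs)
    assert prevs[-1] > prevs[0] + 0.3
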