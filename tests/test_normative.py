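"""Normative regression, W-scores, extreme masks and the multivariate composite."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ndmap.containers import MetricMatrix
from ndmap.normative import (
    NormativeRegression,
    extreme_mask,
    fit_normative,
    multivariate_composite,
    prevalence,
)


def _cohort(rng, n_hc=200, n_pat=50, p=8, slope=0.5, sex_beta=2.0, noise=1.0):
    n = n_hc + n_pat
    subjects = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": ["HC"] * n_hc + ["TLE"] * n_pat,
        "site": "s1",
        "age": rng.uniform(18, 60, n),
        "sex": rng.integers(0, 2, n),
        "focus": ["none"] * n_hc + ["left"] * n_pat,
        "mean_fd": rng.lognormal(np.log(0.15), 0.3, n),
    })
    Y = 10 + slope * subjects["age"].to_numpy()[:, None] \
        + sex_beta * subjects["sex"].to_numpy()[:, None] \
        + noise * rng.normal(size=(n, p))
    m = MetricMatrix("SV", Y, list(subjects["subject_id"]), np.arange(1, p + 1))
    return m, subjects


class TestFit:
    def test_age_slope_recovery(self):
        rng = np.random.default_rng(0)
        m, subjects = _cohort(rng, slope=0.5, noise=1.0)
        res = fit_normative(m, subjects)
        assert np.all(np.abs(res.coef[1] - 0.5) < 0.1)

    def test_zero_noise_exact_recovery(self):
        rng = np.random.default_rng(1)
        m, subjects = _cohort(rng, noise=1e-12)
        res = fit_normative(m, subjects)
        assert np.allclose(res.coef[0], 10, atol=1e-6)
        assert np.allclose(res.coef[1], 0.5, atol=1e-9)
        assert np.allclose(res.coef[2], 2.0, atol=1e-6)

    def test_motion_covariate_variant(self):
        rng = np.random.default_rng(2)
        m, subjects = _cohort(rng)
        res = fit_normative(m, subjects, covariates=["age", "sex", "mean_fd"])
        assert res.coef.shape[0] == 4
        assert "mean_fd" in res.covariates

    def test_degenerate_sex_rejected(self):
        rng = np.random.default_rng(3)
        m, subjects = _cohort(rng)
        subjects["sex"] = 1
        with pytest.raises(ValueError, match="full rank|degenerate"):
            fit_normative(m, subjects)


class TestWScore:
    def test_arithmetic(self):
        rng = np.random.default_rng(4)
        m, subjects = _cohort(rng, n_pat=1)
        res = fit_normative(m, subjects)
        pat = subjects.tail(1).reset_index(drop=True)
        pred = res.predict(pat)
        obs = MetricMatrix("SV", pred + 3.92, ["x"], m.region_ids)
        w = res.w_score(obs, pat)
        assert np.allclose(w, 3.92 / res.residual_sd[None, :])
        obs0 = MetricMatrix("SV", pred.copy(), ["x"], m.region_ids)
        assert np.allclose(res.w_score(obs0, pat), 0.0)

    def test_in_sample_controls_standardized(self):
        rng = np.random.default_rng(5)
        m, subjects = _cohort(rng, n_hc=200, n_pat=0)
        res = fit_normative(m, subjects)
        w = res.w_score(m, subjects)
        assert np.abs(w.mean(axis=0)).max() < 0.05
        assert np.abs(w.std(axis=0) - 1).max() < 0.1

    def test_shift_equivariance(self):
        rng = np.random.default_rng(6)
        m, subjects = _cohort(rng)
        res = fit_normative(m, subjects)
        w1 = res.w_score(m, subjects)
        shifted = MetricMatrix("SV", m.values + 2.5, m.subject_ids, m.region_ids)
        w2 = res.w_score(shifted, subjects)
        assert np.allclose(w2 - w1, 2.5 / res.residual_sd[None, :])


class TestMaskAndPrevalence:
    def test_threshold_boundary_inclusive(self):
        w = np.array([[1.96, -1.959, -1.961, 0.0]])
        assert extreme_mask(w).tolist() == [[True, False, True, False]]

    def test_standard_normal_tail_fraction(self):
        rng = np.random.default_rng(7)
        w = rng.standard_normal((2000, 50))
        frac = extreme_mask(w).mean()
        assert abs(frac - 0.05) < 0.002

    def test_prevalence_ratios(self):
        mask = np.zeros((99, 3), bool)
        mask[:7, 0] = True
        mask[:, 1] = True
        prev, counts = prevalence(mask)
        assert np.allclose(prev, [7 / 99, 1.0, 0.0])
        assert counts[:7].tolist() == [2] * 7


class TestComposite:
    def _controls(self, rng, n=400, p=5, k=3):
        A = rng.normal(size=(k, k))
        cov = A @ A.T + np.eye(k)
        wc = rng.multivariate_normal(np.zeros(k), cov, size=(n, p))
        return wc, cov

    def test_identity_covariance_reduction(self, rng):
        wc = rng.standard_normal((20000, 1, 3))
        wp = np.array([[[1.96, 0.0, 0.0]]])
        D, z = multivariate_composite(wp, wc)
        assert abs(D[0, 0] - 1.96) < 0.05

    def test_center_gives_zero_distance(self, rng):
        wc, _ = self._controls(rng)
        mu = wc.mean(axis=0)
        D, z = multivariate_composite(mu[None], wc)
        assert np.allclose(D, 0.0, atol=1e-8)

    def test_matches_linear_solve_oracle(self, rng):
        wc, _ = self._controls(rng)
        wp = rng.normal(size=(6, 5, 3))
        D, _ = multivariate_composite(wp, wc)
        for s in range(6):
            for r in range(5):
                mu = wc[:, r].mean(axis=0)
                cov = np.cov(wc[:, r], rowvar=False)
                d = wp[s, r] - mu
                ref = np.sqrt(d @ np.linalg.solve(cov, d))
                assert abs(D[s, r] - ref) < 1e-10

    def test_affine_invariance(self, rng):
        wc, _ = self._controls(rng)
        wp = rng.normal(size=(4, 5, 3))
        M = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        D1, _ = multivariate_composite(wp, wc)
        D2, _ = multivariate_composite(wp @ M.T, wc @ M.T)
        assert np.allclose(D1, D2, atol=1e-8)

    def test_singular_covariance_names_region(self, rng):
        wc = np.repeat(rng.normal(size=(300, 2, 1)), 3, axis=2)  # rank-1 metrics
        wp = rng.normal(size=(2, 2, 3))
        with pytest.raises(ValueError, match="region"):
            multivariate_composite(wp, wc)

    def test_signed_z_tail_matches_extreme_rule(self, rng):
        """Under the control distribution |z| >= 1.96 flags ~5%."""
        wc, _ = self._controls(rng, n=3000, p=2)
        _, z = multivariate_composite(wc, wc)
        frac = (np.abs(z) >= 1.96).mean()
        assert abs(frac - 0.05) < 0.02
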