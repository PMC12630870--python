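"""Parametric empirical-Bayes batch harmonization (ComBat).

Removes additive and multiplicative site/scanner effects from a
subjects x regions metric matrix while preserving the variance associated
with designated biological covariates (age, sex, diagnosis).  Per-batch
location (gamma) and scale (delta^2) estimates are shrunk across features
toward method-of-moments priors (normal for gamma, inverse-gamma for
delta^2) via the standard iterative conditional posterior means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MetricMatrix


def _design(subjects: pd.DataFrame, batch_col: str, preserve: list[str]):
    batches = pd.Categorical(subjects[batch_col])
    B = pd.get_dummies(batches).to_numpy(float)           # one-hot batch
    cov_cols = []
    X_cov = []
    for col in preserve:
        v = subjects[col]
        if v.dtype == object or str(v.dtype) == "category":
            d = pd.get_dummies(pd.Categorical(v), drop_first=True)
            for c in d.columns:
                X_cov.append(d[c].to_numpy(float))
                cov_cols.append(f"{col}[{c}]")
        else:
            X_cov.append(v.to_numpy(float))
            cov_cols.append(col)
    X_cov = np.column_stack(X_cov) if X_cov else np.empty((len(subjects), 0))
    return B, X_cov, list(batches.categories), cov_cols


@dataclass
class ComBatResults:
    """Fitted batch model; apply with :meth:`transform`."""

    batch_levels: list
    cov_cols: list
    beta_hat: np.ndarray          # (n_batch + n_cov) x features
    grand_mean: np.ndarray        # per feature
    var_pooled: np.ndarray        # per feature
    gamma_hat: np.ndarray         # batches x features (raw location)
    delta_hat: np.ndarray         # batches x features (raw scale)
    gamma_star: np.ndarray        # EB-shrunk
    delta_star: np.ndarray
    gamma_bar: np.ndarray         # prior means per batch
    t2: np.ndarray                # prior variances per batch
    a_prior: np.ndarray
    b_prior: np.ndarray
    batch_col: str
    preserve: list

    def _standardize(self, values: np.ndarray, subjects: pd.DataFrame):
        B, X_cov, levels, _ = _design(subjects, self.batch_col, self.preserve)
        unknown = set(levels) - set(self.batch_levels)
        if unknown:
            raise ValueError(f"unseen batch labels: {sorted(unknown)}")
        n_b = len(self.batch_levels)
        stand_mean = self.grand_mean[None, :] + X_cov @ self.beta_hat[n_b:]
        sd = np.sqrt(self.var_pooled)[None, :]
        z = (values - stand_mean) / sd
        batch_idx = np.array([self.batch_levels.index(b) for b in subjects[self.batch_col]])
        return z, stand_mean, sd, batch_idx

    def transform(self, m: MetricMatrix, subjects: pd.DataFrame) -> MetricMatrix:
        """Remove batch effects from ``m`` (batches must be seen at fit)."""
        z, stand_mean, sd, bi = self._standardize(m.values, subjects)
        adj = (z - self.gamma_star[bi]) / np.sqrt(self.delta_star[bi])
        out = adj * sd + stand_mean
        return MetricMatrix(m.metric_name, out, m.subject_ids, m.region_ids)


class ComBatModel:
    """Location/scale batch-effect model for one metric matrix.

    Parameters
    ----------
    m : MetricMatrix
        Subjects x regions values (one metric).
    subjects : DataFrame aligned with the rows of ``m``.
    batch_col : column holding the site/scanner label.
    preserve : covariate columns whose variance must be retained
        (numeric, or categorical which are dummy-expanded).
    """

    def __init__(self, m: MetricMatrix, subjects: pd.DataFrame,
                 batch_col: str = "site",
                 preserve: list[str] = ("age", "sex", "group")):
        if len(subjects) != m.n_subjects:
            raise ValueError("subject table does not match metric rows")
        self.m = m
        self.subjects = subjects.reset_index(drop=True)
        self.batch_col = batch_col
        self.preserve = list(preserve)

    def fit(self, eb: bool = True, max_iter: int = 200, tol: float = 1e-6) -> ComBatResults:
        Y = self.m.values
        n, p = Y.shape
        B, X_cov, levels, cov_cols = _design(self.subjects, self.batch_col, self.preserve)
        counts = B.sum(axis=0)
        if (counts < 2).any():
            bad = [levels[i] for i in np.nonzero(counts < 2)[0]]
            raise ValueError(f"singleton batches: {bad}")
        X = np.hstack([B, X_cov])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank-deficient "
                             "(collinear covariates or confounded batch)")
        beta_hat, *_ = np.linalg.lstsq(X, Y, rcond=None)
        n_b = len(levels)
        grand_mean = (counts / n) @ beta_hat[:n_b]
        resid = Y - X @ beta_hat
        var_pooled = (resid ** 2).mean(axis=0)
        if (var_pooled <= 0).any():
            raise ValueError("zero pooled variance for some regions")

        stand_mean = grand_mean[None, :] + X_cov @ beta_hat[n_b:]
        z = (Y - stand_mean) / np.sqrt(var_pooled)[None, :]

        gamma_hat = np.empty((n_b, p))
        delta_hat = np.empty((n_b, p))
        for i in range(n_b):
            zi = z[B[:, i] == 1]
            gamma_hat[i] = zi.mean(axis=0)
            delta_hat[i] = zi.var(axis=0, ddof=1)
        gamma_bar = gamma_hat.mean(axis=1)
        t2 = gamma_hat.var(axis=1, ddof=1)
        m_d = delta_hat.mean(axis=1)
        # guard: delta_hat can be (numerically) constant across features
        s2_d = np.maximum(delta_hat.var(axis=1, ddof=1), 1e-12)
        a_prior = (2 * s2_d + m_d ** 2) / s2_d
        b_prior = (m_d * s2_d + m_d ** 3) / s2_d

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        if eb:
            for i in range(n_b):
                ni = counts[i]
                zi = z[B[:, i] == 1]
                g, d = gamma_hat[i].copy(), delta_hat[i].copy()
                for _ in range(max_iter):
                    g_new = (t2[i] * ni * gamma_hat[i] + d * gamma_bar[i]) / (t2[i] * ni + d)
                    sum2 = ((zi - g_new[None, :]) ** 2).sum(axis=0)
                    d_new = (0.5 * sum2 + b_prior[i]) / (ni / 2.0 + a_prior[i] - 1.0)
                    change = max(np.abs(g_new - g).max() / max(np.abs(g).max(), 1e-12),
                                 np.abs(d_new - d).max() / max(np.abs(d).max(), 1e-12))
                    g, d = g_new, d_new
                    if change < tol:
                        break
                gamma_star[i], delta_star[i] = g, d
        if (delta_star <= 0).any():
            raise ValueError("non-positive shrunk scale estimate")

        return ComBatResults(levels, cov_cols, beta_hat, grand_mean, var_pooled,
                             gamma_hat, delta_hat, gamma_star, delta_star,
                             gamma_bar, t2, a_prior, b_prior,
                             self.batch_col, self.preserve)


def fit_harmonizer(m: MetricMatrix, subjects: pd.DataFrame, batch_col: str = "site",
                   preserve: list[str] = ("age", "sex", "group")) -> ComBatResults:
    return ComBatModel(m, subjects, batch_col, preserve).fit()


def apply_harmonizer(model: ComBatResults, m: MetricMatrix,
                     subjects: pd.DataFrame) -> MetricMatrix:
    return model.transform(m, subjects)


def harmonize(m: MetricMatrix, subjects: pd.DataFrame, batch_col: str = "site",
              preserve: list[str] = ("age", "sex", "group")) -> MetricMatrix:
    """Fit-and-apply convenience wrapper (single metric, all subjects)."""
    model = fit_harmonizer(m, subjects, batch_col, preserve)
    return model.transform(m, subjects)
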