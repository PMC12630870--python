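"""Normative modelling of regional metrics and W-score deviation maps.

A per-region ordinary least squares model is fit on healthy controls,

    value = b0 + b1 * age + b2 * sex (+ extra covariates) + residual,

and any subject's deviation is expressed as a W-score: the residual from
the control model divided by the control residual standard deviation — a
covariate-adjusted z-score with mean 0 and SD 1 in controls.  Regions with
|W| >= 1.96 (the two 2.5% normative tails) are extreme deviations; the
per-region proportion of patients flagged is the prevalence map.  A
multivariate composite aggregates several metrics per region via the
Mahalanobis distance to the control cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .containers import MetricMatrix

EXTREME_THRESHOLD = 1.96


def _design(subjects: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = [np.ones(len(subjects))]
    for c in covariates:
        if c not in subjects.columns:
            raise ValueError(f"missing covariate column {c!r}")
        v = subjects[c].to_numpy(float)
        if np.isnan(v).any():
            raise ValueError(f"covariate {c!r} has missing values")
        cols.append(v)
    return np.column_stack(cols)


class NormativeRegression:
    """Per-region normative model, fit on the control rows of a metric.

    Parameters
    ----------
    m : MetricMatrix for all subjects.
    subjects : aligned subject table; rows with ``group == "HC"`` form the
        reference sample.
    covariates : columns of the linear predictor (default age and sex;
        add ``mean_fd`` for the head-motion sensitivity variant).
    """

    def __init__(self, m: MetricMatrix, subjects: pd.DataFrame,
                 covariates: list[str] = ("age", "sex")):
        if len(subjects) != m.n_subjects:
            raise ValueError("subject table does not match metric rows")
        self.m = m
        self.subjects = subjects.reset_index(drop=True)
        self.covariates = list(covariates)

    def fit(self) -> "NormativeResults":
        hc = (self.subjects["group"] == "HC").to_numpy()
        if hc.sum() < 10:
            raise ValueError("need at least 10 controls")
        X = _design(self.subjects[hc], self.covariates)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("degenerate covariates (design not full rank)")
        Y = self.m.values[hc]
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        dof = X.shape[0] - X.shape[1]
        residual_sd = np.sqrt((resid ** 2).sum(axis=0) / dof)
        if (residual_sd <= 0).any():
            raise ValueError("zero residual variance for some regions")
        return NormativeResults(self.m.metric_name, self.covariates, coef,
                                residual_sd, int(hc.sum()), self.m.region_ids)


@dataclass
class NormativeResults:
    """Fitted coefficients and control residual scale, per region."""

    metric_name: str
    covariates: list
    coef: np.ndarray          # (1 + n_cov) x regions; row 0 = intercept
    residual_sd: np.ndarray
    n_controls: int
    region_ids: np.ndarray

    def predict(self, subjects: pd.DataFrame) -> np.ndarray:
        X = _design(subjects, self.covariates)
        return X @ self.coef

    def w_score(self, m: MetricMatrix, subjects: pd.DataFrame) -> np.ndarray:
        """W = (observed - predicted) / control residual SD, per region."""
        if len(subjects) != m.n_subjects:
            raise ValueError("subject table does not match metric rows")
        return (m.values - self.predict(subjects)) / self.residual_sd[None, :]

    def summary(self) -> pd.DataFrame:
        rows = {"region_id": self.region_ids, "intercept": self.coef[0]}
        for i, c in enumerate(self.covariates):
            rows[f"beta_{c}"] = self.coef[1 + i]
        rows["residual_sd"] = self.residual_sd
        return pd.DataFrame(rows)


def fit_normative(m: MetricMatrix, subjects: pd.DataFrame,
                  covariates: list[str] = ("age", "sex")) -> NormativeResults:
    return NormativeRegression(m, subjects, covariates).fit()


def extreme_mask(w: np.ndarray, threshold: float = EXTREME_THRESHOLD) -> np.ndarray:
    """Boolean mask of extreme deviations, |W| >= threshold (inclusive)."""
    w = np.asarray(w, float)
    if not np.isfinite(w).all():
        raise ValueError("W scores must be finite")
    return np.abs(w) >= threshold


def prevalence(mask: np.ndarray):
    """Per-region proportion of flagged patients, plus per-patient counts."""
    mask = np.asarray(mask, bool)
    if mask.ndim != 2 or mask.shape[0] < 1:
        raise ValueError("need a patients x regions mask")
    return mask.mean(axis=0), mask.sum(axis=1)


def multivariate_composite(w_patients: np.ndarray, w_controls: np.ndarray):
    """Signed multivariate deviation per (subject, region).

    ``w_*`` are subjects x regions x metrics stacks of W-scores.  For each
    region the Mahalanobis distance D of a subject's metric vector to the
    control cloud is computed; D^2 is mapped through the chi-square CDF
    (df = n_metrics) and the standard-normal quantile to a z-equivalent,
    signed by the mean W over metrics so the usual |z| >= 1.96 rule
    applies.  Returns ``(D, signed_z)``.
    """
    wp = np.asarray(w_patients, float)
    wc = np.asarray(w_controls, float)
    if wp.ndim != 3 or wc.ndim != 3 or wp.shape[1:] != wc.shape[1:]:
        raise ValueError("expected subjects x regions x metrics stacks")
    n_sub, n_reg, k = wp.shape
    D = np.empty((n_sub, n_reg))
    for r in range(n_reg):
        mu = wc[:, r, :].mean(axis=0)
        cov = np.cov(wc[:, r, :], rowvar=False)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(f"singular metric covariance in region index {r}")
        d = wp[:, r, :] - mu
        sol = np.linalg.solve(L, d.T)
        D[:, r] = np.sqrt((sol ** 2).sum(axis=0))
    cdf = stats.chi2.cdf(D ** 2, df=k)
    # upper tail via sf for numerical accuracy at large D
    z = np.where(cdf < 0.5, ndtri(np.clip(cdf, 1e-300, 1.0)),
                 -ndtri(np.clip(stats.chi2.sf(D ** 2, df=k), 1e-300, 1.0)))
    signed = np.abs(z) * np.sign(wp.mean(axis=2))
    return D, signed


@dataclass
class DeviationSet:
    """W-scores, extreme masks and prevalence for one cohort of patients."""

    metrics: list
    w: np.ndarray                 # subjects x regions x metrics
    threshold: float
    region_ids: np.ndarray
    subject_ids: list
    composite_d: np.ndarray | None = None
    composite_z: np.ndarray | None = None

    @property
    def extreme(self) -> np.ndarray:
        return extreme_mask(self.w, self.threshold)

    def prevalence_map(self, metric: str) -> np.ndarray:
        j = self.metrics.index(metric)
        return self.extreme[:, :, j].mean(axis=0)

    def deviation_counts(self) -> np.ndarray:
        """Number of extreme (region, metric) deviations per patient."""
        return self.extreme.reshape(len(self.subject_ids), -1).sum(axis=1)

    def composite_prevalence_map(self) -> np.ndarray:
        if self.composite_z is None:
            raise ValueError("composite not computed")
        return (np.abs(self.composite_z) >= self.threshold).mean(axis=0)


def deviation_set(metric_matrices: dict[str, MetricMatrix], subjects: pd.DataFrame,
                  covariates: list[str] = ("age", "sex"),
                  patient_mask: np.ndarray | None = None,
                  threshold: float = EXTREME_THRESHOLD,
                  composite: bool = True) -> tuple[DeviationSet, DeviationSet]:
    """Fit normative models on controls and score patients and controls.

    Returns ``(patients, controls)`` DeviationSets over the given metrics
    (the control set carries in-sample W-scores from the same fit).
    """
    metrics = list(metric_matrices)
    first = metric_matrices[metrics[0]]
    subjects = subjects.reset_index(drop=True)
    hc = (subjects["group"] == "HC").to_numpy()
    if patient_mask is None:
        patient_mask = (subjects["group"] == "TLE").to_numpy()
    w_all = []
    for name in metrics:
        res = fit_normative(metric_matrices[name], subjects, covariates)
        w_all.append(res.w_score(metric_matrices[name], subjects))
    w_all = np.stack(w_all, axis=2)
    wp, wc = w_all[patient_mask], w_all[hc]
    pat_ids = [s for s, m in zip(first.subject_ids, patient_mask) if m]
    hc_ids = [s for s, m in zip(first.subject_ids, hc) if m]
    pat = DeviationSet(metrics, wp, threshold, first.region_ids, pat_ids)
    ctl = DeviationSet(metrics, wc, threshold, first.region_ids, hc_ids)
    if composite and len(metrics) >= 2:
        pat.composite_d, pat.composite_z = multivariate_composite(wp, wc)
        ctl.composite_d, ctl.composite_z = multivariate_composite(wc, wc)
    return pat, ctl
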