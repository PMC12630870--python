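"""Clinical utility of individual deviation scores.

Diagnosis, seizure-focus lateralization and surgical-outcome tasks are
evaluated with a linear support vector machine in a stratified nested
5-fold cross-validation: an inner 5-fold grid search selects the cost
parameter c on the training folds only, the model is refit on the full
training folds, and decision values pooled over the outer test folds give
one AUC per outer iteration.  Significance comes from label-permutation
nulls.  Interhemispheric (ipsi vs contra) deviation load is contrasted
with one-sided paired t-tests under Benjamini-Hochberg FDR correction,
and deviation counts are related to clinical course variables with
bivariate correlations and Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

DEFAULT_COST_GRID = tuple(2.0 ** k for k in range(-5, 6))


@dataclass
class ClassifierSpec:
    """Nested-CV configuration for the linear-margin classifier."""

    cost_grid: tuple = DEFAULT_COST_GRID
    n_outer_folds: int = 5
    n_inner_folds: int = 5
    n_outer_iterations: int = 100
    seed: int = 0


@dataclass
class EvalResult:
    auc_point: float              # median AUC over outer iterations
    auc_interval: tuple           # (2.5th, 97.5th percentile)
    aucs: np.ndarray
    p_perm: float | None = None
    fold_audit: list = field(default_factory=list)

    def summary(self) -> dict:
        return {"auc_median": self.auc_point,
                "auc_ci": list(self.auc_interval),
                "p_perm": self.p_perm,
                "n_iterations": int(len(self.aucs))}


def _fit_decision(Xtr, ytr, Xte, c):
    import warnings

    scaler = StandardScaler().fit(Xtr)
    clf = LinearSVC(C=c, loss="hinge", max_iter=5000, tol=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # convergence warnings at large C
        clf.fit(scaler.transform(Xtr), ytr)
    return clf.decision_function(scaler.transform(Xte))


def _one_iteration(X, y, spec: ClassifierSpec, rng: np.random.Generator, audit: list | None):
    outer = StratifiedKFold(spec.n_outer_folds, shuffle=True,
                            random_state=int(rng.integers(2 ** 31)))
    dec = np.empty(len(y))
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        Xtr, ytr = X[tr], y[tr]
        best_c, best_auc = spec.cost_grid[0], -np.inf
        inner = StratifiedKFold(spec.n_inner_folds, shuffle=True,
                                random_state=int(rng.integers(2 ** 31)))
        inner_splits = list(inner.split(Xtr, ytr))
        for c in spec.cost_grid:
            scores = []
            for itr, ite in inner_splits:
                d = _fit_decision(Xtr[itr], ytr[itr], Xtr[ite], c)
                scores.append(roc_auc_score(ytr[ite], d))
            score = float(np.mean(scores))
            if score > best_auc:
                best_auc, best_c = score, c
        dec[te] = _fit_decision(Xtr, ytr, X[te], best_c)
        if audit is not None:
            audit.append({"fold": fold, "train_idx": tr.tolist(),
                          "test_idx": te.tolist(), "chosen_c": best_c,
                          "decision_values": dec[te].tolist()})
    return roc_auc_score(y, dec)


def nested_cv_classify(features: np.ndarray, labels: np.ndarray,
                       spec: ClassifierSpec | None = None) -> EvalResult:
    """Median AUC (with percentile interval) over repeated nested CV."""
    spec = spec or ClassifierSpec()
    X = np.asarray(features, float)
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < 10:
        raise ValueError("need at least 10 subjects per class")
    rng = np.random.default_rng(spec.seed)
    audit: list = []
    aucs = np.array([
        _one_iteration(X, y, spec, rng, audit if it == 0 else None)
        for it in range(spec.n_outer_iterations)
    ])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return EvalResult(float(np.median(aucs)), (float(lo), float(hi)), aucs,
                      fold_audit=audit)


def permutation_pvalue(result: EvalResult, features, labels,
                       spec: ClassifierSpec | None = None, n_perm: int = 1000,
                       null_iterations: int = 5, seed: int = 0) -> float:
    """Fraction of permuted-label AUCs at or above the observed AUC.

    Null replicates rerun the full nested pipeline with shuffled labels
    (with a reduced number of outer iterations, recorded in the spec).
    """
    spec = spec or ClassifierSpec()
    rng = np.random.default_rng(seed)
    y = np.asarray(labels).astype(int)
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(y))
        null_spec = ClassifierSpec(spec.cost_grid, spec.n_outer_folds,
                                   spec.n_inner_folds, null_iterations,
                                   seed=int(rng.integers(2 ** 31)))
        res = nested_cv_classify(features, y[perm], null_spec)
        nulls[b] = res.auc_point
    p = float((1 + (nulls >= result.auc_point).sum()) / (1 + n_perm))
    result.p_perm = p
    return p


# ---------------------------------------------------------------------------
# Interhemispheric contrasts and clinical associations
# ---------------------------------------------------------------------------

def interhemispheric_contrast(ipsi: pd.DataFrame, contra: pd.DataFrame,
                              subgroups: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided paired t-tests of ipsi - contra deviation load per lobe.

    ``ipsi``/``contra`` are patients x lobes proportions of extreme
    deviations; ``subgroups`` labels each patient (e.g. seizure-free vs
    non-seizure-free).  Positive t means more ipsilateral deviations; the
    one-sided p tests that direction.  BH-FDR is applied across lobes
    within each subgroup.
    """
    if not ipsi.columns.equals(contra.columns):
        raise ValueError("ipsi and contra lobe columns differ")
    rows = []
    for grp in pd.unique(subgroups):
        sel = (subgroups == grp).to_numpy()
        if sel.sum() < 3:
            raise ValueError(f"subgroup {grp!r} has fewer than 3 patients")
        pvals, stats_ = [], []
        for lobe in ipsi.columns:
            d = ipsi.loc[sel, lobe].to_numpy(float) - contra.loc[sel, lobe].to_numpy(float)
            if np.allclose(d.std(ddof=1), 0):
                raise ValueError(f"zero-variance differences for lobe {lobe!r}")
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            p = float(stats.t.sf(t, df=len(d) - 1))
            stats_.append(t)
            pvals.append(p)
        rej, p_fdr, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for lobe, t, p, pf, rj in zip(ipsi.columns, stats_, pvals, p_fdr, rej):
            rows.append({"subgroup": grp, "lobe": lobe, "t": float(t),
                         "p": p, "p_fdr": float(pf), "significant": bool(rj)})
    return pd.DataFrame(rows)


def clinical_associations(counts: np.ndarray, subjects: pd.DataFrame) -> pd.DataFrame:
    """Bivariate associations of per-patient deviation counts with
    disease-course variables, plus a Welch t-test over the FBTCS split."""
    counts = np.asarray(counts, float)
    rows = []
    for var in ("duration", "onset_age", "n_asm"):
        if var not in subjects.columns:
            continue
        v = subjects[var].to_numpy(float)
        ok = np.isfinite(v)
        if np.ptp(v[ok]) == 0:
            raise ValueError(f"variable {var!r} is constant")
        r, p_r = stats.pearsonr(counts[ok], v[ok])
        rho, p_rho = stats.spearmanr(counts[ok], v[ok])
        rows.append({"variable": var, "test": "correlation", "pearson_r": float(r),
                     "p_pearson": float(p_r), "spearman_rho": float(rho),
                     "p_spearman": float(p_rho), "t": np.nan, "p_t": np.nan})
    if "fbtcs" in subjects.columns:
        fb = subjects["fbtcs"].astype(bool).to_numpy()
        if 0 < fb.sum() < len(fb):
            t, p = stats.ttest_ind(counts[fb], counts[~fb], equal_var=False)
            rows.append({"variable": "fbtcs", "test": "welch_t", "pearson_r": np.nan,
                         "p_pearson": np.nan, "spearman_rho": np.nan,
                         "p_spearman": np.nan, "t": float(t), "p_t": float(p)})
    return pd.DataFrame(rows)


def lobe_loads(mask: np.ndarray, atlas, lateralized: bool = True):
    """Per-patient proportion of flagged regions per (lobe, ipsi/contra).

    ``mask`` is patients x regions booleans already lateralized so left =
    ipsilateral.  Returns ``(ipsi, contra)`` DataFrames over cortical
    lobes plus subcortex.
    """
    t = atlas.table
    ipsi_cols, contra_cols = {}, {}
    for lobe in pd.unique(t["lobe"]):
        li = ((t["lobe"] == lobe) & (t["hemisphere"] == "left")).to_numpy()
        ri = ((t["lobe"] == lobe) & (t["hemisphere"] == "right")).to_numpy()
        if li.sum() == 0 or ri.sum() == 0:
            continue
        ipsi_cols[lobe] = mask[:, li].mean(axis=1)
        contra_cols[lobe] = mask[:, ri].mean(axis=1)
    return pd.DataFrame(ipsi_cols), pd.DataFrame(contra_cols)
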