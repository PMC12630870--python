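"""Structure-function coupling of deviation prevalence maps.

A multilinear model predicts the functional deviation prevalence map from
the structural (CT, FA, MD) deviation prevalence maps,

    y = b0 + b1*CT + b2*FA + b3*MD,

with fit quantified by the adjusted R^2 and spatial significance of the
empirical-vs-predicted Spearman correlation assessed by spinning y.
Dominance analysis decomposes the explained variance into per-predictor
general-dominance shares by averaging incremental fit gains over all
2^k - 1 predictor subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr

from .network import SpinNull, _perm_pvalue


def _r2(y: np.ndarray, X: np.ndarray, adjusted: bool = False) -> float:
    res = sm.OLS(y, sm.add_constant(X)).fit()
    return float(res.rsquared_adj if adjusted else res.rsquared)


def dominance_analysis(y: np.ndarray, X: np.ndarray, adjusted: bool = False):
    """General dominance of each predictor.

    Fits every non-empty predictor subset; the general dominance of
    predictor j is the mean (over model sizes s) of the mean incremental
    fit gain from adding j to size-s subsets lacking j (s = 0..k-1).
    With ``adjusted=False`` the currency is plain R^2, whose general
    dominances are nonnegative and sum exactly to the full-model R^2.

    Returns ``(dominance, shares)``; shares are normalised by total fit.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    k = X.shape[1]
    if k > 10:
        raise ValueError("dominance analysis limited to 10 predictors")
    fit: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, k + 1):
        for subset in combinations(range(k), size):
            fit[frozenset(subset)] = _r2(y, X[:, list(subset)], adjusted)
    dominance = np.zeros(k)
    for j in range(k):
        per_size = []
        for size in range(0, k):
            gains = [fit[frozenset(sub) | {j}] - fit[frozenset(sub)]
                     for sub in combinations([i for i in range(k) if i != j], size)]
            per_size.append(np.mean(gains))
        dominance[j] = np.mean(per_size)
    total = fit[frozenset(range(k))]
    shares = dominance / total if total > 0 else np.full(k, np.nan)
    return dominance, shares


@dataclass
class CouplingResults:
    """Fitted structure-function coupling model."""

    predictor_names: list
    params: np.ndarray            # intercept followed by slopes
    rsquared: float
    rsquared_adj: float
    predicted: np.ndarray
    rho: float                    # Spearman(empirical, predicted)
    p_spin: float | None
    dominance: np.ndarray
    dominance_shares: np.ndarray

    def summary(self) -> pd.DataFrame:
        rows = [{"term": "intercept", "coef": self.params[0],
                 "dominance": np.nan, "share": np.nan}]
        for i, name in enumerate(self.predictor_names):
            rows.append({"term": name, "coef": self.params[1 + i],
                         "dominance": self.dominance[i],
                         "share": self.dominance_shares[i]})
        return pd.DataFrame(rows)


class StructureFunctionCoupling:
    """OLS model of a functional map on structural predictor maps.

    Parameters
    ----------
    y : functional deviation prevalence map (per region).
    X : DataFrame (regions x predictors) or array of structural maps.
    """

    def __init__(self, y: np.ndarray, X):
        self.y = np.asarray(y, float)
        if isinstance(X, pd.DataFrame):
            self.names = list(X.columns)
            self.X = X.to_numpy(float)
        else:
            self.X = np.asarray(X, float)
            self.names = [f"x{i}" for i in range(self.X.shape[1])]
        if self.y.size <= 5:
            raise ValueError("need more than 5 regions")
        if self.X.shape[0] != self.y.size:
            raise ValueError("predictor maps do not match y")
        if np.linalg.matrix_rank(np.column_stack([np.ones(self.y.size), self.X])) \
                < self.X.shape[1] + 1:
            raise ValueError("collinear predictors")

    def fit(self, null: SpinNull | None = None, adjusted_dominance: bool = False,
            n_dominance: bool = True) -> CouplingResults:
        res = sm.OLS(self.y, sm.add_constant(self.X)).fit()
        predicted = np.asarray(res.fittedvalues)
        rho = spearmanr(self.y, predicted).statistic
        p_spin = None
        if null is not None:
            null_maps = null.apply(self.y)
            Xc = sm.add_constant(self.X)
            beta = np.linalg.lstsq(Xc, null_maps.T, rcond=None)[0]
            null_pred = (Xc @ beta).T
            null_rho = np.array([spearmanr(ym, pm).statistic
                                 for ym, pm in zip(null_maps, null_pred)])
            p_spin = _perm_pvalue(rho, null_rho)
        dom, shares = dominance_analysis(self.y, self.X, adjusted=adjusted_dominance)
        return CouplingResults(self.names, np.asarray(res.params),
                               float(res.rsquared), float(res.rsquared_adj),
                               predicted, float(rho), p_spin, dom, shares)


def fit_coupling(y, X, null: SpinNull | None = None, **kw) -> CouplingResults:
    return StructureFunctionCoupling(y, X).fit(null=null, **kw)
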