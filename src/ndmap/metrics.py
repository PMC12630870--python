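"""Multiscale resting-state fMRI metrics.

Three node-level metrics index function at increasing spatial scale:

* **SV** (signal variability) — successive-difference fluctuation of a
  region's mean BOLD series, ``sqrt(sum((x[i+1]-x[i])^2)) / (T-1)``.
* **ReHo** (regional homogeneity) — Kendall's coefficient of concordance
  among a vertex and its within-region neighbours, averaged per region.
* **NS** (node strength) — signed sum of a region's Pearson functional
  connectivity to all other regions, with a short-/long-range split at a
  Euclidean centroid distance cutoff (75 mm by default).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata

from .atlas import Atlas
from .containers import MetricMatrix, VertexData

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_MM = 75.0


def signal_variability(x: np.ndarray, variant: str = "printed") -> float:
    """Successive-difference signal variability of one time series.

    ``variant="printed"`` divides the root summed squared successive
    difference by (T-1); ``variant="rmssd"`` is the textbook root *mean*
    squared successive difference, ``sqrt(mean(diff^2))``.
    """
    x = np.asarray(x, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D series with at least 2 time points")
    if np.isnan(x).any():
        raise ValueError("series contains NaN")
    d2 = np.diff(x) ** 2
    if variant == "printed":
        return float(np.sqrt(d2.sum()) / (x.size - 1))
    if variant == "rmssd":
        return float(np.sqrt(d2.mean()))
    raise ValueError(f"unknown SV variant {variant!r}")


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance W for K series over T time points.

    Each series is ranked over time (midranks for ties); with rank sums
    R_i over the K series at time point i,

        W = 12 * (sum R_i^2 - T * Rbar^2) / (K^2 * (T^3 - T))

    Rbar is computed empirically from the R_i, which equals K(T+1)/2 when
    no ties are present.  Constant series are rejected: their ranking is
    arbitrary and W would be undefined up to tie handling.
    """
    X = np.asarray(series, float)
    if X.ndim != 2:
        raise ValueError("expected K x T array")
    K, T = X.shape
    if K < 2 or T < 2:
        raise ValueError("need K >= 2 series and T >= 2 time points")
    if np.isnan(X).any():
        raise ValueError("series contain NaN")
    if (X.max(axis=1) - X.min(axis=1) == 0).any():
        raise ValueError("constant series: concordance undefined")
    ranks = rankdata(X, axis=1)
    R = ranks.sum(axis=0)
    Rbar = R.mean()
    W = 12.0 * (np.sum(R ** 2) - T * Rbar ** 2) / (K ** 2 * (T ** 3 - T))
    return float(W)


regional_homogeneity = kendall_w


def region_timeseries(vd: VertexData, atlas: Atlas) -> np.ndarray:
    """Regions x T matrix of mean member-vertex series in atlas order."""
    out = np.empty((atlas.n_regions, vd.T))
    for i, rid in enumerate(atlas.region_ids):
        members = np.nonzero(vd.vertex_region == rid)[0]
        if members.size == 0:
            raise ValueError(f"region {rid} has no vertices")
        out[i] = vd.timeseries[members].mean(axis=0)
    return out


def sv_map(vd: VertexData, atlas: Atlas, variant: str = "printed") -> np.ndarray:
    """Per-region SV of the region-mean time series."""
    rts = region_timeseries(vd, atlas)
    return np.array([signal_variability(row, variant=variant) for row in rts])


def reho_map(vd: VertexData, atlas: Atlas) -> np.ndarray:
    """Per-region mean of vertex-wise ReHo over within-region neighbourhoods.

    Each vertex's neighbourhood is the vertex plus its adjacent vertices
    restricted to the same region; vertices left without any same-region
    neighbour are excluded with a logged warning.
    """
    vertex_w = np.full(vd.n_vertices, np.nan)
    for v in range(vd.n_vertices):
        nbrs = [u for u in vd.vertex_neighbors[v] if vd.vertex_region[u] == vd.vertex_region[v]]
        if not nbrs:
            logger.warning("vertex %d has no same-region neighbours; excluded from ReHo", v)
            continue
        vertex_w[v] = kendall_w(vd.timeseries[[v] + nbrs])
    out = np.empty(atlas.n_regions)
    for i, rid in enumerate(atlas.region_ids):
        members = np.nonzero(vd.vertex_region == rid)[0]
        vals = vertex_w[members]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"region {rid} has no vertices with defined ReHo")
        out[i] = vals.mean()
    return out


def node_strength(rts: np.ndarray, atlas: Atlas, range_: str = "full",
                  cutoff_mm: float = DEFAULT_CUTOFF_MM) -> np.ndarray:
    """Signed sum of Pearson FC from each region to all others.

    ``range_`` restricts the sum to region pairs whose centroid Euclidean
    distance is at most (``short``) or beyond (``long``) ``cutoff_mm``;
    ``full`` sums over every pair.  By construction
    ``NS_short + NS_long == NS_full`` exactly.
    """
    rts = np.asarray(rts, float)
    sd = rts.std(axis=1)
    if (sd == 0).any():
        bad = atlas.region_ids[sd == 0]
        raise ValueError(f"zero-variance series for regions {bad.tolist()}")
    fc = np.corrcoef(rts)
    np.fill_diagonal(fc, 0.0)
    if range_ == "full":
        mask = np.ones_like(fc, bool)
    else:
        c = atlas.centroids
        dist = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        if range_ == "short":
            mask = dist <= cutoff_mm
        elif range_ == "long":
            mask = dist > cutoff_mm
        else:
            raise ValueError(f"unknown range {range_!r}")
    np.fill_diagonal(mask, False)
    return (fc * mask).sum(axis=1)


def global_signal_regress(vd: VertexData) -> VertexData:
    """Regress the global mean signal out of every vertex series (GSR variant)."""
    g = vd.timeseries.mean(axis=0)
    g = g - g.mean()
    denom = float(g @ g)
    if denom == 0:
        raise ValueError("global signal is constant")
    X = vd.timeseries - vd.timeseries.mean(axis=1, keepdims=True)
    beta = (X @ g) / denom
    resid = vd.timeseries - beta[:, None] * g[None, :]
    return VertexData(resid, vd.vertex_region, vd.vertex_neighbors)


def compute_metrics(vertex_data: dict[str, VertexData], atlas: Atlas,
                    cutoff_mm: float = DEFAULT_CUTOFF_MM,
                    sv_variant: str = "printed") -> dict[str, MetricMatrix]:
    """All functional metrics for a cohort of subjects.

    Returns MetricMatrix objects for SV, ReHo, NS, NS_short and NS_long in
    the canonical atlas order.
    """
    subject_ids = list(vertex_data)
    maps: dict[str, list[np.ndarray]] = {m: [] for m in ("SV", "ReHo", "NS", "NS_short", "NS_long")}
    for sid in subject_ids:
        vd = vertex_data[sid]
        rts = region_timeseries(vd, atlas)
        maps["SV"].append(sv_map(vd, atlas, variant=sv_variant))
        maps["ReHo"].append(reho_map(vd, atlas))
        maps["NS"].append(node_strength(rts, atlas, "full", cutoff_mm))
        maps["NS_short"].append(node_strength(rts, atlas, "short", cutoff_mm))
        maps["NS_long"].append(node_strength(rts, atlas, "long", cutoff_mm))
    return {m: MetricMatrix(m, np.vstack(v), subject_ids, atlas.region_ids)
            for m, v in maps.items()}
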