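"""Connectome-constrained analyses of deviation maps.

* neighborhood deviation: degree-normalised, connectivity-weighted mean of
  the prevalence of each region's structurally connected neighbours,
  ``pbar_i = (1/N_i) * sum_j p_j * C_ij`` over the N_i nonzero neighbours;
* spin permutation nulls for cortical maps: random 3-D rotations of the
  hemispheric sphere coordinates (mirrored across hemispheres), with a
  greedy one-to-one nearest-centroid reassignment so every null map is a
  true permutation of the original values;
* label-shuffle nulls for subcortical maps;
* epicenter likelihood: Spearman correlation between each region's
  structural connectivity profile and the group prevalence map, ranked
  among spin-significant regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr, special_ortho_group

from .atlas import Atlas
from .containers import Connectome

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 5000


def neighborhood_deviation(p: np.ndarray, sc: Connectome,
                           normalize: str = "degree") -> np.ndarray:
    """Collective neighbour prevalence per region.

    ``normalize="degree"`` divides the connectivity-weighted sum by the
    number of connected neighbours (node degree), as printed;
    ``normalize="weights"`` divides by the summed weights instead (a true
    weighted mean).  Regions without neighbours get NaN with a warning.
    """
    p = np.asarray(p, float)
    W = sc.weights
    if p.shape[0] != W.shape[0]:
        raise ValueError("prevalence map and connectome sizes differ")
    if not (W > 0).any():
        raise ValueError("connectome has no edges")
    deg = (W > 0).sum(axis=1).astype(float)
    if normalize == "degree":
        denom = deg
    elif normalize == "weights":
        denom = W.sum(axis=1)
    else:
        raise ValueError(f"unknown normalize {normalize!r}")
    out = np.full(p.shape[0], np.nan)
    ok = deg > 0
    if not ok.all():
        logger.warning("%d regions have no structural neighbours; excluded",
                       int((~ok).sum()))
    out[ok] = (W @ p)[ok] / denom[ok]
    return out


# ---------------------------------------------------------------------------
# Permutation nulls
# ---------------------------------------------------------------------------

def _greedy_assign(dist: np.ndarray) -> np.ndarray:
    """One-to-one assignment rotated->original, closest pairs first.

    Returns ``perm`` with ``perm[i] = j``: rotated region i takes the value
    originally at region j.
    """
    n = dist.shape[0]
    order = np.argsort(dist, axis=None)
    perm = np.full(n, -1)
    used_row = np.zeros(n, bool)
    used_col = np.zeros(n, bool)
    filled = 0
    for k in order:
        i, j = divmod(int(k), n)
        if used_row[i] or used_col[j]:
            continue
        perm[i] = j
        used_row[i] = used_col[j] = True
        filled += 1
        if filled == n:
            break
    return perm


@dataclass
class SpinNull:
    """Hemisphere-restricted spin permutations of cortical regions.

    ``perms[it, i]`` gives, for every region position i in the atlas, the
    position whose original value region i takes in iteration ``it``
    (identity for subcortical positions unless shuffled separately).
    """

    perms: np.ndarray
    n_iter: int
    seed: int

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Null maps, shape (n_iter, n_regions)."""
        values = np.asarray(values, float)
        return values[self.perms]


def spin_permute(atlas: Atlas, n_iter: int = DEFAULT_N_ITER, seed: int = 0,
                 shuffle_subcortex: bool = True) -> SpinNull:
    """Spatial-autocorrelation-preserving permutations of the atlas regions.

    Per iteration a uniformly random rotation is applied to the left-
    hemisphere sphere coordinates and its x-mirror to the right, and each
    rotated region is greedily matched to the nearest original centroid
    one-to-one within its hemisphere.  Subcortical regions (no sphere
    coordinates) are uniformly shuffled within hemisphere-agnostic blocks,
    or left fixed if ``shuffle_subcortex`` is false.
    """
    rng = np.random.default_rng(seed)
    cort = atlas.cortical_mask
    left = atlas.hemisphere_mask("left") & cort
    right = atlas.hemisphere_mask("right") & cort
    mid = cort & ~left & ~right
    if mid.any():
        raise ValueError("midline cortical regions are not spinnable")
    sph = atlas.sphere_coords
    if np.isnan(sph[cort]).any():
        raise ValueError("cortical regions lack sphere coordinates")
    idx_l, idx_r = np.nonzero(left)[0], np.nonzero(right)[0]
    sub = np.nonzero(~cort)[0]
    mirror = np.diag([-1.0, 1.0, 1.0])

    n = atlas.n_regions
    perms = np.tile(np.arange(n), (n_iter, 1))
    for it in range(n_iter):
        rot = special_ortho_group.rvs(3, random_state=rng)
        rot_r = mirror @ rot @ mirror
        for idx, Rm in ((idx_l, rot), (idx_r, rot_r)):
            pts = sph[idx]
            rotated = pts @ Rm.T
            dist = np.linalg.norm(rotated[:, None] - pts[None, :], axis=-1)
            perms[it, idx] = idx[_greedy_assign(dist)]
        if shuffle_subcortex and sub.size:
            perms[it, sub] = rng.permutation(sub)
    return SpinNull(perms, n_iter, seed)


def shuffle_permute(n_regions: int, n_iter: int = DEFAULT_N_ITER, seed: int = 0) -> SpinNull:
    """Uniform label permutations (for subcortical-only maps)."""
    if n_regions < 3:
        raise ValueError("need at least 3 regions for shuffle nulls")
    rng = np.random.default_rng(seed)
    perms = np.vstack([rng.permutation(n_regions) for _ in range(n_iter)])
    return SpinNull(perms, n_iter, seed)


def _perm_pvalue(observed: float, nulls: np.ndarray) -> float:
    """One-sided (1 + #{null >= obs}) / (1 + n) permutation p-value."""
    nulls = nulls[np.isfinite(nulls)]
    return float((1 + (nulls >= observed).sum()) / (1 + len(nulls)))


def _spearman_rows(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of A with b (midranks)."""
    ra = rankdata(A, axis=1)
    rb = rankdata(b)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean()
    num = ra @ rb
    den = np.sqrt((ra ** 2).sum(axis=1) * (rb ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def node_vs_neighbor_coupling(p: np.ndarray, sc: Connectome, null: SpinNull,
                              normalize: str = "degree"):
    """Spearman coupling between a deviation map and its neighbourhood
    estimate, with a spin-permutation p-value.

    Null maps are built by permuting ``p`` and recomputing the neighbour
    estimate against the fixed connectome.
    """
    p = np.asarray(p, float)
    if p.size < 10:
        raise ValueError("need at least 10 regions")
    if np.ptp(p) == 0:
        raise ValueError("constant map: correlation undefined")
    pbar = neighborhood_deviation(p, sc, normalize)
    ok = np.isfinite(pbar)
    rho = spearmanr(p[ok], pbar[ok]).statistic
    null_maps = null.apply(p)
    null_pbar = (sc.weights @ null_maps.T).T
    deg = (sc.weights > 0).sum(axis=1).astype(float)
    denom = deg if normalize == "degree" else sc.weights.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        null_pbar = null_pbar / denom[None, :]
    null_rho = np.array([
        spearmanr(nm[ok], nb[ok]).statistic for nm, nb in zip(null_maps, null_pbar)
    ])
    return rho, _perm_pvalue(rho, null_rho), pbar


def spatial_correlation(a: np.ndarray, b: np.ndarray, null: SpinNull):
    """Spearman correlation of two region maps with a permutation p-value.

    The null permutes ``a`` (spin for cortex / shuffle for subcortex, as
    encoded in ``null``) against the fixed map ``b``.  Used e.g. to relate a
    prevalence map to a surgical-cavity overlap map or to a sensitivity-
    variant map.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    rho = spearmanr(a, b).statistic
    null_rho = _spearman_rows(null.apply(a), b)
    return float(rho), _perm_pvalue(rho, null_rho)


@dataclass
class EpicenterResult:
    region_ids: np.ndarray
    likelihood: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    rank: np.ndarray          # 1 = strongest significant epicenter; 0 = n.s.

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "region_id": self.region_ids, "likelihood": self.likelihood,
            "p": self.p_value, "significant": self.significant, "rank": self.rank,
        })


def epicenter_map(p: np.ndarray, sc: Connectome, null: SpinNull,
                  alpha: float = 0.05) -> EpicenterResult:
    """Epicenter likelihood per region.

    Likelihood of region i is the Spearman correlation between its
    connectivity profile C[i, j != i] and the prevalence map p[j != i];
    the permuted map (spin for cortex, shuffle for subcortex, as encoded
    in ``null``) yields one-sided p-values.  Significant regions
    (p < alpha) are ranked in descending likelihood.
    """
    p = np.asarray(p, float)
    n = p.size
    if sc.weights.shape[0] != n:
        raise ValueError("map and connectome sizes differ")
    null_maps = null.apply(p)
    like = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        profile = sc.weights[i, mask[i]]
        if np.ptp(profile) == 0:
            logger.warning("region index %d has a constant SC profile; excluded", i)
            continue
        obs = spearmanr(profile, p[mask[i]]).statistic
        nulls = _spearman_rows(null_maps[:, mask[i]], profile)
        like[i] = obs
        pval[i] = _perm_pvalue(obs, nulls)
    sig = np.isfinite(pval) & (pval < alpha)
    rank = np.zeros(n, int)
    order = np.argsort(-np.where(sig, like, -np.inf))
    r = 1
    for i in order:
        if sig[i]:
            rank[i] = r
            r += 1
    return EpicenterResult(sc.region_ids.copy(), like, pval, sig, rank)
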