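"""Synthetic multi-site cohorts with known ground truth.

The generator emulates the data model assumed by the downstream stages:
control metric values follow a linear age/sex normative model with
additive residual noise and per-site batch effects; patients are displaced
in designated regions by a configurable number of residual standard
deviations (optionally shaped by one-step diffusion through the structural
connectome from an epicenter seed region).

Functional metrics are realised through vertex-level BOLD-like time series
constructed so the derived SV / ReHo / NS maps hit the designed targets:

* a global component with per-region loading ``w`` controls node strength,
* within-region coherence ``c`` controls regional homogeneity,
* the region amplitude ``a`` controls signal variability.

Structural metrics (CT, FA, MD) are generated directly at region level
with displacements scaled by the ``structure_coupling`` coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.sparse.csgraph import minimum_spanning_tree, connected_components
from scipy.stats import rankdata

from .atlas import Atlas, validate_subjects
from .containers import Connectome, MetricMatrix, VertexData

# temporal lag-1 autocorrelation of every latent/noise component
_AR_PHI = 0.3

#: per-metric generative parameters: baseline, age slope (/yr, around age 40),
#: sex offset (female - male) and residual noise SD.  NS entries are per
#: "other region", i.e. multiplied by (n_regions - 1) at build time.
METRIC_PARAMS = {
    "SV":   {"baseline": 6.0,   "age_slope": -0.020,  "sex_offset": 0.30,  "noise_sd": 1.00},
    "ReHo": {"baseline": 0.50,  "age_slope": -0.0008, "sex_offset": 0.010, "noise_sd": 0.040},
    "NS":   {"baseline": 0.30,  "age_slope": -0.0015, "sex_offset": 0.020, "noise_sd": 0.040},
    "CT":   {"baseline": 2.80,  "age_slope": -0.0050, "sex_offset": 0.020, "noise_sd": 0.120},
    "FA":   {"baseline": 0.45,  "age_slope": -0.0005, "sex_offset": 0.005, "noise_sd": 0.020},
    "MD":   {"baseline": 0.85,  "age_slope": 0.0010,  "sex_offset": -0.005, "noise_sd": 0.030},
}

FUNCTIONAL = ("SV", "ReHo", "NS")
STRUCTURAL = ("CT", "FA", "MD")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study. All randomness flows from ``seed``."""

    seed: int = 0
    n_sites: int = 2
    n_hc_per_site: int = 40
    n_tle_per_site: int = 35
    n_fcd_per_site: int = 6
    age_range: tuple = (18.0, 60.0)
    T: int = 150
    vertices_per_region: int = 6
    site_shift: float = 0.3          # additive batch offset, units of noise_sd
    site_scale: float = 0.15         # log-SD of multiplicative batch factor
    region_baseline_jitter: float = 1.0   # units of noise_sd, drawn once per run
    effect_regions: tuple = ()
    effect_size_w: float = 0.0       # target mean W displacement in affected regions
    epicenter_seed_region: int | None = None
    diffusion_strength: float = 1.0
    structure_coupling: dict = field(default_factory=lambda: {"CT": 0.5, "FA": 0.5, "MD": 0.5})
    noise_sd: dict = field(default_factory=dict)   # per-metric overrides
    prop_left_focus: float = 0.52
    n_calibration: int = 80          # replicates for intrinsic-noise estimation

    def __post_init__(self):
        for n in (self.n_sites, self.n_hc_per_site, self.n_tle_per_site):
            if n < 1:
                raise ValueError("site and group counts must be >= 1")
        if self.n_fcd_per_site < 0:
            raise ValueError("n_fcd_per_site must be >= 0")

    def metric_noise_sd(self, metric: str, n_regions: int) -> float:
        sd = self.noise_sd.get(metric, METRIC_PARAMS[metric]["noise_sd"])
        if metric == "NS":
            sd = sd * (n_regions - 1)
        return sd


@dataclass
class GroundTruth:
    """What the generator injected, for downstream parameter-recovery checks."""

    true_effect_map: np.ndarray          # region -> W displacement (left-focus frame)
    true_epicenter: int | None           # region id, or None
    affected_regions: dict               # subject_id -> list of region ids
    region_params: dict                  # metric -> dict of per-region beta arrays

    def to_dict(self) -> dict:
        return {
            "true_effect_map": self.true_effect_map.tolist(),
            "true_epicenter": self.true_epicenter,
            "affected_regions": {k: list(map(int, v)) for k, v in self.affected_regions.items()},
        }


# ---------------------------------------------------------------------------
# Atlas and connectome
# ---------------------------------------------------------------------------

_LOBE_BLOCKS = [("frontal", 0.30), ("parietal", 0.20), ("temporal", 0.25),
                ("occipital", 0.15), ("insula", 0.10)]


def simulate_atlas(n_cortical: int, n_subcortical: int, seed: int = 0) -> Atlas:
    """Hemispherically mirrored spherical parcellation.

    Cortical regions come in left/right homologue pairs with sphere
    coordinates mirrored in x; centroids sit on a 70 mm sphere.  Subcortical
    structures (also paired) sit near the midline without sphere coordinates.
    Lobes are assigned in contiguous anterior-to-posterior blocks.
    """
    if n_cortical % 2 != 0:
        raise ValueError("n_cortical must be even (hemisphere-paired)")
    if n_subcortical % 2 != 0:
        raise ValueError("n_subcortical must be even (hemisphere-paired)")
    rng = np.random.default_rng(seed)
    n_pairs = n_cortical // 2
    pts = rng.normal(size=(n_pairs, 3))
    pts[:, 0] = np.clip(np.abs(pts[:, 0]), 0.15, None)   # right hemisphere: x > 0
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    order = np.argsort(-pts[:, 1])                       # anterior -> posterior
    pts = pts[order]

    lobes = []
    counts = [max(1, int(round(f * n_pairs))) for _, f in _LOBE_BLOCKS]
    while sum(counts) > n_pairs:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_pairs:
        counts[int(np.argmax([f for _, f in _LOBE_BLOCKS]))] += 1
    for (lobe, _), c in zip(_LOBE_BLOCKS, counts):
        lobes.extend([lobe] * c)

    rows = []
    rid = 1
    for k in range(n_pairs):
        right = pts[k]
        left = np.array([-right[0], right[1], right[2]])
        rid_l, rid_r = rid, rid + 1
        for hemi, rid_self, rid_twin, s in (("left", rid_l, rid_r, left),
                                            ("right", rid_r, rid_l, right)):
            rows.append({
                "region_id": rid_self, "name": f"ctx_{lobes[k]}_{k}_{hemi[0].upper()}",
                "hemisphere": hemi, "lobe": lobes[k], "is_cortical": True,
                "homologue_id": rid_twin,
                "cx": 70.0 * s[0], "cy": 70.0 * s[1], "cz": 70.0 * s[2],
                "sx": s[0], "sy": s[1], "sz": s[2],
            })
        rid += 2
    for k in range(n_subcortical // 2):
        c = np.array([rng.uniform(8, 25), rng.uniform(-30, 10), rng.uniform(-15, 10)])
        rid_l, rid_r = rid, rid + 1
        for hemi, rid_self, rid_twin, sgn in (("left", rid_l, rid_r, -1.0),
                                              ("right", rid_r, rid_l, 1.0)):
            rows.append({
                "region_id": rid_self, "name": f"sctx_{k}_{hemi[0].upper()}",
                "hemisphere": hemi, "lobe": "subcortex", "is_cortical": False,
                "homologue_id": rid_twin,
                "cx": sgn * c[0], "cy": c[1], "cz": c[2],
                "sx": np.nan, "sy": np.nan, "sz": np.nan,
            })
        rid += 2
    return Atlas(pd.DataFrame(rows))


def simulate_connectome(atlas: Atlas, density: float = 0.35, seed: int = 0,
                        length_scale: float = 35.0) -> Connectome:
    """Distance-dependent weighted structural connectome.

    Edge retention favours short inter-centroid distances (exponential
    decay), weights decay with distance with lognormal scatter, and a
    minimum spanning tree is always included so the graph is connected.
    ``density=1`` yields the complete weighted graph.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = atlas.n_regions
    c = atlas.centroids
    dist = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    score = np.exp(-dist[iu] / length_scale) * rng.lognormal(0.0, 0.5, size=iu[0].size)
    n_keep = max(1, int(round(density * iu[0].size)))
    keep = np.zeros(iu[0].size, bool)
    keep[np.argsort(-score)[:n_keep]] = True

    w = np.zeros((n, n))
    vals = np.exp(-dist[iu] / length_scale) * rng.lognormal(0.0, 0.2, size=iu[0].size)
    w[iu[0][keep], iu[1][keep]] = vals[keep]
    # guarantee connectivity via the Euclidean minimum spanning tree
    mst = minimum_spanning_tree(dist).toarray()
    mi, mj = np.nonzero(mst)
    for a, b in zip(mi, mj):
        a, b = min(a, b), max(a, b)
        if w[a, b] == 0:
            w[a, b] = np.exp(-dist[a, b] / length_scale)
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    n_comp, _ = connected_components((w > 0).astype(int), directed=False)
    assert n_comp == 1
    return Connectome(w, atlas.region_ids)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, shape: tuple, phi: float = _AR_PHI) -> np.ndarray:
    """Stationary unit-variance AR(1) rows."""
    e = rng.standard_normal(shape)
    x = lfilter([1.0], [1.0, -phi], e, axis=-1)
    return x * np.sqrt(1.0 - phi ** 2)


def _effect_map(cfg: SimulationConfig, atlas: Atlas, sc: Connectome | None) -> np.ndarray:
    """Per-region W-displacement shape in the left-focus reference frame."""
    eff = np.zeros(atlas.n_regions)
    if cfg.effect_regions:
        for rid in cfg.effect_regions:
            if int(rid) not in set(atlas.region_ids.tolist()):
                raise ValueError(f"effect region {rid} not in atlas")
            eff[atlas.index_of(int(rid))] = 1.0
    if cfg.epicenter_seed_region is not None:
        if sc is None:
            raise ValueError("epicenter seeding requires a connectome")
        if int(cfg.epicenter_seed_region) not in set(atlas.region_ids.tolist()):
            raise ValueError(f"epicenter seed {cfg.epicenter_seed_region} not in atlas")
        i = atlas.index_of(int(cfg.epicenter_seed_region))
        row = sc.weights[i].copy()
        if row.max() <= 0:
            raise ValueError("epicenter seed region has no connections")
        spread = cfg.diffusion_strength * row / row.max()
        spread[i] = 1.0
        eff = np.maximum(eff, spread)
    return eff


def _region_betas(cfg: SimulationConfig, atlas: Atlas, rng: np.random.Generator) -> dict:
    """Per-region normative coefficients (baseline jitter drawn once)."""
    n = atlas.n_regions
    out = {}
    for m, p in METRIC_PARAMS.items():
        scale = (n - 1) if m == "NS" else 1.0
        sd = cfg.metric_noise_sd(m, n)
        out[m] = {
            "b0": p["baseline"] * scale + cfg.region_baseline_jitter * sd * rng.standard_normal(n),
            "b1": np.full(n, p["age_slope"] * scale),
            "b2": np.full(n, p["sex_offset"] * scale),
        }
    return out


def _targets(betas: dict, metric: str, age: float, sex: int) -> np.ndarray:
    b = betas[metric]
    return b["b0"] + b["b1"] * (age - 40.0) + b["b2"] * sex


def _solve_global_loading(ns_target: np.ndarray, beta: np.ndarray, R: np.ndarray,
                          n_iter: int = 12) -> np.ndarray:
    """Per-region loading s=sqrt(w) on the shared component so that the
    expected node strength matches ``ns_target``.

    With region-mean attenuation ``beta`` and latent template correlation
    R, expected FC is  beta_i beta_j (s_i s_j + q_i q_j R_ij), q=sqrt(1-s^2);
    each s_i solves  s A + sqrt(1-s^2) B = y  in closed form given the
    others, iterated to a fixed point.  Targets outside the achievable
    range are clipped.
    """
    n = len(ns_target)
    s = np.full(n, 0.55)
    Rz = R.copy()
    np.fill_diagonal(Rz, 0.0)
    for _ in range(n_iter):
        q = np.sqrt(1.0 - s ** 2)
        A = beta * ((beta * s).sum() - beta * s)
        B = beta * (Rz @ (beta * q))
        y = ns_target
        rho = np.sqrt(A ** 2 + B ** 2)
        ratio = np.clip(y / np.maximum(rho, 1e-12), -1.0, 1.0)
        theta = np.arcsin(ratio) - np.arctan2(B, A)
        s = np.clip(np.sin(theta), 0.05, 0.975)
    return s


def _coherence_from_reho(reho_target: np.ndarray, K: int) -> np.ndarray:
    """Within-region loading c from a target Kendall-W, via the
    equicorrelated-Gaussian approximation W ~= (1 + (K-1) rho_s) / K."""
    rho_s = (K * np.clip(reho_target, 0.02, 0.98) - 1.0) / (K - 1)
    rho = 2.0 * np.sin(np.pi * np.clip(rho_s, 0.0, 0.985) / 6.0)
    return np.sqrt(np.clip(rho, 1e-4, 0.97))


def _subject_vertex_data(rng, cfg, atlas, R_chol, R, sv_t, reho_t, ns_t,
                         neighbors, vertex_region):
    """Vertex time series realising one subject's metric targets."""
    n = atlas.n_regions
    V = cfg.vertices_per_region
    T = cfg.T
    c = _coherence_from_reho(reho_t, K=V)
    beta = c / np.sqrt(c ** 2 + (1.0 - c ** 2) / V)
    s = _solve_global_loading(ns_t, beta, R)
    q = np.sqrt(1.0 - s ** 2)

    g = _ar1(rng, (T,))
    u = R_chol @ _ar1(rng, (n, T))
    z = s[:, None] * g[None, :] + q[:, None] * u
    eta = _ar1(rng, (n * V, T))

    sigma_m = np.sqrt(c ** 2 + (1.0 - c ** 2) / V)
    unit_sv = sigma_m * np.sqrt(2.0 * (1.0 - _AR_PHI) / (T - 1))
    a = np.clip(sv_t, 1e-6, None) / unit_sv

    reg = np.repeat(np.arange(n), V)
    ts = a[reg, None] * (c[reg, None] * z[reg] + np.sqrt(1.0 - c[reg] ** 2)[:, None] * eta)
    return VertexData(ts, vertex_region, neighbors)


def _template_correlation(atlas: Atlas, length_scale: float = 40.0) -> np.ndarray:
    c = atlas.centroids
    dist = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
    R = np.exp(-dist / length_scale)
    # shrink toward identity for numerical positive-definiteness
    R = 0.95 * R + 0.05 * np.eye(len(R))
    np.fill_diagonal(R, 1.0)
    return R


def _fast_metrics(vd: VertexData, atlas: Atlas) -> dict:
    """SV / ReHo / NS maps for one subject (rank computation shared)."""
    from .metrics import node_strength, region_timeseries, signal_variability

    rts = region_timeseries(vd, atlas)
    sv = np.array([signal_variability(r) for r in rts])
    ns = node_strength(rts, atlas, "full")
    T = vd.T
    ranks = rankdata(vd.timeseries, axis=1)
    reho = np.empty(atlas.n_regions)
    for i, rid in enumerate(atlas.region_ids):
        members = np.nonzero(vd.vertex_region == rid)[0]
        K = members.size
        R = ranks[members].sum(axis=0)
        reho[i] = 12.0 * (np.sum(R ** 2) - T * R.mean() ** 2) / (K ** 2 * (T ** 3 - T))
    return {"SV": sv, "ReHo": reho, "NS": ns}


def _intrinsic_sd(cfg: SimulationConfig, atlas: Atlas, betas: dict,
                  R_chol: np.ndarray, R: np.ndarray, neighbors, vertex_region,
                  rng: np.random.Generator) -> dict:
    """Metric sampling noise at baseline targets, by Monte Carlo replication."""
    sv_t = _targets(betas, "SV", 40.0, 0)
    reho_t = _targets(betas, "ReHo", 40.0, 0)
    ns_t = _targets(betas, "NS", 40.0, 0)
    reps = {m: [] for m in FUNCTIONAL}
    for _ in range(cfg.n_calibration):
        vd = _subject_vertex_data(rng, cfg, atlas, R_chol, R, sv_t, reho_t, ns_t,
                                  neighbors, vertex_region)
        got = _fast_metrics(vd, atlas)
        for m in FUNCTIONAL:
            reps[m].append(got[m])
    return {m: float(np.vstack(v).std(axis=0, ddof=1).mean()) for m, v in reps.items()}


def simulate_cohort(cfg: SimulationConfig, atlas: Atlas, sc: Connectome | None = None):
    """Generate subjects, vertex time series, structural metrics and truth.

    Returns ``(subjects, vertex_data, struct_metrics, ground_truth)`` where
    ``vertex_data`` maps subject id to :class:`VertexData` and
    ``struct_metrics`` maps CT/FA/MD to :class:`MetricMatrix`.
    """
    rng = np.random.default_rng(cfg.seed)
    n = atlas.n_regions
    V = cfg.vertices_per_region
    betas = _region_betas(cfg, atlas, rng)
    eff = _effect_map(cfg, atlas, sc)
    R = _template_correlation(atlas)
    R_chol = np.linalg.cholesky(R)
    vertex_region = np.repeat(atlas.region_ids, V)
    neighbors = []
    for r in range(n):
        block = list(range(r * V, (r + 1) * V))
        neighbors.extend([[u for u in block if u != v] for v in block])

    # site batch effects: additive per (site, metric, region), multiplicative
    # residual scale per (site, metric)
    site_names = [f"site{k + 1}" for k in range(cfg.n_sites)]
    site_add = {m: cfg.site_shift * cfg.metric_noise_sd(m, n)
                * rng.standard_normal((cfg.n_sites, n)) for m in METRIC_PARAMS}
    site_mul = {m: np.exp(cfg.site_scale * rng.standard_normal(cfg.n_sites))
                for m in METRIC_PARAMS}
    if cfg.n_sites == 1:
        for m in METRIC_PARAMS:
            site_add[m][:] = 0.0
            site_mul[m][:] = 1.0

    # displacement scale: configured noise + intrinsic metric sampling noise
    if cfg.effect_size_w != 0.0 and eff.any():
        intr = _intrinsic_sd(cfg, atlas, betas, R_chol, R, neighbors, vertex_region,
                             np.random.default_rng(rng.integers(2 ** 31)))
    else:
        intr = {m: 0.0 for m in FUNCTIONAL}
    total_sd = {m: float(np.hypot(cfg.metric_noise_sd(m, n), intr.get(m, 0.0)))
                for m in METRIC_PARAMS}

    # subjects
    rows = []
    groups = (["HC"] * cfg.n_hc_per_site + ["TLE"] * cfg.n_tle_per_site
              + ["FCD"] * cfg.n_fcd_per_site)
    for k, site in enumerate(site_names):
        for j, grp in enumerate(groups):
            age = float(rng.uniform(*cfg.age_range))
            sex = int(rng.integers(0, 2))
            if grp == "HC":
                focus, hs = "none", "unknown"
                onset = duration = np.nan
                n_asm, fbtcs, engel = 0, False, "unknown"
            else:
                focus = "left" if rng.random() < cfg.prop_left_focus else "right"
                hs = ("HS" if rng.random() < 0.68 else "non-HS") if grp == "TLE" else "unknown"
                duration = float(np.clip(rng.normal(14.0, 9.0), 0.8, age - 1.0))
                onset = age - duration
                n_asm = int(1 + rng.poisson(1.2))
                fbtcs = bool(rng.random() < 0.4)
                engel = ("seizure-free" if rng.random() < 0.6 else "non-seizure-free") \
                    if grp == "TLE" else "unknown"
            rows.append({
                "subject_id": f"{site}_{grp}_{j:03d}", "group": grp, "site": site,
                "age": age, "sex": sex, "focus": focus, "hs_status": hs,
                "onset_age": onset, "duration": duration, "n_asm": n_asm,
                "fbtcs": fbtcs, "engel_seizure_free": engel,
                "mean_fd": float(rng.lognormal(np.log(0.15), 0.3)),
            })
    subjects = validate_subjects(pd.DataFrame(rows))

    swap = atlas.swap_permutation()
    vertex_data: dict[str, VertexData] = {}
    struct_vals = {m: np.empty((len(subjects), n)) for m in STRUCTURAL}
    affected: dict[str, list] = {}
    for idx, row in subjects.iterrows():
        site_k = site_names.index(row["site"])
        is_patient = row["group"] == "TLE"
        subj_eff = np.zeros(n)
        if is_patient and eff.any():
            subj_eff = eff if row["focus"] in ("left", "none") else eff[swap]
        affected[row["subject_id"]] = atlas.region_ids[subj_eff > 0.5].tolist()

        t = {}
        for m in FUNCTIONAL:
            base = _targets(betas, m, row["age"], row["sex"])
            noise = site_mul[m][site_k] * cfg.metric_noise_sd(m, n) * rng.standard_normal(n)
            disp = cfg.effect_size_w * total_sd[m] * subj_eff
            t[m] = base + site_add[m][site_k] + noise + disp
        vertex_data[row["subject_id"]] = _subject_vertex_data(
            rng, cfg, atlas, R_chol, R, t["SV"], t["ReHo"], t["NS"],
            neighbors, vertex_region)

        for m in STRUCTURAL:
            base = _targets(betas, m, row["age"], row["sex"])
            noise = site_mul[m][site_k] * cfg.metric_noise_sd(m, n) * rng.standard_normal(n)
            coup = cfg.structure_coupling.get(m, 0.0)
            disp = coup * cfg.effect_size_w * cfg.metric_noise_sd(m, n) * subj_eff
            struct_vals[m][idx] = base + site_add[m][site_k] + noise + disp

    struct = {m: MetricMatrix(m, struct_vals[m], list(subjects["subject_id"]), atlas.region_ids)
              for m in STRUCTURAL}
    truth = GroundTruth(cfg.effect_size_w * eff, cfg.epicenter_seed_region, affected,
                        {m: {k: v.copy() for k, v in b.items()} for m, b in betas.items()})
    return subjects, vertex_data, struct, truth


def simulate_dataset(cfg: SimulationConfig, n_cortical: int = 20, n_subcortical: int = 6,
                     density: float = 0.35):
    """Atlas + connectome + cohort in one call (seeds derived from cfg.seed)."""
    atlas = simulate_atlas(n_cortical, n_subcortical, seed=cfg.seed)
    sc = simulate_connectome(atlas, density=density, seed=cfg.seed + 1)
    subjects, vertex_data, struct, truth = simulate_cohort(cfg, atlas, sc)
    return atlas, sc, subjects, vertex_data, struct, truth
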