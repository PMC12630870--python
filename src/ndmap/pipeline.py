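"""End-to-end orchestration: one config, one reproducible run.

Stages run in the printed order of the analysis: simulate (optional) ->
metrics -> harmonize -> deviate -> network -> couple -> classify.  Every
stage derives its own seed from the master seed and the stage name, and
every output file is recorded with a SHA-256 hash in a run manifest so
deterministic stages can be verified on rerun.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import Atlas, lateralize_to_focus, read_subjects
from .clinical import ClassifierSpec, nested_cv_classify
from .containers import read_matrix, read_vertex_data, write_matrix
from .coupling import fit_coupling
from .harmonize import harmonize
from .metrics import compute_metrics, global_signal_regress
from .network import epicenter_map, node_vs_neighbor_coupling, spin_permute
from .normative import deviation_set
from .simulate import SimulationConfig, simulate_atlas, simulate_cohort, simulate_connectome

FUNCTIONAL_METRICS = ("SV", "ReHo", "NS")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest:
    def __init__(self, config: dict, out_dir: Path):
        self.data = {"config": config, "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
                     "stages": [], "files": {}}
        self.out_dir = out_dir

    def log_stage(self, name: str, seed: int | None, params: dict):
        self.data["stages"].append({"stage": name, "seed": seed, "params": params})

    def log_file(self, path: Path):
        self.data["files"][str(path.relative_to(self.out_dir))] = _sha256(path)

    def write(self, path: Path):
        path.write_text(json.dumps(self.data, indent=2, default=str))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _simulate_stage(cfg: dict, seed: int):
    sim = dict(cfg.get("simulate", {}))
    n_cortical = sim.pop("n_cortical", 20)
    n_subcortical = sim.pop("n_subcortical", 6)
    density = sim.pop("density", 0.35)
    sim.setdefault("seed", seed)
    if "effect_regions" in sim:
        sim["effect_regions"] = tuple(sim["effect_regions"])
    scfg = SimulationConfig(**sim)
    atlas = simulate_atlas(n_cortical, n_subcortical, seed=scfg.seed)
    sc = simulate_connectome(atlas, density=density, seed=scfg.seed + 1)
    subjects, vertex_data, struct, truth = simulate_cohort(scfg, atlas, sc)
    return atlas, sc, subjects, vertex_data, struct, truth


def _load_inputs(cfg: dict):
    paths = cfg["inputs"]
    atlas = Atlas.from_tsv(paths["atlas"])
    subjects = read_subjects(paths["subjects"])
    sc = read_matrix(paths["connectome"], "connectome", atlas)
    struct = {m: read_matrix(paths[m.lower()], "metric", atlas, metric_name=m)
              for m in ("CT", "FA", "MD") if m.lower() in paths}
    return atlas, sc, subjects, struct


def run_all(config: dict | str, out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline from a config dict or YAML path."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    manifest = RunManifest(config, out)

    # --- inputs -----------------------------------------------------------
    if "inputs" in config:
        atlas, sc, subjects, struct = _load_inputs(config)
        vd_dir = Path(config["inputs"]["timeseries_dir"])
        vertex_data = {sid: read_vertex_data(vd_dir, sid)
                       for sid in subjects["subject_id"]}
        manifest.log_stage("load", None, {"inputs": config["inputs"]})
    else:
        atlas, sc, subjects, vertex_data, struct, truth = _simulate_stage(
            config, stage_seed(master_seed, "simulate"))
        manifest.log_stage("simulate", stage_seed(master_seed, "simulate"),
                           config.get("simulate", {}))
        (out / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    atlas.to_tsv(out / "atlas.tsv")
    subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    sc.to_tsv(out / "connectome.tsv")

    # --- metrics ----------------------------------------------------------
    mcfg = config.get("metrics", {})
    if mcfg.get("gsr", False):
        vertex_data = {k: global_signal_regress(v) for k, v in vertex_data.items()}
    mets = compute_metrics(vertex_data, atlas,
                           cutoff_mm=mcfg.get("cutoff_mm", 75.0),
                           sv_variant=mcfg.get("sv_variant", "printed"))
    mets.update(struct)
    manifest.log_stage("metrics", None, mcfg)
    for name, m in mets.items():
        write_matrix(m, out / f"metric_{name}.tsv")

    # --- harmonization ----------------------------------------------------
    hcfg = config.get("harmonize", {})
    if len(set(subjects["site"])) > 1 and hcfg.get("enabled", True):
        mets = {name: harmonize(m, subjects, batch_col=hcfg.get("batch", "site"),
                                preserve=hcfg.get("preserve", ["age", "sex", "group"]))
                for name, m in mets.items()}
        for name, m in mets.items():
            write_matrix(m, out / f"metric_{name}_harmonized.tsv")
    manifest.log_stage("harmonize", None, hcfg)

    # --- deviations -------------------------------------------------------
    dcfg = config.get("deviate", {})
    covariates = dcfg.get("covariates", ["age", "sex"])
    threshold = dcfg.get("threshold", 1.96)
    func = {m: mets[m] for m in FUNCTIONAL_METRICS}
    pat, ctl = deviation_set(func, subjects, covariates=covariates,
                             threshold=threshold,
                             composite=dcfg.get("composite", True))
    manifest.log_stage("deviate", None, dcfg)
    tle = subjects[subjects["group"] == "TLE"].reset_index(drop=True)
    prev = {}
    for j, name in enumerate(pat.metrics):
        w_lat = lateralize_to_focus(pat.w[:, :, j], tle, atlas)
        mask = np.abs(w_lat) >= threshold
        prev[name] = mask.mean(axis=0)
    prev_df = pd.DataFrame(prev, index=atlas.region_ids)
    prev_df.to_csv(out / "prevalence.tsv", sep="\t")
    for j, name in enumerate(pat.metrics):
        pd.DataFrame(pat.w[:, :, j], index=pat.subject_ids,
                     columns=atlas.region_ids).to_csv(out / f"w_{name}.tsv", sep="\t")
    counts = pat.deviation_counts()
    pd.DataFrame({"subject_id": pat.subject_ids, "n_extreme": counts}).to_csv(
        out / "deviation_counts.tsv", sep="\t", index=False)

    # --- network ----------------------------------------------------------
    ncfg = config.get("network", {})
    n_iter = int(ncfg.get("n_iter", 1000))
    null = spin_permute(atlas, n_iter=n_iter, seed=stage_seed(master_seed, "network"))
    net_out = {}
    for name in pat.metrics:
        rho, p_spin, pbar = node_vs_neighbor_coupling(prev[name], sc, null)
        epi = epicenter_map(prev[name], sc, null)
        epi.to_frame().to_csv(out / f"epicenters_{name}.tsv", sep="\t", index=False)
        net_out[name] = {"coupling_rho": rho, "coupling_p_spin": p_spin}
    (out / "network.json").write_text(json.dumps(net_out, indent=2))
    manifest.log_stage("network", stage_seed(master_seed, "network"), {"n_iter": n_iter})

    # --- structure-function coupling --------------------------------------
    struct_prev = {}
    spat, _ = deviation_set({m: mets[m] for m in ("CT", "FA", "MD")}, subjects,
                            covariates=covariates, threshold=threshold, composite=False)
    for j, name in enumerate(spat.metrics):
        w_lat = lateralize_to_focus(spat.w[:, :, j], tle, atlas)
        struct_prev[name] = (np.abs(w_lat) >= threshold).mean(axis=0)
    Xs = pd.DataFrame(struct_prev)
    couple_out = {}
    for name in pat.metrics:
        res = fit_coupling(prev[name], Xs, null=null)
        couple_out[name] = {"r2_adj": res.rsquared_adj, "rho": res.rho,
                            "p_spin": res.p_spin,
                            "dominance_shares": dict(zip(res.predictor_names,
                                                         res.dominance_shares.tolist()))}
    (out / "coupling.json").write_text(json.dumps(couple_out, indent=2))
    manifest.log_stage("couple", None, {})

    # --- classification ---------------------------------------------------
    ccfg = config.get("classify", {})
    spec = ClassifierSpec(n_outer_iterations=int(ccfg.get("n_outer_iterations", 20)),
                          seed=stage_seed(master_seed, "classify"))
    class_out = {}
    for task in ccfg.get("tasks", ["lateralization"]):
        feats, labels = task_features(task, pat, tle, atlas)
        if feats is None:
            raise ValueError(f"stage classify: task {task!r} has too few "
                             "subjects per class (need >= 10)")
        res = nested_cv_classify(feats, labels, spec)
        class_out[task] = res.summary()
    (out / "classification.json").write_text(json.dumps(class_out, indent=2))
    manifest.log_stage("classify", spec.seed, ccfg)

    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.log_file(f)
    manifest.write(out / "manifest.json")
    return manifest


def task_features(task: str, pat, tle: pd.DataFrame, atlas: Atlas):
    """Feature matrix and binary labels for one classification task.

    Diagnosis and outcome tasks use focus-lateralized W-scores; the
    lateralization task keeps native space (the label is the target).
    """
    S, R, K = pat.w.shape
    if task == "lateralization":
        labels = (tle["focus"] == "right").to_numpy().astype(int)
        feats = pat.w.reshape(S, R * K)
    elif task == "outcome":
        keep = tle["engel_seizure_free"].isin(["seizure-free", "non-seizure-free"]).to_numpy()
        if keep.sum() < 20:
            return None, None
        sub = tle[keep].reset_index(drop=True)
        w = np.stack([lateralize_to_focus(pat.w[keep][:, :, j], sub, atlas)
                      for j in range(K)], axis=2)
        feats = w.reshape(keep.sum(), R * K)
        labels = (sub["engel_seizure_free"] == "seizure-free").to_numpy().astype(int)
    else:
        raise ValueError(f"unknown task {task!r} for pipeline features")
    if min(np.bincount(labels)) < 10:
        return None, None
    return feats, labels


def sensitivity_variants(config: dict | str, base_dir: str | Path,
                         out_dir: str | Path) -> dict:
    """Rerun the deviation stage under sensitivity configurations.

    (a) add mean framewise displacement as a normative covariate,
    (b) recompute metrics from GSR-processed series,
    (c) split patients by focus laterality;
    each variant's prevalence map is compared to the base run's with a
    Spearman correlation and a spin-permutation p-value.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    base_dir, out = Path(base_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_manifest = json.loads((base_dir / "manifest.json").read_text())
    base_prev = pd.read_csv(base_dir / "prevalence.tsv", sep="\t", index_col=0)
    atlas = Atlas.from_tsv(base_dir / "atlas.tsv")
    master_seed = int(config.get("seed", 0))
    null = spin_permute(atlas, n_iter=int(config.get("network", {}).get("n_iter", 1000)),
                        seed=stage_seed(master_seed, "variants"))

    report = {"base_manifest_created": base_manifest["created"]}
    variants = {
        "motion_covariate": {"deviate": {**config.get("deviate", {}),
                                         "covariates": ["age", "sex", "mean_fd"]}},
        "gsr": {"metrics": {**config.get("metrics", {}), "gsr": True}},
    }
    from scipy.stats import spearmanr
    for name, override in variants.items():
        vcfg = {**config, **override}
        vdir = out / name
        run_all(vcfg, vdir)
        vprev = pd.read_csv(vdir / "prevalence.tsv", sep="\t", index_col=0)
        rhos = {}
        for col in base_prev.columns:
            rho = spearmanr(base_prev[col], vprev[col]).statistic
            nulls = null.apply(base_prev[col].to_numpy())
            null_rho = np.array([spearmanr(nm, vprev[col]).statistic for nm in nulls])
            p = float((1 + (null_rho >= rho).sum()) / (1 + len(null_rho)))
            rhos[col] = {"rho": float(rho), "p_spin": p}
        report[name] = rhos

    # focus-laterality subgroups on the base run's W-scores
    subjects = read_subjects(base_dir / "subjects.tsv")
    tle = subjects[subjects["group"] == "TLE"].reset_index(drop=True)
    threshold = float(config.get("deviate", {}).get("threshold", 1.96))
    lat_report = {"n_left": int((tle["focus"] == "left").sum()),
                  "n_right": int((tle["focus"] == "right").sum())}
    for col in base_prev.columns:
        wdf = pd.read_csv(base_dir / f"w_{col}.tsv", sep="\t", index_col=0)
        maps = {}
        for side in ("left", "right"):
            sel = (tle["focus"] == side).to_numpy()
            if sel.sum() < 10:
                lat_report.setdefault("skipped", []).append(f"{col}:{side}")
                continue
            sub = tle[sel].reset_index(drop=True)
            w_lat = lateralize_to_focus(wdf.to_numpy()[sel], sub, atlas)
            maps[side] = (np.abs(w_lat) >= threshold).mean(axis=0)
        if len(maps) == 2:
            rho = spearmanr(maps["left"], maps["right"]).statistic
            lat_report[col] = {"rho_left_vs_right": float(rho)}
    report["laterality_subgroups"] = lat_report
    (out / "variants.json").write_text(json.dumps(report, indent=2))
    return report
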