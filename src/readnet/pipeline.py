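"""End-to-end orchestration of the gene-brain-behavior analysis.

Stages: synthetic data -> phenotype residualization/banding -> READ1
carrier coding and contingency testing -> SNP QC + ancestry PCA ->
multinomial association with imputation -> motion QC + nuisance regression
-> ICD mapping with cluster-corrected voxelwise inference -> seed network
and genotype-connectivity regressions.  A manifest records the config
hash, seeds and per-stage sizes so that any output is reproducible from
config + seed alone.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import association as assoc
from . import icd as icd_mod
from . import io
from . import motion as motion_mod
from . import network as net_mod
from . import phenotype as pheno
from . import popstruct
from . import read1
from . import simulate as sim

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "cohort": {"n_subjects": 1000, "missing_rate": 0.015},
    "snp": {"n_snps": 2000, "n_per_population": [100, 100], "fst": 0.1},
    "phenotype": {"banding": "standard"},
    "association": {"m_imputations": 15, "n_pcs": 10},
    "imaging": {
        "enabled": True,
        "n_subjects": 16,
        "grid_shape": [14, 16, 14],
        "n_volumes_per_run": 120,
        "n_runs": 2,
        "carrier_corr_increment": 0.2,
        "voxel_p": 0.001,
        "cluster_p": 0.05,
        "cluster_iters": 1000,
        "smooth_fwhm_mm": 6.0,
        "tau_grid_step": 0.05,
        "network_p": 1e-6,
        "node_radius_mm": 6.0,
        "min_sep_mm": 18.0,
    },
    "stages": ["simulate", "phenotype", "genetics", "popstruct",
               "associate", "imaging", "network"],
}


def _merge(base: dict, override: Optional[dict]) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_seeds(root_seed: int) -> Dict[str, int]:
    ss = np.random.SeedSequence(root_seed)
    names = ["cohort", "snp", "bold", "imputation", "cluster"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: Optional[dict] = None,
                 out_dir: Optional[str] = None) -> dict:
    """Execute the configured stages and return a result bundle.

    The bundle maps stage names to their key outputs and always includes a
    ``manifest``.  If *out_dir* is given, tables/maps/manifest are written
    there in the standard formats.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    seeds = _stage_seeds(int(cfg["seed"]))
    stages = cfg["stages"]
    out: Dict = {}
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "stage_seeds": seeds,
        "version": __version__,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    outp = Path(out_dir) if out_dir else None
    if outp:
        outp.mkdir(parents=True, exist_ok=True)

    def record(stage, **info):
        manifest["stages"][stage] = info
        logger.info("stage %s done: %s", stage, info)

    cohort = None
    try:
        if "simulate" in stages:
            spec = sim.CohortSpec(seed=seeds["cohort"], **cfg["cohort"])
            cohort = sim.generate_cohort(spec)
            out["cohort"] = cohort
            record("simulate", n_subjects=len(cohort))
            if outp is not None:
                io.write_table(cohort, outp / "cohort.tsv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e)

    try:
        if "phenotype" in stages and cohort is not None:
            model = pheno.fit_residual_model(cohort)
            resid, z = model.residualize(cohort)
            cohort["residual"] = resid
            cohort["z"] = z
            cohort["group"] = pheno.classify_groups(
                z, mode=cfg["phenotype"]["banding"])
            record("phenotype", residual_sd=model.residual_sd,
                   n_fit=model.n_fit,
                   group_sizes={g: int((cohort["group"] == g).sum())
                                for g in ("UPC", "EAC", "UGC", "UNCLASSIFIED")})
            out["residual_model"] = model
            if outp is not None:
                io.write_json(model.to_dict(), outp / "residual_model.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("phenotype", e)

    try:
        if "genetics" in stages and cohort is not None:
            calls = read1.calls_from_frame(cohort)
            flags = [
                read1.carrier_status(c, read1.AlleleGroup.RU2SHORT)
                if c is not None else None
                for c in calls
            ]
            cohort["carrier"] = [
                f if isinstance(f, bool) else np.nan for f in flags]
            usable = [c for c in calls if c is not None]
            table = assoc.carrier_contingency(cohort["group"],
                                              cohort["carrier"])
            chi2, dof, p = assoc.chi_square_independence(table.values)
            out["contingency"] = table
            out["chi_square"] = {"chi2": chi2, "df": dof, "p": p}
            record("genetics", call_rate=read1.call_rate(calls),
                   chi2=chi2, df=dof, p=p,
                   proportions=table.proportions.to_dict())
    except Exception as e:  # noqa: BLE001
        raise PipelineError("genetics", e)

    try:
        if "popstruct" in stages and cohort is not None:
            snp_cfg = dict(cfg["snp"])
            snp_cfg["n_per_population"] = tuple(snp_cfg["n_per_population"])
            matrix = sim.generate_snp_matrix(
                sim.SnpSpec(seed=seeds["snp"], **snp_cfg))
            filtered, snp_report = popstruct.snp_qc(matrix)
            pca = popstruct.eigenstrat_pca(
                filtered, K=cfg["association"]["n_pcs"])
            # ancestry scores are assigned cyclically to cohort subjects:
            # the synthetic SNP panel is smaller than the cohort
            n = len(cohort)
            reps = int(np.ceil(n / pca.components.shape[0]))
            pcs = np.tile(pca.components, (reps, 1))[:n]
            for k in range(pca.K):
                cohort[f"PC{k + 1}"] = pcs[:, k]
            out["pca"] = pca
            out["snp_qc_report"] = snp_report
            record("popstruct", **snp_report)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("popstruct", e)

    try:
        if "associate" in stages and cohort is not None:
            classified = cohort[cohort["group"].isin(("UPC", "EAC", "UGC"))]
            config_m = assoc.ModelConfig(n_pcs=cfg["association"]["n_pcs"])
            pooled = assoc.impute_and_pool(
                classified, config_m,
                m=cfg["association"]["m_imputations"],
                seed=seeds["imputation"])
            out["association"] = pooled
            record("associate", n=len(classified), m=pooled.m,
                   min_relative_efficiency=pooled.min_relative_efficiency)
            if outp is not None:
                io.write_table(pooled.results, outp / "association.tsv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("associate", e)

    imaging_out = None
    try:
        if "imaging" in stages and cfg["imaging"]["enabled"] and cohort is not None:
            imaging_out = _imaging_stage(cfg, cohort, seeds, out)
            record("imaging", **imaging_out["summary"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("imaging", e)

    try:
        if ("network" in stages and imaging_out is not None):
            net = _network_stage(cfg, imaging_out, out)
            record("network", **net["summary"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("network", e)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    out["manifest"] = manifest
    if outp is not None:
        io.write_json(manifest, outp / "manifest.json")
    return out


def _imaging_stage(cfg, cohort, seeds, out):
    icfg = cfg["imaging"]
    scale = np.asarray(icfg["grid_shape"]) * 3.0 / np.asarray((60.0, 72.0, 60.0))
    spec = sim.BoldSpec(
        grid_shape=tuple(icfg["grid_shape"]),
        n_volumes_per_run=icfg["n_volumes_per_run"],
        n_runs=icfg["n_runs"],
        carrier_corr_increment=icfg["carrier_corr_increment"],
        node_centers_mm=tuple(
            tuple(np.asarray(c) * scale) for c in sim.DEFAULT_NODE_CENTERS),
        node_radius_mm=max(3.0, float(icfg["node_radius_mm"]) * scale.min()),
        seed=seeds["bold"],
    )
    usable = cohort[cohort["carrier"].isin([True, False])]
    subjects = usable.iloc[: icfg["n_subjects"]]
    carriers = subjects["carrier"].astype(bool).to_numpy()
    bold = sim.generate_bold(spec, carriers)
    masks = bold[0].masks
    brain = masks["gm"] | masks["wm"] | masks["vent"]
    tau = np.arange(0.0, 1.0, icfg["tau_grid_step"])
    beta_maps, keep_rows = [], []
    residual_data = []
    for i, sb in enumerate(bold):
        cm = motion_mod.censor([m for m in sb.motion],
                               [r.data for r in sb.runs], masks["gm"])
        if not cm.include_subject:
            continue
        resids = []
        for run, trace, keep in zip(sb.runs, sb.motion, cm.keep):
            resid, _ = motion_mod.nuisance_regress(
                run.data, trace, keep, masks["wm"], masks["vent"],
                spec.tr_s, analysis_mask=brain)
            resids.append(resid)
        resid_all = np.concatenate(resids, axis=-1)
        maps = icd_mod.icd_subject(resid_all, masks["gm"], tau)
        smoothed = icd_mod.smooth_map(maps.beta, icfg["smooth_fwhm_mm"],
                                      masks["gm"], spec.voxel_size_mm)
        beta_maps.append(smoothed)
        residual_data.append(resid_all)
        keep_rows.append(i)
    sub = subjects.iloc[keep_rows]
    covs = pd.DataFrame({
        "phenotype": sub["z"].to_numpy(float),
        "sex_female": sub["sex_female"].to_numpy(float),
        "maternal_edu_years": sub["maternal_edu_years"].fillna(
            sub["maternal_edu_years"].mean()).to_numpy(float),
        "ses_low": sub["ses_low"].fillna(0).to_numpy(float),
    })
    for k in range(3):
        col = f"PC{k + 1}"
        if col in sub:
            covs[col] = sub[col].to_numpy(float)
    # small desk-scale samples cannot support the full covariate set;
    # drop trailing covariates (phenotype always stays) until df > 0
    while covs.shape[1] + 2 > len(covs) and covs.shape[1] > 1:
        covs = covs.iloc[:, :-1]
    t_map, p_map, resid_maps, dof = icd_mod.voxelwise_model(
        beta_maps, covs, "phenotype", masks["gm"])
    clusters = icd_mod.cluster_correct(
        t_map, resid_maps, masks["gm"], dof, spec.affine,
        voxel_p=icfg["voxel_p"], cluster_p=icfg["cluster_p"],
        iters=icfg["cluster_iters"], voxel_size_mm=spec.voxel_size_mm,
        seed=seeds["cluster"])
    out["icd"] = {"t_map": t_map, "clusters": clusters, "spec": spec}
    return {
        "spec": spec, "masks": masks, "subjects": sub,
        "residual_data": residual_data, "t_map": t_map,
        "clusters": clusters, "carriers": carriers[keep_rows],
        "summary": {
            "n_imaging": len(keep_rows),
            "n_clusters": len(clusters.clusters),
            "cluster_size_threshold": clusters.cluster_size_threshold,
        },
    }


def _network_stage(cfg, imaging, out):
    icfg = cfg["imaging"]
    spec = imaging["spec"]
    masks = imaging["masks"]
    clusters = imaging["clusters"]
    if clusters.clusters:
        seed_mask = np.zeros(spec.grid_shape, bool)
        vox = clusters.clusters[0]["voxels"]
        seed_mask[tuple(np.asarray(vox).T)] = True
    else:
        # fall back to the planted seed-node sphere
        seed_mask = sim.node_masks(spec)[0]
    z_maps = [net_mod.seed_corr_map(r, seed_mask, masks["gm"])
              for r in imaging["residual_data"]]
    t_map, net_mask = net_mod.group_network(z_maps, masks["gm"],
                                            p_thresh=icfg["network_p"])
    peaks = net_mod.find_peaks(t_map, net_mask, spec.affine,
                               min_sep_mm=icfg["min_sep_mm"])
    if not peaks:
        return {"summary": {"n_peaks": 0, "n_nodes": 0}}
    nodes = net_mod.build_node_set(peaks, spec.grid_shape, spec.affine,
                                   radius_mm=icfg["node_radius_mm"])
    vals = net_mod.node_values(z_maps, nodes)
    sub = imaging["subjects"]
    pool = pd.DataFrame({
        "age_months": sub["age_months"].to_numpy(float),
        "piq": sub["piq"].to_numpy(float),
        "sex_female": sub["sex_female"].to_numpy(float),
        "maternal_edu_years": sub["maternal_edu_years"].fillna(
            sub["maternal_edu_years"].mean()).to_numpy(float),
        "ses_low": sub["ses_low"].fillna(0).to_numpy(float),
    })
    while pool.shape[1] + 2 >= len(pool) and pool.shape[1] > 1:
        pool = pool.iloc[:, :-1]
    models = net_mod.analyze_network_nodes(
        vals, imaging["carriers"].astype(float), pool)
    out["network"] = {"nodes": nodes, "node_values": vals, "models": models,
                      "peaks": peaks}
    return {"summary": {"n_peaks": len(peaks), "n_nodes": len(nodes.labels)}}
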