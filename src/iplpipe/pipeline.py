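"""End-to-end orchestration with a single validated config and manifest.

Stages run in dependency order: simulate -> parcellate -> classify ->
connectivity -> ecperm.  One global seed is expanded into independent
per-stage seeds through a fixed splitting scheme (numpy SeedSequence
spawning), so any stage can be reproduced in isolation.  Every run writes
a manifest (config hash, per-stage seeds and wall times, package version,
warnings) sufficient to reproduce the outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classify, connectivity, ecperm, io, parcellation
from . import synthetic as syn

logger = logging.getLogger(__name__)

STAGES = ("simulate", "parcellate", "classify", "connectivity", "ecperm")

DEFAULTS: dict = {
    "seed": 0,
    "n_subjects": 22,
    "n_runs": 12,
    "accuracy": 0.95,
    "roi_shape": [10, 11, 10],
    "anterior_fraction": 0.5,
    "effect": 1.0,
    "noise_sd": 1.0,
    "subject_sd": 0.5,
    "n_parcels": 400,
    "coupling_rho": 0.5,
    "k_min": 2,
    "k_max": 7,
    "n_init": 1000,
    "stability_threshold": 1.0,
    "C": 1.0,
    "alpha": 0.05,
    "conn_n_perm": 5000,
    "ec_n_perm": 10000,
    "ec_percentile": 99.9,
    "ec_subject_sd": 0.5,
}


def validate_config(config: dict | None) -> dict:
    """Fill defaults and reject contradictory or out-of-range settings.

    Error messages name the offending field.
    """
    cfg = dict(DEFAULTS)
    config = config or {}
    unknown = sorted(set(config) - set(DEFAULTS))
    if unknown:
        raise ValueError(f"unknown config field(s): {unknown}")
    cfg.update(config)
    if not 0.0 < cfg["alpha"] < 1.0:
        raise ValueError(f"alpha: must be in (0, 1), got {cfg['alpha']}")
    if not 0.0 < cfg["ec_percentile"] < 100.0:
        raise ValueError(f"ec_percentile: must be in (0, 100), got {cfg['ec_percentile']}")
    if cfg["k_min"] < 2 or cfg["k_max"] < cfg["k_min"]:
        raise ValueError(f"k range: need 2 <= k_min <= k_max, got {cfg['k_min']}..{cfg['k_max']}")
    for fld in ("n_subjects", "n_runs", "n_parcels", "n_init", "conn_n_perm", "ec_n_perm"):
        if int(cfg[fld]) < 1:
            raise ValueError(f"{fld}: must be a positive integer, got {cfg[fld]}")
    if not 0.0 < cfg["anterior_fraction"] < 1.0:
        raise ValueError(f"anterior_fraction: must be in (0, 1), got {cfg['anterior_fraction']}")
    if not 0.0 < cfg["stability_threshold"] <= 1.0:
        raise ValueError(f"stability_threshold: must be in (0, 1], got {cfg['stability_threshold']}")
    for fld in ("noise_sd", "subject_sd", "ec_subject_sd"):
        if cfg[fld] < 0:
            raise ValueError(f"{fld}: must be >= 0, got {cfg[fld]}")
    if len(cfg["roi_shape"]) != 3 or any(int(s) <= 0 for s in cfg["roi_shape"]):
        raise ValueError(f"roi_shape: must be three positive integers, got {cfg['roi_shape']}")
    return cfg


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the global seed."""
    children = np.random.SeedSequence(int(seed)).spawn(len(STAGES))
    return {
        stage: int(ss.generate_state(1)[0] % (2**31))
        for stage, ss in zip(STAGES, children)
    }


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict | None, outdir, stages=STAGES) -> dict:
    """Execute the selected stages; returns the run manifest (also written
    to ``<outdir>/manifest.json``).

    A selected stage whose upstream outputs are absent from ``outdir`` is
    rejected naming the missing artifact.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg["seed"])
    unknown = sorted(set(stages) - set(STAGES))
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    stages = [s for s in STAGES if s in stages]
    manifest = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "seeds": seeds,
        "stages": {},
        "warnings": [],
    }
    for stage in stages:
        t0 = time.perf_counter()
        _STAGE_FNS[stage](cfg, outdir, seeds[stage])
        manifest["stages"][stage] = {"wall_time_s": round(time.perf_counter() - t0, 3)}
        logger.info("stage %s done in %.1fs", stage, manifest["stages"][stage]["wall_time_s"])
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def _require(outdir: Path, name: str, stage: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs upstream artifact {name!r}; run the producing stage first"
        )
    return path


def _stage_simulate(cfg, outdir: Path, seed: int) -> None:
    ss = np.random.SeedSequence(seed).spawn(5)
    design = syn.generate_full_design(
        n_runs=cfg["n_runs"], n_subjects=cfg["n_subjects"],
        seed=int(ss[0].generate_state(1)[0] % 2**31), accuracy=cfg["accuracy"]
    )
    io.write_tsv(design, outdir / "design.tsv", seed=seed)
    rois = syn.generate_roi(tuple(cfg["roi_shape"]), cfg["anterior_fraction"], mirrored=True)
    left, right, labels = rois
    spec = syn.EffectSpec.default(
        effect=cfg["effect"], noise_sd=cfg["noise_sd"], subject_sd=cfg["subject_sd"]
    )
    betas = syn.generate_both_hemispheres(design, rois, spec, seed=int(ss[1].generate_state(1)[0] % 2**31))
    for hemi, mask in (("left", left), ("right", right)):
        io.write_mask_nifti(mask, outdir / f"mask_{hemi}.nii.gz", values=labels[hemi])
        io.write_matrix_tsv(
            np.round(betas[hemi].data, 6), outdir / f"betas_{hemi}.tsv",
            columns=[f"v{i}" for i in range(mask.n_voxels)], seed=seed,
        )
    # parcel series coupled to the *planted* subregion means
    sub_series = _planted_subregion_series(betas, labels)
    cspec = syn.CouplingSpec.default(n_parcels=cfg["n_parcels"], rho=cfg["coupling_rho"])
    parcels = syn.generate_parcel_betas(design, sub_series, cspec, seed=int(ss[2].generate_state(1)[0] % 2**31))
    io.write_matrix_tsv(
        np.round(parcels, 6), outdir / "parcel_betas.tsv",
        columns=[f"p{i}" for i in range(cfg["n_parcels"])], seed=seed,
    )
    io.write_tsv(cspec.lookup, outdir / "parcel_networks.tsv")
    truth = syn.ModulationTruth.default(subject_sd=cfg["ec_subject_sd"])
    mods = syn.generate_modulations(truth, n_subjects=cfg["n_subjects"], seed=int(ss[3].generate_state(1)[0] % 2**31))
    io.write_tsv(mods.to_frame(), outdir / "modulations.tsv", seed=seed)


def _planted_subregion_series(betas: dict, labels: dict) -> pd.DataFrame:
    cols = {}
    for hemi, prefix in (("left", "L"), ("right", "R")):
        for code, short in ((1, "ant"), (2, "post")):
            sel = labels[hemi] == code
            cols[f"{prefix}-{short}"] = betas[hemi].data[:, sel].mean(axis=1)
    df = betas["left"].table.copy()
    for name in syn.SUBREGIONS:
        df[name] = cols[name]
    return df


def _load_betas(cfg, outdir: Path, stage: str):
    design = io.read_tsv(_require(outdir, "design.tsv", stage))
    design["correct"] = design["correct"].astype("boolean")
    betas = {}
    for hemi in ("left", "right"):
        mask, labels = io.mask_from_nifti(_require(outdir, f"mask_{hemi}.nii.gz", stage), hemi)
        data = io.read_matrix_tsv(_require(outdir, f"betas_{hemi}.tsv", stage))
        betas[hemi] = syn.TrialBetaMatrix(data=data, table=design, mask=mask, planted_labels=labels)
    return design, betas


def _stage_parcellate(cfg, outdir: Path, seed: int) -> None:
    _, betas = _load_betas(cfg, outdir, "parcellate")
    ss = np.random.SeedSequence(seed).spawn(2)
    summary = []
    for hemi, child in zip(("left", "right"), ss):
        feats = parcellation.build_features(betas[hemi])
        res = parcellation.parcellate(
            feats,
            k_range=(cfg["k_min"], cfg["k_max"]),
            n_init=cfg["n_init"],
            stability_threshold=cfg["stability_threshold"],
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        parc = res.parcellation
        io.write_mask_nifti(betas[hemi].mask, outdir / f"parcellation_{hemi}.nii.gz",
                            values=parc.label_volume()[tuple(betas[hemi].mask.coords.T)])
        votes = res.votes.values.copy()
        votes.insert(0, "index", votes.index)
        io.write_tsv(votes.reset_index(drop=True), outdir / f"votes_{hemi}.tsv", seed=seed)
        com = parcellation.centers_of_mass(parc)
        com.insert(0, "hemisphere", hemi)
        com["k_star"] = res.k_star
        com["agreement_pct"] = res.agreement
        com["n_unstable"] = int((~parc.stable).sum())
        summary.append(com)
    io.write_tsv(pd.concat(summary, ignore_index=True), outdir / "parcellation_summary.tsv", seed=seed)


def _load_parcellations(cfg, outdir: Path, stage: str):
    _, betas = _load_betas(cfg, outdir, stage)
    parcs = {}
    for hemi in ("left", "right"):
        vol, _ = io.read_label_nifti(_require(outdir, f"parcellation_{hemi}.nii.gz", stage))
        mask = betas[hemi].mask
        codes = vol[tuple(mask.coords.T)]
        parcs[hemi] = parcellation.Parcellation(
            labels=np.where(codes > 0, codes, 1).astype(np.int32),
            stable=codes > 0,
            stability=(codes > 0).astype(float),
            k=2,
            mask=mask,
            names={1: "anterior", 2: "posterior"},
        )
    return betas, parcs


def _stage_classify(cfg, outdir: Path, seed: int) -> None:
    betas, parcs = _load_parcellations(cfg, outdir, "classify")
    feats = classify.aggregate_subregions(betas, parcs)
    report, signature = classify.loso_crossvalidate(feats, seed=seed, C=cfg["C"])
    io.write_json(
        {
            "overall_accuracy_pct": report.overall_accuracy,
            "per_task_accuracy_pct": report.per_task_accuracy,
            "chance_level_pct": report.chance_level,
            "n_test_trials": report.n_test_trials,
            "confusion": report.confusion.to_dict(),
        },
        outdir / "cv_report.json",
    )
    sig = signature.weights.copy()
    sig.insert(0, "task", sig.index)
    sig["intercept"] = signature.intercepts
    io.write_tsv(sig.reset_index(drop=True), outdir / "signature.tsv", seed=seed)


def _stage_connectivity(cfg, outdir: Path, seed: int) -> None:
    betas, parcs = _load_parcellations(cfg, outdir, "connectivity")
    design = betas["left"].table
    parcels = io.read_matrix_tsv(_require(outdir, "parcel_betas.tsv", "connectivity"))
    lookup = io.read_tsv(_require(outdir, "parcel_networks.tsv", "connectivity"))
    # subregion series over all trials, from the estimated parcellation
    series = {}
    for hemi, prefix in (("left", "L"), ("right", "R")):
        parc = parcs[hemi]
        for code, nm in parc.names.items():
            sel = parc.stable & (parc.labels == code)
            series[f"{prefix}-{'ant' if nm == 'anterior' else 'post'}"] = betas[hemi].data[:, sel].mean(axis=1)
    sub_series = np.column_stack([series[s] for s in syn.SUBREGIONS])
    tensor = connectivity.taskwise_correlation(sub_series, parcels, design)
    null = connectivity.permutation_baseline(
        sub_series, parcels, design, n_perm=cfg["conn_n_perm"], seed=seed
    )
    tensor = connectivity.significant_shifts(tensor, null, alpha=cfg["alpha"])
    io.write_tsv(tensor.to_frame(), outdir / "connectivity.tsv", seed=seed)
    io.write_tsv(connectivity.network_aggregate(tensor, lookup), outdir / "network_summary.tsv", seed=seed)


def _stage_ecperm(cfg, outdir: Path, seed: int) -> None:
    mods = syn.ModulationSet.from_frame(io.read_tsv(_require(outdir, "modulations.tsv", "ecperm")))
    result = ecperm.permutation_test(
        mods, n_perm=cfg["ec_n_perm"], percentile=cfg["ec_percentile"], seed=seed
    )
    io.write_tsv(result.table, outdir / "ec_test.tsv", seed=seed)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "parcellate": _stage_parcellate,
    "classify": _stage_classify,
    "connectivity": _stage_connectivity,
    "ecperm": _stage_ecperm,
}
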