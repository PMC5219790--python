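"""End-to-end pipeline orchestration: simulate -> qc -> cluster -> test -> report.

Every stage writes plain TSV/CSV/JSON artifacts into the output directory and
the run closes with a manifest (inputs, parameters, seeds, output hashes).
Reruns with the same configuration and seed are bit-identical; nothing
wall-clock-dependent is recorded.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import cluster_condition_scan
from .coexpression import (delta_coexpression, focal_coexpression,
                           preranked_enrichment, read_gmt, write_gmt)
from .imaging import classify_stain, detect_blobs, detection_table, track_motility
from .io import sha256_of, write_expression, write_json, write_metadata
from .qc import QCConfig, filter_cells, tpm_normalize
from .rankprod import rank_product_test
from .simulate import SimulatedExperiment, iter_chamber_images, simulate_experiment, study_config
from .states import UNASSIGNED, discover_states

__all__ = ["default_pipeline_config", "load_pipeline_config", "run_pipeline"]


def default_pipeline_config() -> dict:
    return {
        "sim": {"with_states": True, "with_effects": True,
                "n_bulk_controls_per_chip": 2, "doublet_rate": 0.02,
                "low_cdna_rate": 0.02},
        "qc": {"cdna_floor": 0.05, "bulk_rule": True},
        "cluster": {"dims": 5, "k_max": 6, "min_cells": 3, "replicate_fraction": 0.5},
        "de": {"contrast_col": "genotype", "levels": ["WT", "KO"],
               "condition_on": "cluster", "min_cells": 3, "fdr": 0.05},
        "coexpress": {"focal": "auto", "n_perm": 200, "weight_exponent": 1.0,
                      "min_cells": 10},
        "imaging": {"enabled": True, "top_n": 30, "min_size": 4},
        "associate": {"by": ["media", "lps", "genotype", "time_h"], "level": 0.95},
    }


def load_pipeline_config(path) -> dict:
    config = default_pipeline_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if section not in config:
            raise ValueError(f"unknown configuration section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"configuration section {section!r} must be a mapping")
        config[section].update(values)
    return config


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _run_simulate(config, out, seed) -> SimulatedExperiment:
    sim = simulate_experiment(study_config(seed=seed, **config["sim"]))
    write_expression(sim.expression, out, fmt="mtx")
    sim.gene_lengths.to_csv(out / "gene_lengths.tsv", sep="\t", float_format="%.10g")
    write_metadata(sim.metadata, out / "meta.csv")
    write_json(sim.truth.to_jsonable(), out / "truth.json")
    # gene sets for the enrichment stage: state programs + effect genes + decoys
    sets = {f"program_{s}": sorted(p) for s, p in sim.truth.state_programs.items() if p}
    if sim.truth.true_global_de:
        sets["global_shift_genes"] = sorted(sim.truth.true_global_de)
    rng = np.random.default_rng([seed, 53])
    all_genes = np.array(sim.expression.gene_ids)
    for i in range(3):
        sets[f"random_set_{i}"] = sorted(rng.choice(all_genes, size=50, replace=False).tolist())
    write_gmt(sets, out / "sets.gmt")
    return sim


@_stage("qc")
def _run_qc(sim, config, out):
    tpm = tpm_normalize(sim.expression, sim.gene_lengths)
    filtered, report = filter_cells(tpm, sim.metadata, QCConfig(**config["qc"]))
    report.per_cell.to_csv(out / "qc_report.tsv", sep="\t")
    return filtered


@_stage("cluster")
def _run_cluster(tpm_expr, meta, config, out, seed):
    frame = tpm_expr.to_frame()
    result = discover_states(frame, meta.loc[frame.columns], random_state=seed,
                             **config["cluster"])
    for t, emb in result["embeddings"].items():
        pd.DataFrame(emb.coords, index=emb.cell_ids,
                     columns=[f"dim{i+1}" for i in range(emb.coords.shape[1])]
                     ).to_csv(out / f"embedding_t{t}.tsv", sep="\t", float_format="%.10g")
        cm = result["consensus"][t]
        pd.DataFrame(cm.values, index=cm.cell_ids, columns=cm.cell_ids
                     ).to_csv(out / f"consensus_t{t}.tsv", sep="\t", float_format="%.6g")
        result["assignments"][t].replication_table.to_csv(
            out / f"replication_t{t}.tsv", sep="\t")
    labels = result["labels"]
    pd.DataFrame({"cell_id": labels.index, "cluster": labels.to_numpy(),
                  "chip": meta.loc[labels.index, "chip"].to_numpy()}
                 ).to_csv(out / "assignment.csv", index=False)
    if "matching" in result:
        result["matching"].to_csv(out / "cluster_matching.tsv", sep="\t", index=False)
    return labels


@_stage("de")
def _run_de(tpm_expr, meta, labels, config, out):
    frame = np.log2(tpm_expr.to_frame() + 1.0)
    meta = meta.loc[frame.columns].copy()
    subtype_col = config["de"]["condition_on"]
    if subtype_col == "cluster":
        meta["cluster"] = labels.reindex(frame.columns)
        keep = meta.index[meta["cluster"] != UNASSIGNED]
        frame, meta = frame[keep], meta.loc[keep]
    res = rank_product_test(
        frame, meta,
        contrast=(config["de"]["contrast_col"], tuple(config["de"]["levels"])),
        subtype_col=subtype_col,
        min_cells=config["de"]["min_cells"],
        fdr=config["de"]["fdr"],
    )
    res.table.to_csv(out / "de_per_direction.tsv", sep="\t", index=False,
                     float_format="%.6g")
    res.summary.to_csv(out / "de_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
    return res


@_stage("coexpress")
def _run_coexpress(tpm_expr, meta, labels, de_result, config, out, seed):
    frame = np.log2(tpm_expr.to_frame() + 1.0)
    meta = meta.loc[frame.columns]
    cfg = config["coexpress"]
    focal = cfg["focal"]
    if focal == "auto":
        mad = de_result.summary[de_result.summary["test"] == "mad"]
        focal = mad.sort_values(["q", "p_two_sided", "gene_id"]).iloc[0]["gene_id"]
    lab = labels.reindex(frame.columns)
    at8 = meta["time_h"] == 8
    counts = lab[at8 & (lab != UNASSIGNED)].value_counts()
    if counts.empty:
        warnings.warn("no clustered 8 h cells; coexpression stage skipped")
        return None
    cluster = counts.index[0]
    cells = meta.index[(lab == cluster) & at8]
    ko = [c for c in cells if meta.loc[c, "genotype"] == "KO"]
    wt = [c for c in cells if meta.loc[c, "genotype"] == "WT"]
    if min(len(ko), len(wt)) < cfg["min_cells"]:
        warnings.warn("too few KO or WT cells for differential coexpression; skipped")
        return None
    prof_ko = focal_coexpression(frame, ko, focal, min_cells=cfg["min_cells"])
    prof_wt = focal_coexpression(frame, wt, focal, min_cells=cfg["min_cells"])
    delta = delta_coexpression(prof_ko, prof_wt)
    delta.rename("delta_rho").to_csv(out / "delta_coexpression.rnk", sep="\t",
                                     header=False, float_format="%.6g")
    sets = read_gmt(out / "sets.gmt")
    rows = []
    for name, members in sorted(sets.items()):
        res = preranked_enrichment(delta, members, set_name=name,
                                   weight_exponent=cfg["weight_exponent"],
                                   n_perm=cfg["n_perm"], seed=seed)
        if res is not None:
            rows.append({"gene_set": name, "es": res.es, "p": res.p,
                         "n_overlap": res.n_overlap, "n_perm": res.n_perm})
    pd.DataFrame(rows, columns=["gene_set", "es", "p", "n_overlap", "n_perm"]
                 ).to_csv(out / "enrichment.tsv", sep="\t", index=False,
                          float_format="%.6g")
    return focal


@_stage("image")
def _run_imaging(sim, config, out):
    cfg = config["imaging"]
    det_rows = []
    track_rows = []
    stain_rows = []
    for chamber_id, channels, _cells in iter_chamber_images(sim.config):
        for channel in ("orange", "green"):
            images = list(channels[channel].values())
            table = detection_table(images, top_n=cfg["top_n"], min_size=cfg["min_size"])
            det_rows.append(table)
        orange_by_t = {t: detect_blobs(img, cfg["top_n"], cfg["min_size"])
                       for t, img in channels["orange"].items()}
        if sum(1 for b in orange_by_t.values() if b) >= 2:
            track = track_motility(orange_by_t, pixel_size_um=sim.config.imaging.pixel_size_um)
            for (t0, _), d_px, d_um in zip(track.centroids[:-1], track.displacements_px,
                                           track.displacements_um):
                track_rows.append({"chamber_id": chamber_id, "from_t": t0,
                                   "displacement_px": d_px, "displacement_um": d_um})
        t0 = min(channels["orange"])
        scheme = {"double": sim.metadata.loc[chamber_id, "stain_scheme"].split("=")[1]}
        labels, anomalies = classify_stain(
            detect_blobs(channels["orange"][t0], cfg["top_n"], cfg["min_size"]),
            detect_blobs(channels["green"][t0], cfg["top_n"], cfg["min_size"]),
            scheme,
        )
        for li, lab in enumerate(labels):
            stain_rows.append({"chamber_id": chamber_id, "blob_id": li,
                               "genotype_call": lab, "n_green_anomalies": len(anomalies)})
    nonempty = [t for t in det_rows if not t.empty]
    det_table = (pd.concat(nonempty, ignore_index=True) if nonempty else det_rows[0])
    det_table.to_csv(out / "detections.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(track_rows, columns=["chamber_id", "from_t", "displacement_px",
                                      "displacement_um"]
                 ).to_csv(out / "tracks.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(stain_rows, columns=["chamber_id", "blob_id", "genotype_call",
                                      "n_green_anomalies"]
                 ).to_csv(out / "stain_calls.tsv", sep="\t", index=False)


@_stage("associate")
def _run_associate(labels, meta, config, out):
    scan = cluster_condition_scan(labels, meta.loc[labels.index],
                                  by=config["associate"]["by"],
                                  level=config["associate"]["level"])
    scan.to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.6g")
    return scan


def run_pipeline(config: dict | str | Path | None, out_dir, seed: int = 0) -> dict:
    """Execute every stage on a synthetic experiment; returns the manifest."""
    if config is None:
        config = default_pipeline_config()
    elif not isinstance(config, dict):
        config = load_pipeline_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = _run_simulate(config, out, seed)
    tpm = _run_qc(sim, config, out)
    meta = sim.metadata
    labels = _run_cluster(tpm, meta, config, out, seed)
    de_result = _run_de(tpm, meta, labels, config, out)
    focal = _run_coexpress(tpm, meta, labels, de_result, config, out, seed)
    if config["imaging"]["enabled"]:
        _run_imaging(sim, config, out)
    _run_associate(labels, meta.loc[labels.index], config, out)

    outputs = sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "scgxe",
        "version": __version__,
        "seed": seed,
        "config": config,
        "sim_config": dataclasses.asdict(sim.config),
        "focal_gene": focal,
        "stages": ["simulate", "qc", "cluster", "de", "coexpress",
                   "image" if config["imaging"]["enabled"] else None, "associate"],
        "outputs": {name: sha256_of(out / name) for name in outputs},
    }
    manifest["stages"] = [s for s in manifest["stages"] if s]
    write_json(manifest, out / "manifest.json")
    return manifest
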