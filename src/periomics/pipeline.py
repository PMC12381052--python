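"""End-to-end orchestration: simulate/load -> filter -> ordination ->
PERMANOVA/PERMDISP -> CAP -> differential -> pathways -> ecology -> biomarkers.

Every run resolves a :class:`PipelineConfig` (whose defaults are the
workflow's standard operating values), derives all stage seeds from one
root seed, and writes per-stage TSV/JSON outputs plus a resolved-config
snapshot so that a run is fully replayable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from periomics import __version__
from periomics.biomarkers import assemble_datasets, biomarker_report, rf_evaluate, rfe
from periomics.cap import cap_fit, save_model
from periomics.differential import differential_table, volcano_select
from periomics.ec import aggregate_to_ec, read_annotations, taxon_resolved_ec
from periomics.ecology import activity_folds, classify_roles, export_network
from periomics.ordination import bray_curtis, nmds, pcoa
from periomics.pathways import load_pathways, pathway_matrix
from periomics.permtests import permanova, permdisp
from periomics.simulate import SimulationConfig, simulate_cohort
from periomics.tables import (FeatureTable, aggregate_rank, log1p_transform,
                              prevalence_filter, read_metadata, read_table,
                              to_relative, write_table)

log = logging.getLogger("periomics")


@dataclass
class PipelineConfig:
    """Resolved parameters of a full run; defaults are the working values."""

    # inputs: either a simulation seed or paths to real tables
    simulate: bool = True
    dna_table: str | None = None
    rna_gene_table: str | None = None
    annotations: str | None = None
    metadata: str | None = None
    pathway_file: str | None = None
    # stage parameters
    min_rel: float = 0.001
    min_samples: int = 1
    n_perm: int = 99_999
    strata: str | None = "patient_id"
    m_grid_max: int = 30
    r_cut: float = 0.4
    p_cut: float = 0.001
    ecology_threshold: float = 1.5
    rf_repeats: int = 20
    rf_folds: int = 10
    rf_trees: int = 500
    rf_tune: bool = True
    rfe_step: int = 10
    rf_datasets: tuple[str, ...] = ("species", "genus", "EC",
                                    "species+EC", "genus+EC")
    seed: int = 0
    sim: SimulationConfig | None = None

    def resolved(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


def _prep(table: FeatureTable, cfg: PipelineConfig):
    """filter -> relative -> log1p -> Bray-Curtis, the standard transform."""
    filtered, report = prevalence_filter(table, cfg.min_rel, cfg.min_samples)
    rel = to_relative(filtered) if filtered.scale == "counts" else filtered
    logged = log1p_transform(rel)
    return logged, rel, bray_curtis(logged), report


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Execute the whole workflow and write a report bundle to *outdir*."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    seeds = {k: int(rng.integers(2**31)) for k in
             ("permanova", "permdisp", "nmds", "rf", "rfe")}
    report: dict = {"seed": cfg.seed, "version": __version__}

    # --- inputs ----------------------------------------------------------
    if cfg.simulate:
        sim = cfg.sim or SimulationConfig(seed=cfg.seed)
        dna, rna_genes, ann, tensor, pathways, metadata, truth = simulate_cohort(sim)
        truth.to_json(out / "truth.json")
    else:
        for name in ("dna_table", "rna_gene_table", "annotations",
                     "metadata", "pathway_file"):
            if getattr(cfg, name) is None:
                raise FileNotFoundError(f"stage=inputs: config lacks {name}")
        dna = read_table(cfg.dna_table)
        rna_genes = read_table(cfg.rna_gene_table)
        ann = read_annotations(cfg.annotations)
        metadata = read_metadata(cfg.metadata)
        pathways = load_pathways(cfg.pathway_file)
        tensor = taxon_resolved_ec(rna_genes, ann, taxon_rank="class")
    metadata.validate_against(dna)
    diag = metadata.diagnosis(dna.sample_ids)
    strata = metadata.patients(dna.sample_ids) if cfg.strata else None

    # --- DNA block: species and genus ------------------------------------
    blocks = {}
    for block_name, table in (("species", dna),
                              ("genus", aggregate_rank(dna, "genus"))):
        logged, rel, dm, filt = _prep(table, cfg)
        report[f"{block_name}_filter"] = filt
        write_table(logged, out / f"{block_name}_log1p.tsv")
        perma = permanova(dm, diag, strata=strata, n_perm=cfg.n_perm,
                          seed=seeds["permanova"])
        disp = permdisp(dm, diag, n_perm=min(cfg.n_perm, 9999),
                        seed=seeds["permdisp"])
        ords = pcoa(dm)
        ords.coordinates.to_csv(out / f"{block_name}_pcoa.tsv", sep="\t")
        nm = nmds(dm, seed=seeds["nmds"])
        nm.coordinates.to_csv(out / f"{block_name}_nmds.tsv", sep="\t")
        model = cap_fit(dm, diag)
        save_model(model, out / f"cap_{block_name}")
        blocks[block_name] = (logged, model)
        report[block_name] = {
            "permanova_p": perma.p_value, "permanova_F": perma.statistic,
            "permdisp_p": disp.p_value, "cap_delta_sq1": float(model.delta_sq[0]),
            "cap_m": model.m, "cap_loo_success": model.loo_success,
            "nmds_stress": nm.stress,
        }
        log.info("%s: PERMANOVA p=%.4g, CAP delta^2=%.3f, LOO=%.2f",
                 block_name, perma.p_value, model.delta_sq[0], model.loo_success)

    # --- RNA block: EC4 ---------------------------------------------------
    ec4 = aggregate_to_ec(rna_genes, ann, level=4)
    logged_ec, rel_ec, dm_ec, filt_ec = _prep(ec4, cfg)
    report["EC_filter"] = filt_ec
    ec_model = cap_fit(dm_ec, diag)
    save_model(ec_model, out / "cap_EC")
    blocks["EC"] = (logged_ec, ec_model)
    diff = differential_table(logged_ec, metadata, ec_model,
                              r_cut=cfg.r_cut, p_cut=cfg.p_cut)
    diff.to_csv(out / "differential_ec.tsv", sep="\t")
    selected = volcano_select(diff, cfg.r_cut, cfg.p_cut)
    report["EC"] = {
        "cap_delta_sq1": float(ec_model.delta_sq[0]),
        "cap_loo_success": ec_model.loo_success,
        "n_selected": {k: len(v) for k, v in selected.items()},
    }

    # --- pathways + ecology ----------------------------------------------
    pw_matrix = pathway_matrix(rel_ec, pathways)
    write_table(pw_matrix, out / "pathway_abundance.tsv")
    if pw_matrix.n_features:
        dm_pw = bray_curtis(log1p_transform(to_relative(pw_matrix)))
        perma_pw = permanova(dm_pw, diag.loc[list(dm_pw.ids)], strata=None,
                             n_perm=min(cfg.n_perm, 9999),
                             seed=seeds["permanova"])
        report["pathways"] = {"permanova_p": perma_pw.p_value}
    folds = activity_folds(tensor, pathways, group_by="diagnosis",
                           metadata=metadata)
    net = classify_roles(folds, threshold=cfg.ecology_threshold)
    export_network(net, out / "ecology_network.tsv", fmt="tsv")
    export_network(net, out / "ecology_network.graphml", fmt="graphml")
    report["ecology"] = {"n_edges": int(len(net.edges))}

    # --- biomarkers -------------------------------------------------------
    datasets = assemble_datasets(blocks, metadata, r_cut=cfg.r_cut)
    rf_report = {}
    for name in cfg.rf_datasets:
        if name not in datasets or datasets[name].n_features == 0:
            continue
        ev = rf_evaluate(datasets[name], repeats=cfg.rf_repeats,
                         folds=cfg.rf_folds, seed=seeds["rf"],
                         n_trees=cfg.rf_trees, tune=cfg.rf_tune)
        rf_report[name] = {"mean_auc": ev.mean_auc,
                           "loocv_accuracy": ev.loocv_accuracy,
                           "n_features": datasets[name].n_features}
        if name == "species+EC":
            rfe_ev = rfe(datasets[name], step=cfg.rfe_step,
                         folds=cfg.rf_folds, seed=seeds["rfe"],
                         n_trees=cfg.rf_trees)
            rfe_ev.rfe_profile.to_csv(out / "rfe_profile.tsv", sep="\t")
            rf_report[name]["rfe_optimal_size"] = rfe_ev.optimal_size
            top = biomarker_report(ev, diff)
            top.to_csv(out / "biomarkers.tsv", sep="\t")
    report["random_forest"] = rf_report

    (out / "config.json").write_text(json.dumps(cfg.resolved(), indent=1,
                                                default=str))
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
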