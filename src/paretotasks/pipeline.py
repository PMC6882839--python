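"""End-to-end run orchestration: simulate -> fit -> downstream stages.

Every stage writes machine-readable TSV tables plus a JSON manifest
recording the seed, shuffle counts, and package version, so a config
plus seed reproduces a run bit-for-bit and reported p-values are
auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

import paretotasks
from paretotasks.config import RunConfig
from paretotasks.enrichment import bin_by_distance, enrichment_table, pathway_scores
from paretotasks.io import (
    read_expression_matrix,
    read_gmt,
    read_table,
    write_expression_matrix,
    write_gmt,
    write_table,
)
from paretotasks.mutations import align_alterations
from paretotasks.parti import select_k
from paretotasks.preprocess import ExpressionMatrix, center_genes, filter_primary, pca
from paretotasks.synthetic import (
    ClinicalSpec,
    DriverSpec,
    DrugSpec,
    generate_alterations,
    generate_clinical,
    generate_drug_panel,
    generate_gene_sets,
    generate_single_cells,
    generate_tumors,
    make_truth,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_manifest(out: Path, config: RunConfig, extra: dict) -> None:
    manifest = {
        "version": paretotasks.__version__,
        "seed": config.seed,
        "n_shuffles_tratio": config.n_shuffles_tratio,
        "n_shuffles_alignment": config.n_shuffles_alignment,
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def stage_simulate(config: RunConfig, out: Path) -> None:
    """Generate a synthetic cohort with planted structure and write all tables."""
    seed = config.stage_seed("simulate")
    k = 3
    truth = make_truth(
        n_samples=400,
        n_archetypes=k,
        n_genes=200,
        dirichlet_concentration=0.3,
        noise_sd=0.2,
        driver_specs=[
            DriverSpec("DRIVER_A0", 0.25, 0, 1.0, in_front=True, label="driver"),
            DriverSpec("PASSENGER_0", 0.25, 0, 1.0, in_front=False, label="passenger"),
        ],
        drug_specs=[
            DrugSpec("DRUG_A0", 0, baseline_aoc=1.0, decay_slope=0.15, noise_sd=0.05),
            DrugSpec("CONTROL_DRUG", None, baseline_aoc=0.6, noise_sd=0.05),
        ],
        clinical_specs=[
            ClinicalSpec("age_like", "continuous", 1, effect_size=2.0),
            ClinicalSpec("stage_like", "discrete", 2, effect_size=0.5),
        ],
        seed=seed,
    )
    expr = generate_tumors(truth)
    alterations, labels, expr = generate_alterations(truth, expr)
    clinical = generate_clinical(truth)
    sets = generate_gene_sets(truth)
    write_expression_matrix(expr, out / "expression.tsv")
    write_table(expr.metadata, out / "metadata.tsv")
    write_table(alterations, out / "alterations.tsv")
    write_table(labels, out / "alteration_labels.tsv")
    write_table(clinical, out / "clinical.tsv")
    write_gmt(sets, out / "gene_sets.gmt")
    # a small cell-line panel drawn from the same planted archetypes
    rng = np.random.default_rng([seed, 99])
    line_weights = rng.dirichlet([0.3] * truth.n_archetypes, size=56)
    lines = replace(
        truth,
        weights=line_weights,
        sample_types=np.zeros(56, dtype=int),
        driver_specs=[], clinical_specs=[],
        seed=seed + 1,
    )
    line_expr = generate_tumors(lines)
    line_expr.values.index = [f"LINE{i:03d}" for i in range(56)]
    line_expr.metadata.index = line_expr.values.index
    line_space = pca(center_genes(line_expr), truth.n_archetypes - 1)
    line_mean = line_expr.values.mean(axis=0).to_numpy()
    arch_coords = (truth.archetypes - line_mean) @ line_space.loadings.to_numpy()
    aoc = generate_drug_panel(lines, line_space.scores.to_numpy(), arch_coords,
                              missingness=0.05,
                              line_ids=list(line_expr.sample_ids))
    write_expression_matrix(line_expr, out / "cell_lines.tsv")
    write_table(aoc, out / "drug_aoc.tsv")
    # per-tumor single-cell clouds aligned with the inter-tumor axes
    tumor_space = pca(center_genes(filter_primary(expr)), truth.n_archetypes - 1)
    counts, covariates = generate_single_cells(
        truth, expr, tumor_space, n_tumors=6, cells_per_tumor=60,
        non_cancer_fraction=0.1,
    )
    write_table(counts, out / "single_cells.tsv")
    write_table(covariates, out / "cell_covariates.tsv")
    truth_record = {
        "n_archetypes": truth.n_archetypes,
        "noise_sd": truth.noise_sd,
        "sc_alignment": truth.sc_alignment,
        "seed": truth.seed,
        "archetype_blocks": {f"TASK_SET_{i}": b
                             for i, b in enumerate(truth.archetype_blocks)},
    }
    (out / "truth.json").write_text(json.dumps(truth_record, indent=2, sort_keys=True))
    _write_manifest(out, config, {"stage": "simulate"})


def stage_fit(config: RunConfig, out: Path) -> None:
    """Filter, center, run PCA, and select the polytope over k_range."""
    expr = read_expression_matrix(config.paths["expression"],
                                  metadata=read_table(config.paths["metadata"]))
    expr = filter_primary(expr)
    expr = center_genes(expr)
    max_k = max(config.k_range)
    # keep extra components beyond the fit space: the alignment stage
    # measures angles of effect vectors out of the front's plane
    n_comp = min(max(max_k - 1, config.n_pcs_alignment),
                 expr.n_samples - 1, expr.n_genes)
    space = pca(expr, n_comp)
    scores_by_k = {k: space.scores.to_numpy()[:, : k - 1] for k in config.k_range}
    fit = select_k(scores_by_k, config.k_range, alpha=config.significance_alpha,
                   n_shuffles=config.n_shuffles_tratio,
                   seed=config.stage_seed("fit"))
    write_table(space.scores, out / "pc_scores.tsv")
    write_table(space.loadings, out / "pc_loadings.tsv")
    result: dict = {"selected_k": None}
    if fit is not None:
        arch = pd.DataFrame(fit.archetypes,
                            columns=space.scores.columns[: fit.k - 1],
                            index=[f"A{i}" for i in range(fit.k)])
        write_table(arch, out / "archetypes_pc.tsv")
        back = arch.to_numpy() @ space.loadings.to_numpy()[:, : fit.k - 1].T
        write_table(pd.DataFrame(back, index=arch.index, columns=space.loadings.index),
                    out / "archetypes_genes.tsv")
        write_table(pd.DataFrame({"t_ratio": fit.null_t_ratios}),
                    out / "null_t_ratios.tsv")
        result = {"selected_k": fit.k, "t_ratio": fit.t_ratio,
                  "p_value": fit.p_value, "n_shuffles": fit.n_shuffles}
    (out / "fit.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    _write_manifest(out, config, {"stage": "fit", **result})


def stage_enrich(config: RunConfig, out: Path) -> None:
    """Enrichment tables for pathways and clinical features at each archetype."""
    expr = read_expression_matrix(config.paths["expression"],
                                  metadata=read_table(config.paths["metadata"]))
    expr = center_genes(filter_primary(expr))
    scores = read_table(config.paths["pc_scores"])
    archetypes = read_table(config.paths["archetypes_pc"]).to_numpy()
    d = archetypes.shape[1]
    binnings = [
        bin_by_distance(scores.iloc[:, :d], archetypes[a],
                        base_count=config.bin_base_count,
                        min_fraction=config.bin_min_fraction,
                        n_bins=config.n_peak_bins, archetype_id=a)
        for a in range(archetypes.shape[0])
    ]
    sets = read_gmt(config.paths["gene_sets"])
    pw = pathway_scores(expr, sets)
    write_table(enrichment_table(pw, binnings, "continuous", config.fdr_q),
                out / "enrichment_pathways.tsv")
    if "clinical" in config.paths:
        clinical = read_table(config.paths["clinical"])
        continuous = clinical.select_dtypes(include=[float])
        discrete = clinical.select_dtypes(include=[int, bool])
        if not continuous.empty:
            write_table(enrichment_table(continuous, binnings, "continuous",
                                         config.fdr_q),
                        out / "enrichment_clinical_continuous.tsv")
        if not discrete.empty:
            write_table(enrichment_table(discrete, binnings, "discrete",
                                         config.fdr_q),
                        out / "enrichment_clinical_discrete.tsv")
    _write_manifest(out, config, {"stage": "enrich"})


def stage_mutations(config: RunConfig, out: Path) -> None:
    """Front-alignment analysis of the alteration table."""
    scores = read_table(config.paths["pc_scores"])
    archetypes = read_table(config.paths["archetypes_pc"]).to_numpy()
    alterations = read_table(config.paths["alterations"])
    labels = (read_table(config.paths["alteration_labels"])
              if "alteration_labels" in config.paths else None)
    d = archetypes.shape[1]
    n_pcs = min(config.n_pcs_alignment, scores.shape[1])
    if n_pcs > d:  # embed the front plane in the larger PC space
        archetypes = np.hstack([archetypes, np.zeros((archetypes.shape[0],
                                                      n_pcs - d))])
    binnings = [
        bin_by_distance(scores.iloc[:, :d], archetypes[a][:d],
                        base_count=config.bin_base_count,
                        min_fraction=config.bin_min_fraction,
                        n_bins=config.n_peak_bins, archetype_id=a)
        for a in range(archetypes.shape[0])
    ]
    table = align_alterations(
        scores.iloc[:, :n_pcs], archetypes,
        alterations.reindex(scores.index), labels,
        n_shuffles=config.n_shuffles_alignment,
        seed=config.stage_seed("mutations"),
        fdr_q=config.fdr_q, binnings=binnings,
    )
    write_table(table, out / "alignment.tsv")
    _write_manifest(out, config, {"stage": "mutations"})


def stage_universal(config: RunConfig, out: Path) -> None:
    """Pool cancer types, fit universal archetypes, report type composition."""
    from paretotasks.universal import pool_and_fit, type_composition_near_archetypes

    expr = read_expression_matrix(config.paths["expression"],
                                  metadata=read_table(config.paths["metadata"]))
    expr = filter_primary(expr)
    cohorts = [
        ExpressionMatrix(expr.values.loc[idx], expr.metadata.loc[idx])
        for _, idx in expr.metadata.groupby("cancer_type").groups.items()
    ]
    fit, scores, types = pool_and_fit(
        cohorts, config.k_range, n_shuffles=config.n_shuffles_tratio,
        alpha=config.significance_alpha, seed=config.stage_seed("universal"),
    )
    write_table(scores, out / "pooled_pc_scores.tsv")
    result: dict = {"selected_k": None}
    if fit is not None:
        arch = pd.DataFrame(fit.archetypes,
                            columns=scores.columns[: fit.k - 1],
                            index=[f"A{i}" for i in range(fit.k)])
        write_table(arch, out / "universal_archetypes_pc.tsv")
        comp = type_composition_near_archetypes(
            scores.iloc[:, : fit.k - 1], types, fit.archetypes)
        write_table(comp, out / "type_composition.tsv")
        result = {"selected_k": fit.k, "t_ratio": fit.t_ratio, "p_value": fit.p_value}
    (out / "universal_fit.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    _write_manifest(out, config, {"stage": "universal", **result})


def stage_drugs(config: RunConfig, out: Path) -> None:
    """Project cell lines into tumor PC space and score the drug panel."""
    from paretotasks.drugs import (joint_quantile_normalize, project_cell_lines,
                                   score_drug_panel)

    tumors = read_expression_matrix(config.paths["expression"],
                                    metadata=read_table(config.paths["metadata"]))
    tumors = center_genes(filter_primary(tumors))
    lines = read_expression_matrix(config.paths["cell_lines"])
    lines_n, tumors_n = joint_quantile_normalize(lines, tumors)
    archetypes = read_table(config.paths["archetypes_pc"]).to_numpy()
    space = pca(center_genes(tumors_n), archetypes.shape[1])
    coords = project_cell_lines(lines_n, space)
    aoc = read_table(config.paths["drug_aoc"])
    arch_coords = read_table(config.paths["archetypes_pc"]).to_numpy()
    table = score_drug_panel(coords, arch_coords, aoc,
                             n_bins=config.n_drug_bins,
                             min_per_bin=config.min_lines_per_bin,
                             fdr_q=config.fdr_q)
    write_table(table.set_index("drug") if not table.empty else table,
                out / "drug_scores.tsv")
    _write_manifest(out, config, {"stage": "drugs"})


def stage_cells(config: RunConfig, out: Path) -> None:
    """Single-cell QC, marker exclusion, regression, and the variance ratio."""
    from paretotasks.heterogeneity import (exclude_by_markers, qc_filter,
                                           regress_covariates,
                                           shuffled_reference_control)

    counts = read_table(config.paths["single_cells"])
    covariates = read_table(config.paths["cell_covariates"])
    tumors = read_expression_matrix(config.paths["expression"],
                                    metadata=read_table(config.paths["metadata"]))
    tumors = center_genes(filter_primary(tumors))
    # synthetic gene universes are small; scale the detectable-gene gates
    g = counts.shape[1]
    counts = qc_filter(counts, min_genes=min(1500, g // 4), max_genes=max(8000, g))
    counts = exclude_by_markers(counts)
    log_expr = np.log2(counts + 1.0)
    residuals = regress_covariates(log_expr, covariates.loc[counts.index])
    table, p, control_mean = shuffled_reference_control(
        tumors.values, residuals, covariates["tumor_id"],
        m=config.n_pcs_heterogeneity, n_reps=5,
        seed=config.stage_seed("cells"),
    )
    write_table(table, out / "variance_ratios.tsv")
    summary = {"mean_ratio": float(table["ratio"].mean()),
               "mean_control_ratio": control_mean, "t_test_p": p}
    (out / "heterogeneity.json").write_text(json.dumps(summary, indent=2,
                                                       sort_keys=True))
    _write_manifest(out, config, {"stage": "cells", **summary})


_STAGES = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "enrich": stage_enrich,
    "universal": stage_universal,
    "mutations": stage_mutations,
    "drugs": stage_drugs,
    "cells": stage_cells,
}


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 stages: list[str] | None = None) -> Path:
    """Run the requested stages in order, writing into ``out_dir``.

    Defaults to simulate -> fit -> enrich -> mutations on the synthetic
    cohort, wiring each stage's outputs into the next stage's input
    paths. Any stage failure aborts with the stage name and cause.
    Identical config and seed produce byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = stages or ["simulate", "fit", "enrich", "mutations"]
    for stage in order:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    defaults = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "alterations": out / "alterations.tsv",
        "alteration_labels": out / "alteration_labels.tsv",
        "clinical": out / "clinical.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "pc_scores": out / "pc_scores.tsv",
        "archetypes_pc": out / "archetypes_pc.tsv",
        "cell_lines": out / "cell_lines.tsv",
        "drug_aoc": out / "drug_aoc.tsv",
        "single_cells": out / "single_cells.tsv",
        "cell_covariates": out / "cell_covariates.tsv",
    }
    for key, path in defaults.items():
        config.paths.setdefault(key, str(path))
    for stage in order:
        logger.info("running stage %s", stage)
        try:
            _STAGES[stage](config, out)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(stage, exc) from exc
    return out
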