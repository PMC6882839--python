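"""Intra-tumor heterogeneity versus inter-tumor diversity.

Single cells are QC-filtered, non-cancer cells excluded by marker
expression, technical covariates regressed out, and each tumor's cells
compared against the PC axes of a bulk tumor reference: the fraction of
within-tumor variance captured by the top-m reference PCs, divided by
the fraction captured by the cells' own top-m PCs (the upper bound, by
optimality of a tumor's own PCA). A ratio near 1 means intra-tumor
heterogeneity runs along the same expression axes as inter-tumor
diversity. The gene-resampling control destroys reference correlations
while preserving per-gene variances, and a paired t-test compares real
against control ratios across tumors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel

logger = logging.getLogger(__name__)


def detectable_genes(counts: pd.DataFrame) -> pd.Series:
    """Number of genes with nonzero counts per cell."""
    return (counts > 0).sum(axis=1)


def qc_filter(
    counts: pd.DataFrame,
    min_gene_cell_fraction: float = 0.05,
    min_genes: int = 1500,
    max_genes: int = 8000,
) -> pd.DataFrame:
    """Remove rarely detected genes, then outlier cells.

    Genes detected in fewer than ``min_gene_cell_fraction`` of cells are
    dropped first; cells whose detectable-gene count falls below
    ``min_genes`` or above ``max_genes`` are dropped second (the order
    matters and is logged). Idempotent in the common case where the cell
    filter does not push further genes under the detection fraction.
    """
    detected_frac = (counts > 0).mean(axis=0)
    keep_genes = detected_frac >= min_gene_cell_fraction
    filtered = counts.loc[:, keep_genes]
    n_genes_dropped = int((~keep_genes).sum())
    per_cell = detectable_genes(filtered)
    keep_cells = (per_cell >= min_genes) & (per_cell <= max_genes)
    out = filtered.loc[keep_cells]
    logger.info("qc_filter: dropped %d genes then %d cells",
                n_genes_dropped, int((~keep_cells).sum()))
    if out.empty:
        raise ValueError("no cells or genes survive QC")
    return out


def exclude_by_markers(
    counts: pd.DataFrame,
    markers: dict[str, list[str]] | None = None,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Drop cells expressing any non-cancer marker above ``threshold``.

    Default marker lists cover hematopoietic cells (PTPRC),
    cancer-associated fibroblasts (PDGFRA, ZEB1, ACTA2), and endothelial
    cells (PECAM1). Missing marker genes are logged and skipped.
    """
    if markers is None:
        markers = {
            "hematopoietic": ["PTPRC"],
            "CAF": ["PDGFRA", "ZEB1", "ACTA2"],
            "endothelial": ["PECAM1"],
        }
    exclude = pd.Series(False, index=counts.index)
    for cell_type, genes in markers.items():
        for gene in genes:
            if gene not in counts.columns:
                logger.info("marker %s (%s) absent; skipped", gene, cell_type)
                continue
            exclude |= counts[gene] > threshold
    return counts.loc[~exclude]


def regress_covariates(expr: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Residualize each gene on total count, mito fraction, and tumor id.

    The design has an intercept, the numeric covariates, and tumor
    indicator variables; a rank-deficient design is handled by the
    minimum-norm least-squares solution (collinear columns carry no
    unique coefficient but residuals are unaffected). Residuals are
    orthogonal to every design column.
    """
    cov = covariates.reindex(expr.index)
    if cov.isna().any().any():
        raise ValueError("covariates must be complete for every cell")
    design_parts = [np.ones((len(expr), 1))]
    for col in ("total_count", "mito_fraction"):
        if col in cov.columns:
            design_parts.append(cov[col].to_numpy(dtype=float)[:, None])
    if "tumor_id" in cov.columns:
        design_parts.append(pd.get_dummies(cov["tumor_id"], drop_first=True)
                            .to_numpy(dtype=float))
    design = np.hstack(design_parts)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning("covariate design rank-deficient (%d < %d); using "
                       "minimum-norm solution", rank, design.shape[1])
    y = expr.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ beta
    return pd.DataFrame(residuals, index=expr.index, columns=expr.columns)


def _top_pc_variance(x: np.ndarray, m: int) -> float:
    """Total variance captured by the top-m PCs of (already centered) x."""
    s = np.linalg.svd(x, compute_uv=False)
    return float(np.sum(s[:m] ** 2) / (x.shape[0] - 1))


def variance_explained_ratio(
    cells: pd.DataFrame,
    tumor_ids: pd.Series,
    reference_loadings: pd.DataFrame,
    m: int = 5,
) -> pd.DataFrame:
    """Per-tumor ratio of reference-PC variance to own-PC variance.

    Cells are restricted to genes shared with the reference and centered
    within tumor; the reference loadings are re-orthonormalized after
    the gene restriction. The numerator is the within-tumor variance of
    cell profiles projected onto the top-m reference PCs, the
    denominator the variance captured by the tumor's own top-m PCs —
    an upper bound, so the ratio lies in [0, 1]. Tumors with fewer than
    m + 1 cells are excluded (logged).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    shared = cells.columns.intersection(reference_loadings.index)
    if shared.empty:
        raise ValueError("no genes shared with the reference")
    ref = reference_loadings.loc[shared].to_numpy(dtype=float)[:, :m]
    q, _ = np.linalg.qr(ref)  # restriction breaks orthonormality
    rows = []
    for tumor, idx in cells.groupby(tumor_ids.reindex(cells.index)).groups.items():
        block = cells.loc[idx, shared].to_numpy(dtype=float)
        if block.shape[0] < m + 1:
            logger.info("tumor %s: %d cells < m+1; excluded", tumor, block.shape[0])
            continue
        centered = block - block.mean(axis=0)
        proj = centered @ q
        ref_var = float(np.sum(proj.var(axis=0, ddof=1)))
        own_var = _top_pc_variance(centered, m)
        rows.append({"tumor": tumor, "reference_fraction": ref_var,
                     "own_fraction": own_var,
                     "ratio": ref_var / own_var if own_var > 0 else np.nan})
    if not rows:
        raise ValueError("no tumor has enough cells for the requested m")
    return pd.DataFrame(rows).set_index("tumor")


def shuffled_reference_control(
    tumor_expr: pd.DataFrame,
    cells: pd.DataFrame,
    tumor_ids: pd.Series,
    m: int = 5,
    n_reps: int = 10,
    seed: int = 0,
    resample: str = "permute",
) -> tuple[pd.DataFrame, float, float]:
    """Gene-resampled reference control and paired t-test.

    Each repetition independently resamples every gene's expression
    column across reference tumors (permutation by default, preserving
    each gene's variance exactly; with-replacement resampling as an
    option), recomputes the reference PCs, and recomputes the per-tumor
    ratio. Returns (per-tumor mean control ratios, real-vs-control
    paired two-sided t-test p, mean control ratio).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    x = tumor_expr.to_numpy(dtype=float)
    real = variance_explained_ratio(cells, tumor_ids,
                                    _reference_loadings(x, tumor_expr.columns, m), m=m)
    controls = []
    for _ in range(n_reps):
        shuffled = np.empty_like(x)
        for j in range(x.shape[1]):
            if resample == "permute":
                shuffled[:, j] = x[rng.permutation(x.shape[0]), j]
            else:
                shuffled[:, j] = x[rng.integers(x.shape[0], size=x.shape[0]), j]
        ctrl_load = _reference_loadings(shuffled, tumor_expr.columns, m)
        controls.append(variance_explained_ratio(cells, tumor_ids, ctrl_load, m=m)["ratio"])
    control = pd.concat(controls, axis=1).mean(axis=1)
    common = real.index.intersection(control.index)
    stat = ttest_rel(real.loc[common, "ratio"], control.loc[common])
    out = real.copy()
    out["control_ratio"] = control
    return out, float(stat.pvalue), float(control.mean())


def _reference_loadings(x: np.ndarray, gene_ids, m: int) -> pd.DataFrame:
    centered = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return pd.DataFrame(vt[:m].T, index=gene_ids,
                        columns=[f"PC{j + 1}" for j in range(m)])


def pc_count_robustness(
    cells: pd.DataFrame,
    tumor_ids: pd.Series,
    tumor_expr: pd.DataFrame,
    m_values: list[int],
) -> pd.DataFrame:
    """Mean variance-explained ratio as a function of the PC count m."""
    x = tumor_expr.to_numpy(dtype=float)
    rows = []
    for m in m_values:
        loadings = _reference_loadings(x, tumor_expr.columns, m)
        table = variance_explained_ratio(cells, tumor_ids, loadings, m=m)
        rows.append({"m": m, "mean_ratio": float(table["ratio"].mean()),
                     "n_tumors": len(table)})
    return pd.DataFrame(rows).set_index("m")
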