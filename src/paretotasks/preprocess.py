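"""Expression-matrix transforms preceding the geometry.

All downstream geometry operates on per-gene-centered log2 expression:
entries are log2 fold changes of a gene in a sample relative to the
cohort (or cancer-type) mean of that gene. PCA is covariance-based
(unscaled), so large correlated expression changes dominate the leading
components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: metadata value marking primary tumors (mirrors the TCGA annotation)
PRIMARY_TUMOR = "Primary Tumor"

#: the five ordinal copy-number categories, strong deletion .. strong amplification
CNA_CATEGORIES = (-2, -1, 0, 1, 2)


@dataclass
class ExpressionMatrix:
    """Samples x genes log2 expression with per-sample metadata.

    ``values`` rows are samples, columns are genes. ``metadata`` is
    indexed by sample id; the columns ``cancer_type`` and ``sample_type``
    are used by :func:`filter_primary` and :func:`center_within_type`.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.values.index)
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if not self.metadata.index.equals(self.values.index):
            self.metadata = self.metadata.reindex(self.values.index)
        if self.values.isna().any().any():
            s, g = next(zip(*np.nonzero(self.values.isna().to_numpy())))
            raise ValueError(
                "expression matrix has missing values "
                f"(first at sample {self.values.index[s]!r}, gene {self.values.columns[g]!r})"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class PCSpace:
    """Principal-component frame: the coordinate system for all geometry.

    ``loadings`` columns are unit-norm gene-space directions,
    ``scores`` are per-sample coordinates, ``variance_explained`` the
    per-component fraction of total variance.
    """

    loadings: pd.DataFrame  # genes x components
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def filter_primary(expr: ExpressionMatrix, primary_value: str = PRIMARY_TUMOR) -> ExpressionMatrix:
    """Keep primary tumors only, excluding normals and metastases."""
    if "sample_type" not in expr.metadata.columns:
        raise ValueError("sample_type metadata required for primary-tumor filtering")
    keep = expr.metadata["sample_type"] == primary_value
    if not keep.any():
        raise ValueError("no primary tumor samples remain after filtering")
    return ExpressionMatrix(expr.values.loc[keep], expr.metadata.loc[keep])


def center_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean over samples.

    Entries become log2 fold changes relative to the cohort mean of the
    gene; every column mean is zero afterwards.
    """
    if expr.n_samples < 2:
        raise ValueError("centering requires at least 2 samples")
    centered = expr.values - expr.values.mean(axis=0)
    return ExpressionMatrix(centered, expr.metadata)


def center_within_type(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean within every cancer type.

    Removes tissue identity so that pooled tumors are compared by how
    they deviate from their own tissue's mean; the pooled per-gene mean
    is zero as well.
    """
    if "cancer_type" not in expr.metadata.columns:
        raise ValueError("cancer_type metadata required for within-type centering")
    types = expr.metadata["cancer_type"]
    counts = types.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"cancer type with a single sample: {singletons.index[0]!r}")
    centered = expr.values - expr.values.groupby(types).transform("mean")
    return ExpressionMatrix(centered, expr.metadata)


def pca(expr: ExpressionMatrix, n_components: int) -> PCSpace:
    """Unscaled (covariance-based) PCA of a per-gene-centered matrix.

    Computed by singular-value decomposition of the centered matrix. A
    deterministic sign convention is applied: within each loading
    column the entry of largest magnitude is made positive (ties broken
    by first index), so archetype coordinates are reproducible.
    """
    n, g = expr.values.shape
    max_comp = min(n - 1, g)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    x = expr.values.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    total_var = float(np.sum(s**2))
    var_explained = (s**2 / total_var) if total_var > 0 else np.zeros_like(s)
    loadings = pd.DataFrame(
        vt[:n_components].T,
        index=expr.gene_ids,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    scores = pd.DataFrame(
        (u[:, :n_components] * s[:n_components]),
        index=expr.sample_ids,
        columns=loadings.columns,
    )
    return PCSpace(loadings, scores, var_explained[:n_components])


def cna_entropy(f, tol: float = 1e-8) -> float:
    """Entropy -sum f_i log f_i of a copy-number category distribution.

    Natural log; zero-frequency categories contribute nothing. A gene
    whose copy number is never altered has entropy 0; the uniform
    distribution over the five categories maximizes it at ln 5.
    """
    f = np.asarray(f, dtype=float)
    if (f < -tol).any():
        raise ValueError("frequencies must be nonnegative")
    if abs(f.sum() - 1.0) > tol:
        raise ValueError(f"frequencies must sum to 1, got {f.sum()!r}")
    pos = f[f > 0]
    return float(-np.sum(pos * np.log(pos))) + 0.0  # normalize -0.0


def select_top_entropy_genes(cna: pd.DataFrame, fraction: float) -> pd.Index:
    """Genes with the highest copy-number entropy.

    ``cna`` is samples x genes with ordinal categories in {-2..2}. The
    ceil(fraction * G) genes with highest entropy are returned; ties are
    broken lexicographically by gene id for determinism.
    """
    if cna.shape[1] == 0 or cna.shape[0] == 0:
        raise ValueError("empty copy-number matrix")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    bad = set(np.unique(cna.to_numpy())) - set(CNA_CATEGORIES)
    if bad:
        raise ValueError(f"copy-number categories outside {{-2..2}}: {sorted(bad)}")
    n = cna.shape[0]
    entropies = {}
    for gene in cna.columns:
        counts = cna[gene].value_counts()
        freqs = counts.reindex(CNA_CATEGORIES, fill_value=0).to_numpy() / n
        entropies[gene] = cna_entropy(freqs)
    k = math.ceil(fraction * cna.shape[1])
    # entropies rounded so mathematically tied genes break ties by id,
    # not by floating-point summation order
    order = sorted(entropies, key=lambda gid: (-round(entropies[gid], 12), str(gid)))
    return pd.Index(order[:k])


def filter_mutation_frequency(alterations: pd.DataFrame, min_fraction: float) -> pd.DataFrame:
    """Keep alterations carried by at least ``min_fraction`` of samples (inclusive)."""
    vals = alterations.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("alteration matrix must be binary")
    frac = alterations.mean(axis=0)
    return alterations.loc[:, frac >= min_fraction]


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a samples x genes matrix.

    Each sample's sorted value vector is replaced by the across-sample
    mean of sorted vectors; within-sample ranks are preserved and ties
    receive the mean of their tied target quantiles. Idempotent.
    """
    x = values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n, g = x.shape
    target = np.sort(x, axis=1).mean(axis=0)
    out = np.empty_like(x)
    positions = np.arange(1, g + 1, dtype=float)
    for i in range(n):
        ranks = rankdata(x[i], method="average")
        out[i] = np.interp(ranks, positions, target)
    return pd.DataFrame(out, index=values.index, columns=values.columns)
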