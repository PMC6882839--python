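"""Archetype characterization by feature enrichment near each vertex.

Tumors are ranked by Euclidean distance to an archetype in PC space.
The first distance bin holds the max(base_count, ceil(min_fraction*n))
closest tumors (50 tumors, or 5% when 50 would be less than 5% of the
cohort). Continuous features are tested by a two-sided Mann-Whitney U
of the first bin against all other tumors; discrete features by a
one-sided hypergeometric test. FDR is controlled per feature family by
Benjamini-Hochberg, and a feature is only reported at an archetype when
its per-bin profile peaks in the first bin and the archetype is the one
where it is maximally enriched. Pathway enrichments of large sets can
additionally be vetted by a leave-one-out refit that removes the
pathway's genes from the geometry to rule out circular inference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from paretotasks.io import GeneSetCollection
from paretotasks.preprocess import ExpressionMatrix, pca

logger = logging.getLogger(__name__)


@dataclass
class DistanceBinning:
    """Samples ordered by distance to one archetype and cut into bins."""

    archetype_id: int
    distances: pd.Series  # indexed by sample id, ascending order
    first_bin: pd.Index
    bin_index: pd.Series  # 0-based bin per sample
    n_bins: int

    @property
    def sample_ids(self) -> pd.Index:
        return self.distances.index


def first_bin_size(n: int, base_count: int = 50, min_fraction: float = 0.05) -> int:
    """max(base_count, ceil(min_fraction * n)), capped at n.

    Reconciles the two bin rules: a fixed count of closest tumors, or a
    fixed fraction when the cohort is large enough that the fixed count
    would cover less than that fraction.
    """
    return min(n, max(base_count, math.ceil(min_fraction * n)))


def bin_by_distance(
    scores: pd.DataFrame,
    archetype: np.ndarray,
    base_count: int = 50,
    min_fraction: float = 0.05,
    n_bins: int = 5,
    archetype_id: int = 0,
) -> DistanceBinning:
    """Sort samples by distance to the archetype and assign distance bins.

    Bin 0 is the first bin (closest tumors); the remaining samples are
    split into ``n_bins - 1`` equal-count bins for the peak check.
    Distance ties are broken by sample id for determinism.
    """
    n = scores.shape[0]
    if n < base_count:
        raise ValueError(f"need at least base_count={base_count} samples, got {n}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    d = np.linalg.norm(scores.to_numpy(dtype=float) - np.asarray(archetype), axis=1)
    order = sorted(range(n), key=lambda i: (d[i], str(scores.index[i])))
    ordered_ids = scores.index[order]
    distances = pd.Series(d[order], index=ordered_ids)
    b = first_bin_size(n, base_count, min_fraction)
    bins = np.empty(n, dtype=int)
    bins[:b] = 0
    rest = n - b
    if rest:
        edges = np.linspace(0, rest, n_bins).round().astype(int)
        for j in range(n_bins - 1):
            bins[b + edges[j]: b + edges[j + 1]] = j + 1
    bin_index = pd.Series(bins, index=ordered_ids)
    return DistanceBinning(archetype_id, distances, ordered_ids[:b], bin_index, n_bins)


def test_continuous(values: pd.Series, binning: DistanceBinning) -> tuple[float, float, int]:
    """Mann-Whitney U of the first bin vs all other samples (two-sided).

    Returns (U statistic, p-value, direction); direction is the sign of
    median(first bin) - median(others). Missing values are dropped
    pairwise; a constant feature gets p = 1 by convention.
    """
    v = values.reindex(binning.sample_ids)
    missing = v.isna()
    if missing.any():
        logger.debug("test_continuous: dropping %d missing values", int(missing.sum()))
    in_bin = v.index.isin(binning.first_bin) & ~missing
    out_bin = ~v.index.isin(binning.first_bin) & ~missing
    a, b = v[in_bin].to_numpy(float), v[out_bin].to_numpy(float)
    if len(a) == 0 or len(b) == 0 or len(np.unique(np.concatenate([a, b]))) < 2:
        return math.nan, 1.0, 0
    u, p = mannwhitneyu(a, b, alternative="two-sided")
    direction = int(np.sign(np.median(a) - np.median(b)))
    return float(u), float(p), direction


def test_discrete(labels: pd.Series, binning: DistanceBinning) -> tuple[float, float]:
    """One-sided hypergeometric overrepresentation in the first bin.

    Returns (fold, p) with fold = (x/bin) / (K/n) where x positives fall
    in the first bin out of K positives among n samples.
    """
    v = labels.reindex(binning.sample_ids)
    mask = ~v.isna()
    v = v[mask]
    n = len(v)
    big_k = int(v.sum())
    if big_k <= 0:
        raise ValueError("discrete feature has no positive samples")
    in_bin = v.index.isin(binning.first_bin)
    b = int(in_bin.sum())
    x = int(v[in_bin].sum())
    p = float(hypergeom.sf(x - 1, n, big_k, b))
    fold = (x / b) / (big_k / n) if b else math.nan
    return fold, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-equivariant."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def peak_in_first_bin(values: pd.Series, binning: DistanceBinning) -> bool:
    """True iff the per-bin mean / prevalence is strictly maximal in bin 0.

    Ties are conservative: a feature whose profile merely plateaus at
    the archetype is not counted as peaking there.
    """
    v = values.reindex(binning.sample_ids)
    means = v.groupby(binning.bin_index).mean()
    first = means.loc[0]
    others = means.drop(0)
    if others.empty or not np.isfinite(first):
        return False
    return bool(first > others.max())


def pathway_scores(expr: ExpressionMatrix, sets: GeneSetCollection) -> pd.DataFrame:
    """Collapse genes onto pathways: per-sample mean of member genes.

    Member genes absent from the matrix are dropped (logged); sets with
    no present genes are excluded.
    """
    cols = {}
    for name, members in sets.items():
        present = [g for g in members if g in expr.values.columns]
        dropped = len(members) - len(present)
        if dropped:
            logger.debug("pathway %s: %d member genes absent", name, dropped)
        if not present:
            logger.warning("pathway %s: no member genes present; excluded", name)
            continue
        cols[name] = expr.values[present].mean(axis=1)
    return pd.DataFrame(cols, index=expr.sample_ids)


def enrichment_table(
    features: pd.DataFrame,
    binnings: list[DistanceBinning],
    kind: str = "continuous",
    fdr_q: float = 0.10,
) -> pd.DataFrame:
    """Test every feature at every archetype; one row per (feature, archetype).

    Columns: statistic, p_value, q_value (BH within this feature
    family), direction/fold, peaks_in_first_bin, is_maximal (the
    archetype where the feature is most enriched), and ``reported``
    combining FDR < fdr_q, positive direction, the peak rule, and
    maximality — the criteria a feature must clear to annotate a task.
    """
    if kind not in ("continuous", "discrete"):
        raise ValueError(f"unknown feature kind {kind!r}")
    rows = []
    for feat in features.columns:
        for binning in binnings:
            if kind == "continuous":
                stat, p, direction = test_continuous(features[feat], binning)
                fold = math.nan
            else:
                fold, p = test_discrete(features[feat], binning)
                stat, direction = fold, (1 if fold > 1 else (-1 if fold < 1 else 0))
            rows.append(
                {
                    "feature": feat,
                    "archetype": binning.archetype_id,
                    "statistic": stat,
                    "p_value": p,
                    "direction": direction,
                    "fold": fold,
                    "peaks_in_first_bin": peak_in_first_bin(features[feat], binning),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    # a feature is reported only at the archetype where it is maximally
    # enriched (smallest p among positive-direction tests)
    table["is_maximal"] = False
    for feat, group in table.groupby("feature"):
        positive = group[group["direction"] > 0]
        if positive.empty:
            continue
        table.loc[positive["p_value"].idxmin(), "is_maximal"] = True
    table["reported"] = (
        (table["q_value"] < fdr_q)
        & (table["direction"] > 0)
        & table["peaks_in_first_bin"]
        & table["is_maximal"]
    )
    return table


def leave_one_out_check(
    expr: ExpressionMatrix,
    pathway_genes: list[str],
    archetypes: np.ndarray,
    binning_params: dict | None = None,
    fdr_threshold: float = 0.10,
    loo_min_size: int = 100,
    seed: int = 0,
) -> bool | None:
    """Re-fit the geometry without a pathway's genes and re-test it.

    Guards against circular inference: a pathway large enough to shape
    the PCA could create the very vertex it is then found enriched at.
    The pathway's genes are removed, PCA and the archetype fit are
    recomputed, archetypes are re-matched to the originals by nearest
    gene-space position (Hungarian assignment), and the pathway score
    (still computed on the full matrix) is re-tested at the matched
    archetype. Returns True/False for pathways larger than
    ``loo_min_size`` genes, None (not applicable) otherwise, and None
    with a warning when the re-matching is ambiguous.
    """
    from scipy.optimize import linear_sum_assignment

    from paretotasks.parti import fit_archetypes

    present = [g for g in pathway_genes if g in expr.values.columns]
    if len(present) <= loo_min_size:
        return None
    params = {"base_count": 50, "min_fraction": 0.05, "n_bins": 5}
    params.update(binning_params or {})
    k = archetypes.shape[0]
    full_space = pca(expr, k - 1)
    reduced = ExpressionMatrix(expr.values.drop(columns=present), expr.metadata)
    red_space = pca(reduced, k - 1)
    red_arch = fit_archetypes(red_space.scores.to_numpy(), k, seed=seed)
    # compare archetypes in gene space restricted to the shared genes
    shared = reduced.gene_ids
    orig_genes = archetypes @ full_space.loadings.loc[shared].to_numpy().T
    red_genes = red_arch @ red_space.loadings.to_numpy().T
    cost = np.linalg.norm(orig_genes[:, None, :] - red_genes[None, :, :], axis=2)
    row, col = linear_sum_assignment(cost)
    greedy = cost.argmin(axis=1)
    if len(set(greedy)) < k:
        logger.warning("leave-one-out: archetype re-matching ambiguous; inconclusive")
        return None
    score = expr.values[present].mean(axis=1)
    results = []
    for orig_id, red_id in zip(row, col):
        binning = bin_by_distance(
            red_space.scores, red_arch[red_id], archetype_id=orig_id, **params
        )
        _, p, direction = test_continuous(score, binning)
        results.append((orig_id, p, direction))
    best = min(results, key=lambda r: r[1])
    return bool(best[1] < fdr_threshold and best[2] > 0)
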