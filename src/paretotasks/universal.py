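"""Universal cancer tasks shared across cancer types.

Tumors from several cancer types are pooled after per-type centering
(removing tissue identity), restricted to the shared gene universe, and
fit with one polytope. Per-type representation near each archetype
checks that archetypes are not tissue artifacts; per-type archetype
profiles, collapsed to pathway space, are clustered by Gaussian mixture
modeling with BIC model selection; and tissue archetypes are matched to
universal archetypes by hypergeometric overlap of their significantly
upregulated pathway sets with Bonferroni control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.mixture import GaussianMixture

from paretotasks.enrichment import bin_by_distance, enrichment_table, pathway_scores
from paretotasks.io import GeneSetCollection
from paretotasks.parti import PolyhedronFit, select_k
from paretotasks.preprocess import ExpressionMatrix, center_within_type, pca

logger = logging.getLogger(__name__)


@dataclass
class ArchetypeProfile:
    """Pathway-space signature of one archetype of one source cohort."""

    archetype_id: int
    source: str  # cancer type, or "universal"
    pathway_vector: pd.Series  # mean centered expression of first-bin tumors
    significant_sets: list[str] = field(default_factory=list)


def pool_and_fit(
    exprs: list[ExpressionMatrix],
    k_range: list[int],
    n_shuffles: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[PolyhedronFit | None, pd.DataFrame, pd.Series]:
    """Center each cohort within type, pool, restrict to shared genes, fit.

    Returns (fit-or-None, pooled PC scores, cancer type per sample).
    The fit is invariant to cohort order and within-cohort sample order
    up to the permutation-invariance of the underlying fit.
    """
    if not exprs:
        raise ValueError("no cohorts to pool")
    shared = exprs[0].gene_ids
    for e in exprs[1:]:
        shared = shared.intersection(e.gene_ids)
    if shared.empty:
        raise ValueError("cohorts share no genes")
    centered = []
    for e in exprs:
        c = center_within_type(ExpressionMatrix(e.values[shared], e.metadata))
        centered.append(c)
    pooled_values = pd.concat([c.values for c in centered])
    pooled_meta = pd.concat([c.metadata for c in centered])
    pooled = ExpressionMatrix(pooled_values, pooled_meta)
    max_k = max(k_range)
    space = pca(pooled, max_k - 1)
    scores_by_k = {k: space.scores.to_numpy()[:, : k - 1] for k in k_range}
    fit = select_k(scores_by_k, k_range, alpha=alpha, n_shuffles=n_shuffles,
                   seed=seed, **fit_kwargs)
    return fit, space.scores, pooled.metadata["cancer_type"]


def type_composition_near_archetypes(
    scores: pd.DataFrame,
    types: pd.Series,
    archetypes: np.ndarray,
    fraction: float = 0.10,
) -> pd.DataFrame:
    """Fraction of each type's tumors among those closest to each archetype.

    For each archetype, the ceil(fraction * n) closest tumors are taken
    and, per cancer type, the share of that type's tumors found among
    them is reported. Under even representation every entry is close to
    ``fraction``; a tissue-specific archetype shows one type far above
    it and the others near zero.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    x = scores.to_numpy(dtype=float)
    t = types.reindex(scores.index)
    n = len(scores)
    take = math.ceil(fraction * n)
    rows = {}
    for arch_id in range(archetypes.shape[0]):
        d = np.linalg.norm(x - archetypes[arch_id][: x.shape[1]], axis=1)
        order = np.argsort(d, kind="stable")[:take]
        near_types = t.iloc[order]
        rows[arch_id] = {
            str(ct): float((near_types == ct).sum()) / float((t == ct).sum())
            for ct in t.unique()
        }
    return pd.DataFrame(rows).T.rename_axis("archetype")


def archetype_profile(
    expr: ExpressionMatrix,
    scores: pd.DataFrame,
    archetype: np.ndarray,
    sets: GeneSetCollection,
    archetype_id: int,
    source: str,
    base_count: int = 50,
    min_fraction: float = 0.05,
    fdr_q: float = 0.10,
    min_log2fc: float = 0.1,
) -> ArchetypeProfile:
    """Pathway signature of the tumors in the archetype's first bin.

    The pathway vector is the mean pathway score of first-bin tumors;
    the significant-set list holds pathways at FDR < fdr_q with mean
    log2 fold change above ``min_log2fc`` (the sets used for archetype
    matching).
    """
    binning = bin_by_distance(scores, archetype, base_count=base_count,
                              min_fraction=min_fraction, archetype_id=archetype_id)
    pw = pathway_scores(expr, sets)
    vector = pw.loc[binning.first_bin].mean(axis=0)
    table = enrichment_table(pw, [binning], kind="continuous", fdr_q=fdr_q)
    sig = table[(table["q_value"] < fdr_q) & (table["direction"] > 0)]
    significant = [f for f in sig["feature"] if vector[f] > min_log2fc]
    return ArchetypeProfile(archetype_id, source, vector, significant)


def cluster_archetype_profiles(
    profiles: list[ArchetypeProfile],
    max_components: int = 8,
    seed: int = 0,
    covariance_type: str = "diag",
    restrict_to: list[str] | None = None,
) -> tuple[np.ndarray, int]:
    """Cluster archetype pathway profiles by Gaussian mixture + BIC.

    Each pathway dimension is scaled by its standard deviation across
    profiles (zero-variance pathways dropped); mixtures with 1..max
    components are fit and the component count with the lowest BIC is
    selected. ``restrict_to`` limits the feature space, e.g. to pathways
    significant in every source cohort.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    mat = pd.DataFrame({i: p.pathway_vector for i, p in enumerate(profiles)}).T
    if restrict_to is not None:
        keep = [c for c in restrict_to if c in mat.columns]
        if not keep:
            raise ValueError("no requested pathways present in the profiles")
        mat = mat[keep]
    sd = mat.std(axis=0, ddof=1)
    usable = sd > 0
    if not usable.any():
        # all profiles identical: one component, trivially
        return np.zeros(len(profiles), dtype=int), 1
    mat = mat.loc[:, usable] / sd[usable]
    n = len(profiles)
    cap = min(max_components, n)
    if cap < max_components:
        logger.info("component count capped at the number of profiles (%d)", n)
    best_labels, best_bic, best_n = None, np.inf, 1
    x = mat.to_numpy(dtype=float)
    for n_comp in range(1, cap + 1):
        gm = GaussianMixture(n_components=n_comp, covariance_type=covariance_type,
                             random_state=seed, n_init=5)
        labels = gm.fit_predict(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best_labels, best_bic, best_n = labels, bic, n_comp
    return best_labels, best_n


def match_archetypes(
    tissue: ArchetypeProfile,
    universal: ArchetypeProfile,
    universe: list[str],
) -> float:
    """Hypergeometric p that the two significant-pathway sets overlap.

    The universe is the union of pathways significant at any archetype
    of the tissue's cancer type; Bonferroni correction across all
    tissue x universal pairs is applied by the caller.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty pathway universe")
    a = set(tissue.significant_sets) & uni
    b = set(universal.significant_sets) & uni
    x = len(a & b)
    return float(hypergeom.sf(x - 1, len(uni), len(b), len(a)))


def match_all_archetypes(
    tissue_profiles: list[ArchetypeProfile],
    universal_profiles: list[ArchetypeProfile],
    universes: dict[str, list[str]],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Match every tissue archetype to its best universal archetype.

    One row per (tissue archetype, universal archetype) with the raw
    hypergeometric p, the Bonferroni-corrected p (denominator = all
    pairs tested), a display p (1 when not significant), and a
    ``matched`` flag marking the tissue archetype's most significant
    match when it clears Bonferroni-corrected alpha. Tissue archetypes
    matching nothing are tissue-specific.
    """
    rows = []
    n_tests = len(tissue_profiles) * len(universal_profiles)
    for t in tissue_profiles:
        for u in universal_profiles:
            p = match_archetypes(t, u, universes[t.source])
            rows.append({"tissue_source": t.source, "tissue_archetype": t.archetype_id,
                         "universal_archetype": u.archetype_id, "p_value": p,
                         "p_bonferroni": min(1.0, p * n_tests)})
    table = pd.DataFrame(rows)
    table["display_p"] = np.where(table["p_bonferroni"] < alpha, table["p_value"], 1.0)
    table["matched"] = False
    for (src, tid), group in table.groupby(["tissue_source", "tissue_archetype"]):
        best = group["p_value"].idxmin()
        if table.loc[best, "p_bonferroni"] < alpha:
            table.loc[best, "matched"] = True
    return table
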