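"""Drug sensitivity versus distance to archetypes in cell-line panels.

Cell lines are projected into the tumor PC space (after quantile
normalization of the joint expression matrix) and, per archetype,
grouped into equal-count distance bins. A drug whose potency peaks at
the archetype and decays monotonically away from it earns a high score
Prod_i (G_i - G_{i+1} + 2<sigma>), where G_i is the median GR AOC in
bin i and <sigma> the median within-bin standard error; any consecutive
increase larger than twice that standard error zeroes the score. GR AOC
(area over the growth-rate-corrected dose-response curve) is an input
measured elsewhere; larger means more sensitive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from paretotasks.enrichment import bh_fdr
from paretotasks.preprocess import ExpressionMatrix, PCSpace, quantile_normalize

logger = logging.getLogger(__name__)

#: asymptotic standard error of a median under normality: 1.2533 sd/sqrt(n)
MEDIAN_SE_FACTOR = math.sqrt(math.pi / 2.0)


@dataclass
class DrugBinProfile:
    """Per-bin response summary of one drug at one archetype."""

    drug: str
    archetype_id: int
    medians: np.ndarray  # G_1..G_B
    standard_errors: np.ndarray  # sigma_1..sigma_B
    counts: np.ndarray
    scorable: bool

    @property
    def median_se(self) -> float:
        """<sigma>: the median standard error across bins."""
        return float(np.median(self.standard_errors))


def joint_quantile_normalize(
    cell_expr: ExpressionMatrix, tumor_expr: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Quantile-normalize cell lines and tumors jointly on shared genes."""
    shared = cell_expr.gene_ids.intersection(tumor_expr.gene_ids)
    if shared.empty:
        raise ValueError("cell lines and tumors share no genes")
    joint = pd.concat([cell_expr.values[shared], tumor_expr.values[shared]])
    normed = quantile_normalize(joint)
    n_cells = cell_expr.n_samples
    return (
        ExpressionMatrix(normed.iloc[:n_cells], cell_expr.metadata),
        ExpressionMatrix(normed.iloc[n_cells:], tumor_expr.metadata),
    )


def project_cell_lines(cell_expr: ExpressionMatrix, pc_space: PCSpace) -> pd.DataFrame:
    """Project cell lines onto tumor PCs restricted to shared genes.

    Cell lines are centered per gene over cell lines (so coordinates
    reflect within-panel diversity), then multiplied by the tumor
    loadings restricted to the shared genes.
    """
    shared = cell_expr.gene_ids.intersection(pc_space.loadings.index)
    if shared.empty:
        raise ValueError("no shared genes between cell lines and the PC space")
    values = cell_expr.values[shared]
    centered = values - values.mean(axis=0)
    loadings = pc_space.loadings.loc[shared]
    coords = centered.to_numpy() @ loadings.to_numpy()
    return pd.DataFrame(coords, index=cell_expr.sample_ids, columns=loadings.columns)


def bin_drug_response(
    distances: pd.Series,
    aoc: pd.Series,
    n_bins: int = 4,
    min_per_bin: int = 5,
    drug: str = "",
    archetype_id: int = 0,
    se_method: str = "median",
) -> DrugBinProfile:
    """Split measured cell lines into equal-count distance bins.

    Lines without a measured AOC are dropped first; the drug is marked
    unscorable when any bin holds fewer than ``min_per_bin`` lines.
    Ties in distance are broken by cell-line id.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    measured = aoc.dropna()
    d = distances.reindex(measured.index)
    order = sorted(measured.index, key=lambda i: (d[i], str(i)))
    n = len(order)
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    medians, ses, counts = [], [], []
    for j in range(n_bins):
        ids = order[edges[j]: edges[j + 1]]
        vals = measured[ids].to_numpy(dtype=float)
        counts.append(len(vals))
        if len(vals) == 0:
            medians.append(math.nan)
            ses.append(math.nan)
            continue
        medians.append(float(np.median(vals)))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        se = sd / math.sqrt(len(vals))
        if se_method == "median":
            se *= MEDIAN_SE_FACTOR
        ses.append(se)
    counts = np.asarray(counts)
    scorable = bool((counts >= min_per_bin).all())
    return DrugBinProfile(drug, archetype_id, np.asarray(medians),
                          np.asarray(ses), counts, scorable)


def drug_score(profile: DrugBinProfile) -> float:
    """Prod_i (G_i - G_{i+1} + 2<sigma>), zeroed on any large increase.

    An increase of more than twice the median within-bin standard error
    between consecutive bins zeroes the score (an absorbing rule);
    smaller increases are tolerated and multiply through as-is. The
    score depends only on differences of bin medians, so it is invariant
    to adding a constant to all bins.
    """
    if not profile.scorable:
        raise ValueError(f"drug {profile.drug!r} is not scorable (a bin is too small)")
    g = profile.medians
    two_sigma = 2.0 * profile.median_se
    diffs = g[:-1] - g[1:]
    if np.any(-diffs > two_sigma):  # increase beyond tolerance
        return 0.0
    return float(np.prod(diffs + two_sigma))


def drug_archetype_test(
    aoc: pd.Series,
    distances: pd.Series,
    n_bins: int = 4,
) -> tuple[float, int]:
    """Mann-Whitney of first-bin AOC against all other bins.

    Returns (two-sided p, direction); direction is +1 when the first bin's
    median AOC exceeds the rest, which a targeted drug must satisfy.
    """
    measured = aoc.dropna()
    d = distances.reindex(measured.index)
    order = sorted(measured.index, key=lambda i: (d[i], str(i)))
    n = len(order)
    edge = int(round(n / n_bins))
    a = measured[order[:edge]].to_numpy(dtype=float)
    b = measured[order[edge:]].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0 or len(np.unique(np.concatenate([a, b]))) < 2:
        return 1.0, 0
    _, p = mannwhitneyu(a, b, alternative="two-sided")
    return float(p), int(np.sign(np.median(a) - np.median(b)))


def group_by_mechanism(aoc_table: pd.DataFrame,
                       mechanisms: dict[str, str] | None) -> dict[str, pd.DataFrame]:
    """Pool AOC measurements of drugs sharing a mechanism.

    Returns mechanism-or-drug name -> long table with columns ``line``
    and ``aoc``, one row per drug x line measurement (a line measured
    for several same-mechanism drugs contributes several rows). Drugs
    without a label keep their own name.
    """
    groups: dict[str, list[pd.DataFrame]] = {}
    for drug in aoc_table.columns:
        key = (mechanisms or {}).get(drug, drug)
        long = pd.DataFrame({"line": aoc_table.index, "aoc": aoc_table[drug].to_numpy()})
        groups.setdefault(key, []).append(long)
    return {key: pd.concat(parts, ignore_index=True) for key, parts in groups.items()}


def score_drug_panel(
    line_coords: pd.DataFrame,
    archetype_coords: np.ndarray,
    aoc_table: pd.DataFrame,
    mechanisms: dict[str, str] | None = None,
    n_bins: int = 4,
    min_per_bin: int = 5,
    fdr_q: float = 0.10,
) -> pd.DataFrame:
    """Score every (drug-or-mechanism, archetype) pair.

    Output rows carry the bin medians, the score, the Mann-Whitney p of
    the first bin vs the rest, and BH q-values across all scored pairs.
    """
    grouped = group_by_mechanism(aoc_table, mechanisms)
    rows = []
    for arch_id in range(archetype_coords.shape[0]):
        dist = pd.Series(
            np.linalg.norm(line_coords.to_numpy() - archetype_coords[arch_id], axis=1),
            index=line_coords.index,
        )
        for name, long in grouped.items():
            # pooled tables may repeat line ids; distances follow the line column
            aoc = pd.Series(long["aoc"].to_numpy(), index=long.index)
            d = pd.Series(dist.loc[long["line"]].to_numpy(), index=long.index)
            profile = bin_drug_response(d, aoc, n_bins=n_bins, min_per_bin=min_per_bin,
                                        drug=name, archetype_id=arch_id)
            if not profile.scorable:
                logger.info("drug %s at archetype %d: <%d lines in a bin; discarded",
                            name, arch_id, min_per_bin)
                continue
            p, direction = drug_archetype_test(aoc, d, n_bins=n_bins)
            rows.append({
                "drug": name, "archetype": arch_id,
                "score": drug_score(profile), "p_value": p, "direction": direction,
                "bin_medians": ",".join(f"{g:.4g}" for g in profile.medians),
                "median_se": profile.median_se,
            })
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    table["significant"] = (table["q_value"] < fdr_q) & (table["direction"] > 0)
    return table.sort_values("score", ascending=False).reset_index(drop=True)
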