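"""Alignment of genetic alterations with the Pareto front.

Each alteration's mean effect on expression is the vector u connecting
the centroid of non-carrier tumors to the centroid of carrier tumors in
PC space. The front is the direction space of the affine hull of the
archetypes; u is projected onto it (v) and the alignment angle is
alpha = 180 * arccos(<u,v> / |u||v|) / pi. Significance comes from a
large pool of shuffled carrier assignments; because small angles are
rare among shuffles, the tail of the null is extrapolated by fitting a
fifth-order polynomial to log of the empirical small-angle probability,
using only angles supported by at least ten shuffled controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from paretotasks.enrichment import DistanceBinning, bh_fdr, test_discrete

logger = logging.getLogger(__name__)


def effect_vector(scores: np.ndarray, carrier_mask: np.ndarray) -> np.ndarray:
    """u = centroid(carriers) - centroid(non-carriers) in PC space."""
    x = np.asarray(scores, dtype=float)
    mask = np.asarray(carrier_mask, dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("need at least one carrier and one non-carrier")
    return x[mask].mean(axis=0) - x[~mask].mean(axis=0)


def front_span(archetypes: np.ndarray) -> np.ndarray:
    """Orthonormal basis (d x k-1) of the front's direction space.

    The front is the affine hull of the archetypes; effect vectors are
    differences of centroids, so only its direction space
    span{a_i - a_1} matters.
    """
    a = np.asarray(archetypes, dtype=float)
    if a.shape[0] < 2:
        raise ValueError("need at least 2 archetypes")
    diffs = (a[1:] - a[0]).T  # d x (k-1)
    q, r = np.linalg.qr(diffs)
    if np.abs(np.diag(r)).min() < 1e-10 * max(1.0, np.abs(r).max()):
        raise ValueError("archetypes are affinely dependent")
    return q


def angle_to_front(u: np.ndarray, basis: np.ndarray) -> float:
    """Angle in degrees between u and the subspace spanned by ``basis``.

    v is the orthogonal projection of u onto the span; alpha =
    arccos(<u,v>/(|u||v|)) in degrees, with the convention alpha = 90
    when the projection vanishes.
    """
    u = np.asarray(u, dtype=float)
    nu = np.linalg.norm(u)
    if nu == 0:
        raise ValueError("zero effect vector: angle undefined")
    v = basis @ (basis.T @ u)
    nv = np.linalg.norm(v)
    if nv < 1e-300 * nu:
        return 90.0
    cos = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _angles_batch(u: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Vectorized angle_to_front for rows of ``u``."""
    nu = np.linalg.norm(u, axis=1)
    v = (u @ basis) @ basis.T
    nv = np.linalg.norm(v, axis=1)
    dot = np.einsum("ij,ij->i", u, v)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.clip(dot / (nu * nv), -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    ang[nv < 1e-300 * nu] = 90.0
    return ang


@dataclass
class NullAngleModel:
    """Empirical null of shuffled-carrier angles with an extrapolated tail.

    ``coeffs`` are the fifth-order polynomial coefficients of the fit of
    log p(alpha) = log P(null angle <= alpha) over the supported range;
    below the smallest supported angle the polynomial extrapolates the
    tail. When the fit is non-monotone on the evaluation grid the model
    falls back to the empirical (1+x)/(1+n) estimator.
    """

    angles: np.ndarray  # sorted null angles
    coeffs: np.ndarray | None
    min_supported: float
    support: int = 10
    degree: int = 5
    monotone: bool = True

    @property
    def n(self) -> int:
        return len(self.angles)

    def empirical_pvalue(self, alpha: float) -> float:
        x = int(np.searchsorted(self.angles, alpha, side="right"))
        return (1.0 + x) / (1.0 + self.n)

    def pvalue(self, alpha: float) -> float:
        """p = P(null angle <= alpha), extrapolated below the supported range."""
        if self.coeffs is None or not self.monotone:
            return self.empirical_pvalue(alpha)
        if alpha >= self.min_supported:
            return self.empirical_pvalue(alpha)
        logp = float(np.polyval(self.coeffs, alpha))
        return float(np.clip(np.exp(logp), np.nextafter(0, 1), 1.0))


def null_angles(
    scores: np.ndarray,
    basis: np.ndarray,
    carrier_count_pool: list[int],
    n_shuffles: int = 100_000,
    seed: int = 0,
    support: int = 10,
    degree: int = 5,
    batch: int = 50_000,
) -> NullAngleModel:
    """Null distribution of front angles under random carrier assignment.

    Each shuffle draws a carrier count from the observed pool (the null
    angle distribution is insensitive to alteration frequency, so the
    pool is shared across alterations) and assigns carriers uniformly
    at random. Returns the fitted tail model.
    """
    if n_shuffles < 1000:
        raise ValueError("at least 1000 shuffles are required")
    x = np.asarray(scores, dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    pool = np.asarray(carrier_count_pool, dtype=int)
    if ((pool <= 0) | (pool >= n)).any():
        raise ValueError("carrier counts must be in (0, n)")
    counts = rng.choice(pool, size=n_shuffles)
    totals = x.sum(axis=0)
    angles = np.empty(n_shuffles)
    pos = 0
    # batches grouped by carrier count so the subset draws vectorize
    for c in np.unique(counts):
        m_total = int(np.sum(counts == c))
        done = 0
        while done < m_total:
            m = min(batch, m_total - done)
            # random carrier subsets via argpartition of uniform keys
            keys = rng.random((m, n))
            idx = np.argpartition(keys, c, axis=1)[:, :c]
            s = x[idx].sum(axis=1)
            u = s / c - (totals - s) / (n - c)
            angles[pos: pos + m] = _angles_batch(u, basis)
            pos += m
            done += m
    angles.sort()
    return _fit_null_model(angles, support=support, degree=degree)


def _fit_null_model(sorted_angles: np.ndarray, support: int = 10,
                    degree: int = 5) -> NullAngleModel:
    n = len(sorted_angles)
    # step points of the empirical CDF with at least `support` controls below
    idx = np.arange(support, n + 1)
    alphas = sorted_angles[idx - 1]
    logp = np.log(idx / n)
    min_supported = float(sorted_angles[support - 1])
    # deduplicate tied angles, keeping the largest count at each angle
    uniq, last = np.unique(alphas[::-1], return_index=True)
    logp_u = logp[::-1][last]
    if len(uniq) <= degree + 1:
        logger.warning("too few support points for the polynomial tail; "
                       "using the empirical estimator")
        return NullAngleModel(sorted_angles, None, min_supported, support, degree)
    coeffs = np.polyfit(uniq, logp_u, degree)
    grid = np.linspace(0.0, min_supported, 200)
    fitted = np.polyval(coeffs, grid)
    monotone = bool(np.all(np.diff(fitted) >= -1e-9))
    if not monotone:
        logger.warning("extrapolated null tail is non-monotone; "
                       "falling back to the empirical estimator")
    model = NullAngleModel(sorted_angles, coeffs, min_supported, support, degree,
                           monotone=monotone)
    # diagnostic: polynomial vs empirical agreement where support exists
    for a in np.percentile(sorted_angles, [5, 25, 50]):
        emp = model.empirical_pvalue(float(a))
        pol = float(np.exp(np.polyval(coeffs, a))) if monotone else emp
        if emp > 0 and not (0.5 <= pol / emp <= 2.0):
            logger.warning("tail fit deviates from empirical CDF at %.1f deg "
                           "(poly %.3g vs empirical %.3g)", a, pol, emp)
    return model


def alignment_pvalue(alpha: float, null_model: NullAngleModel) -> float:
    """p-value that an alteration of angle ``alpha`` aligns with the front."""
    if not 0.0 <= alpha <= 90.0:
        raise ValueError("alpha must be in [0, 90] degrees")
    return null_model.pvalue(alpha)


def assign_task(
    u: np.ndarray,
    archetypes: np.ndarray,
    binnings: list[DistanceBinning],
    carrier_series: pd.Series,
    scores: pd.DataFrame,
    fdr_q: float = 0.10,
) -> tuple[list[int], pd.DataFrame]:
    """Archetype(s) an aligned alteration points toward.

    For each archetype the angle between u and (archetype - non-carrier
    centroid) is computed together with the hypergeometric enrichment of
    carriers in the archetype's first distance bin. Archetypes with
    enrichment q < fdr_q qualify; the closest-angle qualifier is listed
    first. A vector pointing at a face can qualify several archetypes,
    which are all reported.
    """
    mask = carrier_series.reindex(scores.index).to_numpy(dtype=bool)
    x = scores.to_numpy(dtype=float)
    non_carrier_centroid = x[~mask].mean(axis=0)
    nu = np.linalg.norm(u)
    per_arch = []
    for arch_id, binning in enumerate(binnings):
        fold, p = test_discrete(carrier_series, binning)
        direction = np.asarray(archetypes[arch_id]) - non_carrier_centroid
        nd = np.linalg.norm(direction)
        if nu == 0 or nd == 0:
            ang = 90.0
        else:
            cos = np.clip(u @ direction / (nu * nd), -1.0, 1.0)
            ang = float(np.degrees(np.arccos(cos)))
        per_arch.append({"archetype": arch_id, "fold": fold, "p_value": p,
                         "angle_to_archetype": ang})
    table = pd.DataFrame(per_arch)
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    qualified = table[table["q_value"] < fdr_q].sort_values("angle_to_archetype")
    return qualified["archetype"].tolist(), table


def align_alterations(
    scores: pd.DataFrame,
    archetypes: np.ndarray,
    alterations: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    n_shuffles: int = 100_000,
    seed: int = 0,
    fdr_q: float = 0.10,
    binnings: list[DistanceBinning] | None = None,
) -> pd.DataFrame:
    """Full alignment analysis: one row per alteration.

    Columns: label, carrier count, angle alpha to the front, p-value
    (tail-extrapolated), BH q-value, and — for alterations passing the
    alignment gate when binnings are given — the assigned archetype(s)
    with enrichment fold and p in the archetypes' first distance bins.
    """
    x = scores.to_numpy(dtype=float)
    basis = front_span(archetypes)
    carrier_counts = [int(alterations[c].sum()) for c in alterations.columns
                      if 0 < alterations[c].sum() < len(alterations)]
    if not carrier_counts:
        raise ValueError("no testable alterations (all zero or all carriers)")
    null = null_angles(x, basis, carrier_counts, n_shuffles=n_shuffles, seed=seed)
    rows = []
    for name in alterations.columns:
        mask = alterations[name].to_numpy(dtype=bool)
        if mask.all() or not mask.any():
            logger.warning("alteration %s has no contrast; skipped", name)
            continue
        u = effect_vector(x, mask)
        alpha = angle_to_front(u, basis)
        p = alignment_pvalue(alpha, null)
        rows.append({"alteration": name, "carriers": int(mask.sum()),
                     "angle": alpha, "p_value": p, "u": u})
    table = pd.DataFrame(rows).set_index("alteration")
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    if labels is not None and "label" in labels.columns:
        table["label"] = labels["label"].reindex(table.index)
    assigned_col, fold_col, enr_p_col = [], [], []
    for name in table.index:
        assigned, fold, enr_p = [], np.nan, np.nan
        if binnings is not None and table.loc[name, "q_value"] < fdr_q:
            assigned, per_arch = assign_task(
                table.loc[name, "u"], archetypes, binnings,
                alterations[name], scores, fdr_q=fdr_q,
            )
            if assigned:
                best = per_arch[per_arch["archetype"] == assigned[0]].iloc[0]
                fold, enr_p = float(best["fold"]), float(best["p_value"])
        assigned_col.append(",".join(map(str, assigned)) if assigned else "")
        fold_col.append(fold)
        enr_p_col.append(enr_p)
    table["assigned_archetypes"] = assigned_col
    table["enrichment_fold"] = fold_col
    table["enrichment_p"] = enr_p_col
    return table.drop(columns=["u"])
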