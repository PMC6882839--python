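"""Polytope fitting in PC space: archetypes, t-ratio, and significance.

A k-vertex simplex spans exactly k-1 dimensions, so k archetypes are
fit to the first k-1 principal components. Fit quality is the t-ratio:
the volume of the minimal enclosing simplex divided by the volume of
the data's convex hull, always >= 1 and approaching 1 when the data
fills its polytope. Significance comes from a permutation null that
shuffles every PC column independently, preserving the marginal
distribution of loadings on each PC while destroying their correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, QhullError

logger = logging.getLogger(__name__)

#: exact hull computation is only attempted in low dimension (the regime
#: of 3-5 archetypes); beyond this Qhull cost explodes combinatorially.
MAX_HULL_DIM = 8


@dataclass
class PolyhedronFit:
    """A fitted k-vertex polytope with its significance evidence."""

    k: int
    archetypes: np.ndarray  # k x (k-1), archetypal-analysis positions
    t_ratio: float
    p_value: float
    n_shuffles: int
    seed: int
    enclosing: bool
    enclosing_simplex: np.ndarray | None = None  # k x (k-1), minimal enclosing
    null_t_ratios: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# simplex geometry


def simplex_volume(vertices: np.ndarray) -> float:
    """Volume of a d-simplex given its k = d+1 vertices (k x d)."""
    v = np.asarray(vertices, dtype=float)
    d = v.shape[1]
    if v.shape[0] != d + 1:
        raise ValueError(f"need {d + 1} vertices in {d} dims, got {v.shape[0]}")
    return abs(np.linalg.det(v[1:] - v[0])) / math.factorial(d)


def barycentric_coordinates(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of ``points`` (n x d) in the simplex (k x d).

    A point lies inside the simplex iff all coordinates are >= 0 (they
    always sum to 1).
    """
    v = np.asarray(vertices, dtype=float)
    p = np.atleast_2d(np.asarray(points, dtype=float))
    d = v.shape[1]
    t = (v[1:] - v[0]).T  # d x d
    lam_rest = np.linalg.solve(t, (p - v[0]).T).T  # n x d
    lam0 = 1.0 - lam_rest.sum(axis=1, keepdims=True)
    return np.hstack([lam0, lam_rest])


def points_enclosed(points: np.ndarray, vertices: np.ndarray, tol: float = 1e-9) -> bool:
    return bool(barycentric_coordinates(points, vertices).min() >= -tol)


def _hull(points: np.ndarray) -> ConvexHull:
    d = points.shape[1]
    if d > MAX_HULL_DIM:
        raise ValueError(
            f"exact convex hulls are only computed up to {MAX_HULL_DIM} dimensions "
            f"(got {d}); reduce the number of archetypes or components"
        )
    try:
        return ConvexHull(points)
    except QhullError as exc:
        raise ValueError(f"degenerate point cloud: convex hull failed ({exc})") from exc


# ---------------------------------------------------------------------------
# archetypal analysis


def _face_subsets(k: int) -> list[tuple[int, ...]]:
    """All nonempty proper vertex subsets of a k-simplex, small first."""
    from itertools import combinations

    subsets: list[tuple[int, ...]] = []
    for m in range(1, k):
        subsets.extend(combinations(range(k), m))
    return subsets


def _best_weights(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Exact simplex-constrained least squares: argmin_S ||X - S Z||.

    With k archetypes spanning k-1 dimensions the optimal convex
    reconstruction of a sample is its Euclidean projection onto the
    simplex conv(Z). The projection lies in the relative interior of
    some face, so it is found exactly by enumerating the 2^k - 2 proper
    faces (cheap for the 3-5 archetypes this method operates at) plus
    the interior case, vectorized over samples.
    """
    x = np.atleast_2d(x)
    n, d = x.shape
    k = z.shape[0]
    s = np.zeros((n, k))
    if k == d + 1 and abs(np.linalg.det(z[1:] - z[0])) > 1e-300:
        lam = barycentric_coordinates(x, z)
        inside = lam.min(axis=1) >= 0.0
        s[inside] = lam[inside]
    else:
        inside = np.zeros(n, dtype=bool)
    out = ~inside
    if not out.any():
        return s
    xo = x[out]
    best_d2 = np.full(xo.shape[0], np.inf)
    best_s = np.zeros((xo.shape[0], k))
    for subset in _face_subsets(k):
        zf = z[list(subset)]
        if len(subset) == 1:
            proj = np.broadcast_to(zf[0], xo.shape)
            coords = np.ones((xo.shape[0], 1))
        else:
            a = zf[1:] - zf[0]  # (m-1) x d
            gram = a @ a.T
            try:
                t = np.linalg.solve(gram, a @ (xo - zf[0]).T).T
            except np.linalg.LinAlgError:
                t, *_ = np.linalg.lstsq(a.T, (xo - zf[0]).T, rcond=None)
                t = t.T
            coords = np.hstack([1.0 - t.sum(axis=1, keepdims=True), t])
            proj = zf[0] + t @ a
        feas = coords.min(axis=1) >= -1e-12
        d2 = np.einsum("ij,ij->i", xo - proj, xo - proj)
        better = feas & (d2 < best_d2)
        if better.any():
            best_d2[better] = d2[better]
            best_s[better] = 0.0
            best_s[np.ix_(better, list(subset))] = coords[better]
    s[out] = best_s
    return s


def _pull_into_hull(z: np.ndarray, equations: np.ndarray,
                    anchor: np.ndarray) -> np.ndarray:
    """Move rows of ``z`` that left the polytope {x : A x + b <= 0} back inside.

    A row violating a single facet is projected perpendicularly onto it;
    otherwise (or when that projection lands outside another facet) the
    row is clipped along the segment to ``anchor``, a point strictly
    inside. Closed form and fully vectorized; the subsequent
    weight/least-squares alternation re-optimizes around the returned
    position.
    """
    a, b = equations[:, :-1], equations[:, -1]
    out = z.copy()
    slack = out @ a.T + b  # rows x facets
    n_viol = (slack > 1e-12).sum(axis=1)
    single = n_viol == 1
    if single.any():
        idx = np.nonzero(single)[0]
        fac = np.argmax(slack[idx] > 1e-12, axis=1)
        cand = out[idx] - slack[idx, fac][:, None] * a[fac]
        ok = (cand @ a.T + b).max(axis=1) <= 1e-12
        out[idx[ok]] = cand[ok]
        n_viol[idx[~ok]] = 2  # fall through to ray clipping
    multi = n_viol > 1
    if multi.any():
        direction = out[multi] - anchor
        denom = direction @ a.T  # rows x facets
        avail = -(b + anchor @ a.T)  # slack at the anchor, > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 1e-300, avail / denom, np.inf)
        t_max = np.clip(t.min(axis=1), 0.0, 1.0)
        out[multi] = anchor + t_max[:, None] * direction
    return out


def fit_archetypes(
    scores: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-8,
    hull: ConvexHull | None = None,
) -> np.ndarray:
    """Fit k archetypes by archetypal analysis (alternating least squares).

    Minimizes the squared residual of the best convex-combination
    reconstruction of each sample, ``min_{S, Z} ||X - S Z||^2``, with
    rows of S on the probability simplex and the archetypes Z
    constrained to the convex hull of the data (the classical
    archetypal-analysis constraint; without it the objective is
    degenerate, since any simplex enclosing all points has zero
    residual). S is updated exactly by simplex projection, Z by least
    squares followed by projection into the hull. Multiple seeded
    restarts guard against local minima; the returned archetypes are
    ordered lexicographically by coordinates so the output is canonical.
    """
    x = np.asarray(scores, dtype=float)
    n, d = x.shape
    if k < 3:
        raise ValueError("k must be >= 3")
    if d != k - 1:
        raise ValueError(f"k={k} archetypes are fit in {k - 1} dims, got {d}")
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples to fit {k} archetypes")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all points identical")
    equations = (_hull(x) if hull is None else hull).equations
    anchor = x.mean(axis=0)
    rng = np.random.default_rng(seed)
    # draw restart positions from a canonically ordered copy so the fit
    # is invariant to the sample order of the input
    pool = x[np.lexsort(x.T[::-1])]
    best_z, best_obj = None, np.inf
    for _ in range(max(1, n_restarts)):
        idx = rng.choice(n, size=k, replace=False)
        z = pool[idx] + 1e-9 * rng.standard_normal((k, d))
        prev = np.inf
        for _ in range(max_iter):
            s = _best_weights(x, z)
            sts = s.T @ s
            z_free = np.linalg.solve(sts + 1e-12 * np.eye(k), s.T @ x)
            z = _pull_into_hull(z_free, equations, anchor)
            obj = float(np.sum((x - s @ z) ** 2))
            if prev - obj < tol * max(prev, 1.0):
                break
            prev = obj
        if obj < best_obj:
            best_obj, best_z = obj, z
    order = np.lexsort(best_z.T[::-1])  # sort by first coord, then second, ...
    return best_z[order]


def archetype_reconstruction_error(scores: np.ndarray, archetypes: np.ndarray) -> float:
    """Residual sum of squares of the best convex reconstruction."""
    s = _best_weights(np.asarray(scores, float), np.asarray(archetypes, float))
    return float(np.sum((scores - s @ archetypes) ** 2))


# ---------------------------------------------------------------------------
# minimal enclosing simplex and t-ratio


def _inflate_to_enclose(vertices: np.ndarray, points: np.ndarray,
                        margin: float = 1e-7) -> np.ndarray:
    """Scale the simplex outward from its centroid until all points are inside."""
    v = np.asarray(vertices, dtype=float)
    k = v.shape[0]
    lam_min = barycentric_coordinates(points, v).min()
    # scaling by s about the centroid maps lambda -> (lambda - 1/k)/s + 1/k
    scale = max(1.0, 1.0 - k * lam_min) * (1.0 + margin)
    centroid = v.mean(axis=0)
    return centroid + scale * (v - centroid)


def minimal_enclosing_simplex(
    scores: np.ndarray,
    init_archetypes: np.ndarray,
    maxiter: int = 60,
    tol: float = 1e-9,
    hull: ConvexHull | None = None,
) -> np.ndarray:
    """Locally volume-minimal simplex enclosing every data point.

    Initialized from the fitted archetypes, inflated outward from their
    centroid until enclosing, then locally optimized over vertex
    coordinates. Enclosure constraints are imposed on the convex-hull
    vertices of the data only, which suffices: a convex body contains a
    cloud iff it contains the cloud's hull vertices. If the optimizer
    fails to return an enclosing simplex of smaller volume, the inflated
    (enclosing but unoptimized) simplex is returned with a warning.
    """
    x = np.asarray(scores, dtype=float)
    v0 = np.asarray(init_archetypes, dtype=float)
    k, d = v0.shape
    if k != d + 1:
        raise ValueError("init vertices must form a simplex (k = d+1)")
    if abs(np.linalg.det(v0[1:] - v0[0])) < 1e-300:
        raise ValueError("init vertices affinely dependent")
    if x.shape[0] > d + 1:
        hull_pts = x[(_hull(x) if hull is None else hull).vertices]
    else:
        hull_pts = x
    v_inflated = _inflate_to_enclose(v0, hull_pts)
    scale = max(np.ptp(x, axis=0).max(), 1e-12)
    p_scaled = hull_pts / scale

    def volume(flat: np.ndarray) -> float:
        return simplex_volume(flat.reshape(k, d))

    def volume_grad(flat: np.ndarray) -> np.ndarray:
        v = flat.reshape(k, d)
        m = v[1:] - v[0]
        vol = abs(np.linalg.det(m)) / math.factorial(d)
        minv = np.linalg.inv(m)
        g = np.empty((k, d))
        g[1:] = vol * minv.T  # d|det M|/dM = |det M| M^{-T}, row-wise
        g[0] = -g[1:].sum(axis=0)
        return g.ravel()

    def constraint(flat: np.ndarray) -> np.ndarray:
        return barycentric_coordinates(p_scaled, flat.reshape(k, d)).ravel()

    def constraint_jac(flat: np.ndarray) -> np.ndarray:
        v = flat.reshape(k, d)
        tinv = np.linalg.inv((v[1:] - v[0]).T)
        t = (p_scaled - v[0]) @ tinv.T  # h x d barycentric (rest)
        coeff = np.empty((t.shape[0], k))
        coeff[:, 0] = t.sum(axis=1) - 1.0
        coeff[:, 1:] = -t
        j_rest = np.einsum("pj,ab->pajb", coeff, tinv)  # dt_a / dv_{j,b}
        jac = np.empty((t.shape[0], k, k, d))
        jac[:, 1:] = j_rest
        jac[:, 0] = -j_rest.sum(axis=1)
        return jac.reshape(t.shape[0] * k, k * d)

    try:
        res = minimize(
            volume,
            (v_inflated / scale).ravel(),
            jac=volume_grad,
            method="SLSQP",
            constraints=[{"type": "ineq", "fun": constraint, "jac": constraint_jac}],
            options={"maxiter": maxiter, "ftol": 1e-12},
        )
        v_opt = res.x.reshape(k, d) * scale
        if points_enclosed(x, v_opt, tol=max(tol, 1e-7)) and (
            simplex_volume(v_opt) <= simplex_volume(v_inflated)
        ):
            return _inflate_to_enclose(v_opt, x, margin=1e-9)
    except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
        logger.warning("enclosing-simplex optimization failed (%s); using inflated simplex", exc)
    else:
        logger.debug("enclosing-simplex optimization did not improve; using inflated simplex")
    return _inflate_to_enclose(v0, x)


def t_ratio(scores: np.ndarray, simplex: np.ndarray, tol: float = 1e-9,
            hull: ConvexHull | None = None) -> float:
    """volume(enclosing simplex) / volume(convex hull of the data).

    >= 1 for any enclosing simplex; near 1 when the data fills its
    polytope out to the vertices.
    """
    x = np.asarray(scores, dtype=float)
    if not points_enclosed(x, simplex, tol=tol):
        raise ValueError("simplex does not enclose all points")
    hull_vol = (_hull(x) if hull is None else hull).volume
    if hull_vol <= 0:
        raise ValueError("convex hull of the data has zero volume (rank-deficient cloud)")
    return simplex_volume(simplex) / hull_vol


def _fit_t_ratio(x: np.ndarray, k: int, seed: int, n_restarts: int,
                 max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    hull = _hull(x)
    arch = fit_archetypes(x, k, seed=seed, n_restarts=n_restarts,
                          max_iter=max_iter, hull=hull)
    enclosing = minimal_enclosing_simplex(x, arch, hull=hull)
    return arch, enclosing, t_ratio(x, enclosing, hull=hull)


def shuffle_significance(
    scores: np.ndarray,
    k: int,
    n_shuffles: int = 1000,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 60,
) -> PolyhedronFit:
    """Permutation test of the polytope against independent-column nulls.

    Each shuffle permutes every PC column independently across samples,
    conserving the marginal distribution of loadings on each component
    but destroying their correlation, then reruns the full
    fit -> enclosing simplex -> t-ratio pipeline. The one-sided p-value
    uses the (1 + #{null <= observed}) / (1 + n) estimator: a smaller
    t-ratio means the data fills its polytope better than the null.

    The observed statistic is computed with exactly the same fit
    settings as the nulls, so observed and shuffled datasets are
    exchangeable under the null hypothesis and the test is calibrated.
    Reported archetype coordinates come from a higher-effort refit.
    """
    if n_shuffles < 100:
        raise ValueError("at least 100 shuffles are required")
    x = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    _, enclosing, observed = _fit_t_ratio(x, k, seed, n_restarts=n_restarts,
                                          max_iter=max_iter)
    arch = fit_archetypes(x, k, seed=seed, n_restarts=max(n_restarts, 10),
                          max_iter=max(max_iter, 200))
    null = np.empty(n_shuffles)
    shuffled = x.copy()
    for i in range(n_shuffles):
        for j in range(x.shape[1]):
            shuffled[:, j] = x[rng.permutation(x.shape[0]), j]
        _, _, null[i] = _fit_t_ratio(
            shuffled, k, seed=int(rng.integers(2**31)),
            n_restarts=n_restarts, max_iter=max_iter,
        )
    p = (1.0 + int(np.sum(null <= observed))) / (1.0 + n_shuffles)
    return PolyhedronFit(
        k=k,
        archetypes=arch,
        t_ratio=observed,
        p_value=p,
        n_shuffles=n_shuffles,
        seed=seed,
        enclosing=True,
        enclosing_simplex=enclosing,
        null_t_ratios=null,
    )


def select_k(
    scores_by_k: dict[int, np.ndarray],
    k_range: list[int],
    alpha: float = 0.01,
    n_shuffles: int = 1000,
    seed: int = 0,
    **fit_kwargs,
) -> PolyhedronFit | None:
    """Smallest k whose polytope is significant at ``alpha``; None otherwise.

    ``scores_by_k[k]`` holds the samples x (k-1) coordinates used for
    that candidate (the first k-1 PCs). Returns None when no candidate
    reaches significance — cohorts that appear as clouds without
    detectable vertices.
    """
    if sorted(k_range) != list(k_range) or min(k_range) < 3:
        raise ValueError("k_range must be ascending with values >= 3")
    for k in k_range:
        fit = shuffle_significance(scores_by_k[k], k, n_shuffles=n_shuffles,
                                   seed=seed, **fit_kwargs)
        if fit.p_value < alpha:
            return fit
    return None


def project_on_face(points: np.ndarray, face_archetypes: np.ndarray) -> np.ndarray:
    """Project points onto the 2D plane of a face defined by 3 archetypes.

    The basis is the Gram-Schmidt orthonormalization of (a2-a1, a3-a1);
    a1 maps to the origin and in-plane distances are preserved.
    """
    a = np.asarray(face_archetypes, dtype=float)
    if a.shape[0] != 3:
        raise ValueError("a face is defined by exactly 3 archetypes")
    b1 = a[1] - a[0]
    n1 = np.linalg.norm(b1)
    if n1 < 1e-12:
        raise ValueError("collinear (coincident) archetypes")
    e1 = b1 / n1
    b2 = a[2] - a[0]
    b2 = b2 - (b2 @ e1) * e1
    n2 = np.linalg.norm(b2)
    if n2 < 1e-12:
        raise ValueError("collinear archetypes: face has no area")
    e2 = b2 / n2
    p = np.atleast_2d(np.asarray(points, dtype=float)) - a[0]
    return np.column_stack([p @ e1, p @ e2])
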