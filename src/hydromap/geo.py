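"""Regional generalisation of plot-level CWM psi50.

Four cooperating pieces turn a scatter of plot values into a defensible
regional picture:

* **Geographically constrained Ward clustering** — agglomerative clustering
  whose merge criterion is a convex combination ``(1 - alpha) * delta0 +
  alpha * delta1`` of Ward pseudo-inertia increments computed from a feature
  dissimilarity matrix D0 and a geographic one D1. ``alpha = 0`` is plain
  Ward on the feature space; raising alpha buys spatial contiguity at the
  price of feature homogeneity, monitored through the explained
  pseudo-inertia proportions Q0 and Q1.
* **Inverse distance weighting (IDW)** with a coarse-to-fine leave-one-out
  search over the power ``idp`` and neighbour count ``nmax``.
* **Spatially constrained k-fold cross-validation** using the clusters as
  folds, reporting RMSE and the variance explained by cross-validation
  (VEcv), plus cluster point-average vs interpolated-average agreement.
* **MESS** (multivariate environmental similarity surface) extrapolation
  diagnostics: negative scores mark locations outside the environmental
  envelope of the reference plots.

All geometry is planar (km). Pseudo-inertia of a cluster C under
dissimilarity d with uniform weights is ``I(C) = sum_{i<j in C} d(i,j)^2 / |C|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import (
    InvalidArgumentError,
    InvalidFoldsError,
    InvalidMatrixError,
)
from .gridio import AsciiGrid, GridSpec

__all__ = [
    "ClusterSolution",
    "IdwParams",
    "Surface",
    "CvReport",
    "MessLayer",
    "constrained_ward",
    "select_alpha",
    "idw_predict",
    "loocv_rmse",
    "loocv_search",
    "fold_averaged_surface",
    "spatial_cv",
    "mess",
]

EXACT_HIT = 1e-9  # map-unit distance below which IDW returns the point value
ZERO_RANGE_SENTINEL = -1e9  # MESS score for a mismatched zero-range variable


# ---------------------------------------------------------------------------
# constrained Ward clustering


@dataclass
class ClusterSolution:
    """Result of one constrained-Ward run cut at k clusters."""

    alpha: float
    k: int
    labels: np.ndarray  # 0-based cluster index per observation
    q0: float  # proportion of feature-space pseudo-inertia explained
    q1: float  # proportion of geographic pseudo-inertia explained
    merges: np.ndarray  # (n-1, 2) merged cluster ids, scipy linkage numbering
    heights: np.ndarray  # mixed criterion value at each merge


def _check_dissimilarity(D: np.ndarray, name: str) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidMatrixError(f"{name} must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise InvalidMatrixError(f"{name} must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise InvalidMatrixError(f"{name} must have a zero diagonal")
    if (D < -1e-12).any():
        raise InvalidMatrixError(f"{name} must be non-negative")
    return D


def _pseudo_inertia_explained(D2: np.ndarray, labels: np.ndarray) -> float:
    """1 - sum_C I(C) / I(all) for squared dissimilarities D2."""
    n = D2.shape[0]
    total = D2.sum() / (2.0 * n)  # sum_{i<j} d^2 / n
    if total == 0:
        return 1.0
    within = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        within += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return float(1.0 - within / total)


def constrained_ward(
    D0: np.ndarray,
    D1: np.ndarray,
    alpha: float,
    k: int,
    normalize: bool = True,
) -> ClusterSolution:
    """Ward-like agglomeration under a mixed feature/geography criterion.

    At each step the pair of clusters whose merge minimises
    ``(1 - alpha) * delta0(A, B) + alpha * delta1(A, B)`` is joined, where
    ``delta_d(A, B) = I_d(A u B) - I_d(A) - I_d(B)`` is the pseudo-inertia
    increment in the respective space. With ``normalize`` each matrix is
    divided by its maximum before mixing so alpha compares like with like.
    The hierarchy is cut at ``k`` clusters; Q0/Q1 are the explained
    pseudo-inertia proportions of that partition in each (raw) space.
    Ties break toward the lexicographically smallest cluster pair.
    """
    D0 = _check_dissimilarity(D0, "D0")
    D1 = _check_dissimilarity(D1, "D1")
    if D0.shape != D1.shape:
        raise InvalidMatrixError("D0 and D1 must have the same shape")
    if not 0.0 <= alpha <= 1.0:
        raise InvalidArgumentError("alpha must lie in [0, 1]")
    n = D0.shape[0]
    if not 1 <= k <= n:
        raise InvalidArgumentError(f"k must lie in [1, {n}]")
    S0_raw, S1_raw = D0**2, D1**2
    e0 = D0 / D0.max() if (normalize and D0.max() > 0) else D0
    e1 = D1 / D1.max() if (normalize and D1.max() > 0) else D1
    # cross-sum matrices between current clusters, within sums, sizes
    X0, X1 = e0**2, e1**2
    W0 = np.zeros(n)
    W1 = np.zeros(n)
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    ids = np.arange(n)  # scipy-style cluster ids
    members: list[list[int]] = [[i] for i in range(n)]
    merges = np.zeros((n - 1, 2), dtype=int)
    heights = np.zeros(n - 1)
    labels_at_k: np.ndarray | None = None
    current = np.arange(n)  # observation -> active slot
    next_id = n
    for step in range(n - 1):
        sz = sizes
        pair_sz = sz[:, None] + sz[None, :]
        d0 = (W0[:, None] + W0[None, :] + X0) / pair_sz - (W0 / sz)[:, None] - (
            W0 / sz
        )[None, :]
        d1 = (W1[:, None] + W1[None, :] + X1) / pair_sz - (W1 / sz)[:, None] - (
            W1 / sz
        )[None, :]
        crit = (1.0 - alpha) * d0 + alpha * d1
        crit[~active, :] = np.inf
        crit[:, ~active] = np.inf
        np.fill_diagonal(crit, np.inf)
        flat = int(np.argmin(crit))  # row-major: ties -> smallest (i, j)
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        merges[step] = (ids[i], ids[j])
        heights[step] = crit[i, j]
        # merge j into i
        W0[i] = W0[i] + W0[j] + X0[i, j]
        W1[i] = W1[i] + W1[j] + X1[i, j]
        X0[i, :] += X0[j, :]
        X0[:, i] = X0[i, :]
        X1[i, :] += X1[j, :]
        X1[:, i] = X1[i, :]
        sizes[i] += sizes[j]
        active[j] = False
        members[i] = members[i] + members[j]
        ids[i] = next_id
        next_id += 1
        n_clusters = n - step - 1
        if n_clusters == k:
            labels_at_k = np.empty(n, dtype=int)
            for new, slot in enumerate(np.flatnonzero(active)):
                labels_at_k[members[slot]] = new
    if labels_at_k is None:  # k == n
        labels_at_k = np.arange(n)
    del current
    q0 = _pseudo_inertia_explained(S0_raw, labels_at_k)
    q1 = _pseudo_inertia_explained(S1_raw, labels_at_k)
    return ClusterSolution(
        alpha=float(alpha),
        k=int(k),
        labels=labels_at_k,
        q0=q0,
        q1=q1,
        merges=merges,
        heights=heights,
    )


def select_alpha(
    D0: np.ndarray,
    D1: np.ndarray,
    k: int,
    alpha_grid=None,
    q0_tolerance: float = 0.1,
    normalize: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Pick the mixing parameter from the Q0/Q1 trade-off curves.

    Evaluates the alpha grid (default 0 to 1 in steps of 0.1), then returns
    the largest alpha whose feature-space explained inertia Q0 has not fallen
    more than ``q0_tolerance`` below the unconstrained value Q0(0) — i.e. the
    most spatial contiguity that does not deteriorate the feature solution.
    The full curves come back for graphical inspection and human override.
    """
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.min() < 0 or alpha_grid.max() > 1:
        raise InvalidArgumentError("alpha grid must lie within [0, 1]")
    rows = []
    for a in alpha_grid:
        sol = constrained_ward(D0, D1, alpha=a, k=k, normalize=normalize)
        rows.append({"alpha": float(a), "q0": sol.q0, "q1": sol.q1})
    curves = pd.DataFrame(rows).sort_values("alpha").reset_index(drop=True)
    baseline = float(curves.loc[curves["alpha"].idxmin(), "q0"])
    ok = curves[curves["q0"] >= baseline - q0_tolerance]
    chosen = float(ok["alpha"].max())
    return chosen, curves


# ---------------------------------------------------------------------------
# inverse distance weighting


@dataclass(frozen=True)
class IdwParams:
    """IDW tuning: inverse-distance power and neighbour count."""

    idp: float = 2.0
    nmax: int = 12

    def __post_init__(self):
        if self.idp < 0:
            raise InvalidArgumentError("idp must be >= 0")
        if self.nmax < 1:
            raise InvalidArgumentError("nmax must be >= 1")


def idw_predict(
    points: np.ndarray,
    values: np.ndarray,
    query: np.ndarray,
    params: IdwParams,
) -> np.ndarray:
    """Inverse-distance-weighted prediction at query locations.

    Uses the ``nmax`` nearest data points with weights ``d^-idp``; a query
    within ``1e-9`` map units of a data point returns that point's value
    exactly. ``idp = 0`` degrades to the unweighted mean of the neighbours.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    query = np.atleast_2d(np.asarray(query, dtype=float))
    if len(points) == 0:
        raise InvalidArgumentError("point set is empty")
    if len(points) != len(values):
        raise InvalidArgumentError("points and values must align")
    kq = min(params.nmax, len(points))
    tree = cKDTree(points)
    dist, idx = tree.query(query, k=kq)
    if kq == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    neigh = values[idx]
    exact = dist[:, 0] < EXACT_HIT
    with np.errstate(divide="ignore"):
        w = np.where(dist < EXACT_HIT, np.inf, dist) ** (-params.idp)
    pred = np.sum(w * neigh, axis=1) / np.sum(w, axis=1)
    if params.idp == 0:
        pred = neigh.mean(axis=1)
    pred[exact] = neigh[exact, 0]
    return pred


def loocv_rmse(
    points: np.ndarray, values: np.ndarray, params: IdwParams
) -> float:
    """Leave-one-out RMSE of IDW with the given parameters."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    n = len(points)
    if n < 3:
        raise InvalidArgumentError("need at least 3 points for LOOCV")
    kq = min(params.nmax + 1, n)
    tree = cKDTree(points)
    dist, idx = tree.query(points, k=kq)
    preds = np.empty(n)
    for i in range(n):
        mask = idx[i] != i
        d = dist[i][mask][: params.nmax]
        nb = idx[i][mask][: params.nmax]
        if d.size == 0:  # all neighbours coincide with i; fall back to rest
            others = np.flatnonzero(np.arange(n) != i)
            preds[i] = values[others].mean()
            continue
        if d[0] < EXACT_HIT:
            preds[i] = values[nb[0]]
        elif params.idp == 0:
            preds[i] = values[nb].mean()
        else:
            w = d ** (-params.idp)
            preds[i] = np.dot(w, values[nb]) / w.sum()
    return float(np.sqrt(np.mean((preds - values) ** 2)))


def loocv_search(
    points: np.ndarray,
    values: np.ndarray,
    idp_grid=None,
    nmax_grid=None,
    n_refine_steps: int = 3,
    shrink: float = 3.0,
) -> tuple[IdwParams, pd.DataFrame]:
    """Coarse-to-fine LOOCV search for the IDW parameters.

    Each step evaluates the current ``idp x nmax`` grid by leave-one-out
    RMSE; the idp grid is then re-centred on the incumbent and shrunk by
    ``shrink`` (the neighbour-count grid is discrete and stays fixed). Ties
    break toward smaller idp, then smaller nmax. Returns the best parameters
    and the full RMSE trace.
    """
    if idp_grid is None:
        idp_grid = np.arange(0.0, 4.0001, 0.5)
    if nmax_grid is None:
        nmax_grid = np.array([4, 8, 16, 32, 64])
    idp_grid = np.unique(np.asarray(idp_grid, dtype=float))
    nmax_grid = np.unique(np.asarray(nmax_grid, dtype=int))
    if idp_grid.size == 0 or nmax_grid.size == 0 or (idp_grid < 0).any() or (
        nmax_grid < 1
    ).any():
        raise InvalidArgumentError("degenerate parameter grids")
    best: tuple[float, float, int] | None = None  # (rmse, idp, nmax)
    trace = []
    span = float(idp_grid.max() - idp_grid.min()) if idp_grid.size > 1 else 1.0
    grid = idp_grid
    # RMSEs within float noise of each other count as ties (tie-break then
    # prefers smaller idp, then smaller nmax)
    tol = 1e-10 * max(1.0, float(np.abs(values).max()))
    for step in range(n_refine_steps):
        for idp in np.sort(grid):
            for nmax in np.sort(nmax_grid):
                rmse = loocv_rmse(points, values, IdwParams(float(idp), int(nmax)))
                trace.append(
                    {"step": step + 1, "idp": float(idp), "nmax": int(nmax),
                     "rmse": rmse}
                )
                cand = (float(idp), int(nmax))
                if (
                    best is None
                    or rmse < best[0] - tol
                    or (abs(rmse - best[0]) <= tol and cand < (best[1], best[2]))
                ):
                    best = (rmse, float(idp), int(nmax))
        span /= shrink
        lo = max(float(idp_grid.min()), best[1] - span)
        hi = min(float(idp_grid.max()), best[1] + span)
        grid = np.unique(np.round(np.linspace(lo, hi, 7), 12))
    assert best is not None
    return IdwParams(best[1], best[2]), pd.DataFrame(trace)


# ---------------------------------------------------------------------------
# surfaces


@dataclass
class Surface:
    """Interpolated CWM grid with provenance and per-fold layers."""

    grid: GridSpec
    values: np.ndarray  # (ny, nx), row 0 = south
    provenance: str  # 'per-fold' | 'averaged' | 'smoothed'
    fold_layers: list[np.ndarray] = field(default_factory=list)

    def to_ascii(self) -> AsciiGrid:
        return AsciiGrid(
            values=self.values,
            xll=self.grid.xll,
            yll=self.grid.yll,
            cell_size=self.grid.cell_size,
        )


def _truncated_mean_filter(values: np.ndarray, window: int) -> np.ndarray:
    """window x window mean with the window truncated at grid edges."""
    if window < 1 or window % 2 == 0:
        raise InvalidArgumentError("smooth_window must be a positive odd integer")
    if window == 1:
        return values.copy()
    kernel = np.ones((window, window))
    total = ndimage.convolve(values, kernel, mode="constant", cval=0.0)
    count = ndimage.convolve(
        np.ones_like(values), kernel, mode="constant", cval=0.0
    )
    return total / count


def _check_folds(folds: np.ndarray, n: int) -> np.ndarray:
    folds = np.asarray(folds)
    if folds.shape != (n,):
        raise InvalidFoldsError("folds must assign every point exactly once")
    uniq = np.unique(folds)
    if uniq.size < 2:
        raise InvalidFoldsError("need at least 2 folds")
    for f in uniq:
        if np.sum(folds == f) == n:
            raise InvalidFoldsError(f"fold {f!r} contains every point")
    return folds


def fold_averaged_surface(
    points: np.ndarray,
    values: np.ndarray,
    folds: np.ndarray,
    params: IdwParams,
    grid: GridSpec,
    smooth_window: int = 9,
    training: str = "complement",
) -> Surface:
    """Fold-wise IDW surfaces, smoothed and averaged into the final map.

    For each fold an IDW surface is interpolated from the *other* folds'
    points (or from all points with ``training='all'``), smoothed with a
    ``smooth_window`` square mean filter (truncated at edges), and the
    cell-wise mean across folds is returned. The smoothing suppresses the
    linear artefacts IDW produces where plots are sparse.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    folds = _check_folds(folds, len(points))
    if training not in ("complement", "all"):
        raise InvalidArgumentError("training must be 'complement' or 'all'")
    gx, gy = grid.meshgrid()
    query = np.column_stack([gx.ravel(), gy.ravel()])
    layers = []
    for f in np.unique(folds):
        mask = folds != f if training == "complement" else np.ones(
            len(points), dtype=bool
        )
        layer = idw_predict(points[mask], values[mask], query, params)
        layer = layer.reshape(grid.ny, grid.nx)
        layers.append(_truncated_mean_filter(layer, smooth_window))
    avg = np.mean(layers, axis=0)
    return Surface(grid=grid, values=avg, provenance="averaged", fold_layers=layers)


# ---------------------------------------------------------------------------
# spatial cross-validation


@dataclass
class CvReport:
    """Spatially constrained k-fold CV metrics."""

    fold_rmse: dict  # fold id -> RMSE (MPa)
    pooled_rmse: float
    vecv: float  # percent, <= 100
    predictions: pd.DataFrame  # fold, observed, predicted per held-out point
    cluster_agreement: pd.DataFrame | None = None  # point vs interpolated means


def spatial_cv(
    points: np.ndarray,
    values: np.ndarray,
    folds: np.ndarray,
    params: IdwParams,
    surface: Surface | None = None,
) -> CvReport:
    """Hold out each spatial cluster in turn and score the IDW predictions.

    Per-fold RMSE, pooled RMSE, and VEcv =
    ``(1 - SSE / SST) * 100`` over all held-out predictions (SST about the
    mean of the observations). When a ``surface`` is supplied, each cluster's
    point-average value is also compared with the mean of the surface cells
    inside the cluster's convex hull.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    folds = _check_folds(folds, len(points))
    rows = []
    for f in np.unique(folds):
        test = folds == f
        pred = idw_predict(points[~test], values[~test], points[test], params)
        for o, p in zip(values[test], pred):
            rows.append({"fold": f, "observed": float(o), "predicted": float(p)})
    preds = pd.DataFrame(rows)
    fold_rmse = {
        f: float(np.sqrt(np.mean((g["observed"] - g["predicted"]) ** 2)))
        for f, g in preds.groupby("fold")
    }
    err = preds["observed"] - preds["predicted"]
    pooled = float(np.sqrt(np.mean(err**2)))
    sst = float(np.sum((preds["observed"] - preds["observed"].mean()) ** 2))
    vecv = float((1.0 - np.sum(err**2) / sst) * 100.0) if sst > 0 else 100.0
    agreement = None
    if surface is not None:
        agreement = _cluster_agreement(points, values, folds, surface)
    return CvReport(
        fold_rmse=fold_rmse,
        pooled_rmse=pooled,
        vecv=vecv,
        predictions=preds,
        cluster_agreement=agreement,
    )


def _cluster_agreement(
    points: np.ndarray,
    values: np.ndarray,
    folds: np.ndarray,
    surface: Surface,
) -> pd.DataFrame:
    import shapely
    from shapely.geometry import MultiPoint

    gx, gy = surface.grid.meshgrid()
    rows = []
    for f in np.unique(folds):
        mask = folds == f
        point_avg = float(values[mask].mean())
        hull = MultiPoint([tuple(p) for p in points[mask]]).convex_hull
        inside = shapely.intersects_xy(hull, gx.ravel(), gy.ravel())
        cells = surface.values.ravel()[inside]
        interp_avg = float(cells.mean()) if cells.size else np.nan
        rows.append(
            {
                "cluster": f,
                "n_points": int(mask.sum()),
                "point_average": point_avg,
                "interpolated_average": interp_avg,
                "n_cells": int(inside.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MESS


@dataclass
class MessLayer:
    """Per-cell worst-variable environmental similarity."""

    scores: np.ndarray  # (ny, nx) or arbitrary query shape
    limiting: np.ndarray  # index into `variables` of the worst variable
    variables: list[str]

    @property
    def extrapolating(self) -> np.ndarray:
        """Boolean mask of cells outside the reference envelope."""
        return self.scores < 0


def _mess_one(ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Similarity score of query values against one reference variable.

    With f the percentage of reference values strictly below the query:
    f = 0 -> 100 (q - min)/(max - min); 0 < f <= 50 -> 2 f;
    50 < f < 100 -> 2 (100 - f); f = 100 -> 100 (max - q)/(max - min).
    Values below the minimum or above the maximum come out negative.
    """
    ref = np.sort(np.asarray(ref, dtype=float))
    n = ref.size
    rmin, rmax = ref[0], ref[-1]
    span = rmax - rmin
    q = np.asarray(q, dtype=float)
    if span == 0:
        out = np.where(q == rmin, 100.0, ZERO_RANGE_SENTINEL)
        if (q != rmin).any():
            warnings.warn(
                "zero-range reference variable with non-matching query values",
                stacklevel=3,
            )
        return out
    f = 100.0 * np.searchsorted(ref, q, side="left") / n
    out = np.where(
        f == 0,
        100.0 * (q - rmin) / span,
        np.where(
            f <= 50,
            2.0 * f,
            np.where(f < 100, 2.0 * (100.0 - f), 100.0 * (rmax - q) / span),
        ),
    )
    return out


def mess(
    reference: dict[str, np.ndarray],
    query: dict[str, np.ndarray],
) -> MessLayer:
    """Multivariate environmental similarity of query cells vs reference plots.

    ``reference`` maps variable name to the values observed at the source
    plots; ``query`` maps the same names to equally shaped query grids. Each
    cell's score is the *worst* per-variable similarity, with the arg-min
    variable recorded; scores below zero flag extrapolation beyond the
    reference min-max envelope.
    """
    if not reference:
        raise InvalidArgumentError("need at least one reference variable")
    names = sorted(reference)
    if sorted(query) != names:
        raise InvalidArgumentError("reference and query variables must match")
    shapes = {np.asarray(query[v]).shape for v in names}
    if len(shapes) != 1:
        raise InvalidArgumentError("query grids must share one shape")
    scores = []
    for v in names:
        ref = np.asarray(reference[v], dtype=float)
        if ref.size == 0:
            raise InvalidArgumentError(f"reference for {v!r} is empty")
        scores.append(_mess_one(ref, np.asarray(query[v], dtype=float)))
    stack = np.stack(scores)
    limiting = np.argmin(stack, axis=0)
    return MessLayer(
        scores=np.min(stack, axis=0), limiting=limiting, variables=names
    )
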