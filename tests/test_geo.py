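"""Tests of clustering, interpolation, cross-validation and MESS."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hydromap.errors import (
    InvalidArgumentError,
    InvalidFoldsError,
    InvalidMatrixError,
)
from hydromap.geo import (
    IdwParams,
    _truncated_mean_filter,
    constrained_ward,
    fold_averaged_surface,
    idw_predict,
    loocv_rmse,
    loocv_search,
    mess,
    select_alpha,
    spatial_cv,
)
from hydromap.gridio import GridSpec


def euclid(X):
    X = np.atleast_2d(X.T).T
    return np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))


# ---------------------------------------------------------------------------
# constrained Ward


def pseudo_inertia(D2, members):
    return sum(
        D2[np.ix_(c, c)].sum() / (2.0 * len(c)) for c in members
    )


def greedy_oracle(D0, D1, alpha):
    """From-scratch greedy merges recomputing every delta from member lists."""
    n = D0.shape[0]
    e0 = D0 / D0.max() if D0.max() > 0 else D0
    e1 = D1 / D1.max() if D1.max() > 0 else D1
    S0, S1 = e0**2, e1**2
    clusters = [[i] for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            u = clusters[i] + clusters[j]

            def delta(S):
                return (
                    S[np.ix_(u, u)].sum() / (2 * len(u))
                    - S[np.ix_(clusters[i], clusters[i])].sum()
                    / (2 * len(clusters[i]))
                    - S[np.ix_(clusters[j], clusters[j])].sum()
                    / (2 * len(clusters[j]))
                )

            crit = (1 - alpha) * delta(S0) + alpha * delta(S1)
            if best is None or crit < best[0] - 1e-12:
                best = (crit, i, j)
        _, i, j = best
        merges.append((sorted(clusters[i]), sorted(clusters[j])))
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return merges


@pytest.mark.parametrize("alpha", [0.0, 0.3, 1.0])
def test_hierarchy_matches_brute_force_merge_oracle(alpha):
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(8, 2))
    feats = rng.normal(size=8)
    D0, D1 = euclid(feats), euclid(pts)
    sol = constrained_ward(D0, D1, alpha=alpha, k=1)
    oracle = greedy_oracle(D0, D1, alpha)
    # replay the implementation's merges into member lists
    members = {i: [i] for i in range(8)}
    nxt = 8
    for step, (a, b) in enumerate(sol.merges):
        ga, gb = sorted(members.pop(a)), sorted(members.pop(b))
        assert {tuple(ga), tuple(gb)} == {
            tuple(oracle[step][0]), tuple(oracle[step][1])
        }
        members[nxt] = ga + gb
        nxt += 1


def test_alpha_zero_ignores_geography():
    rng = np.random.default_rng(3)
    feats = np.concatenate([rng.normal(0, 0.1, 6), rng.normal(5, 0.1, 6)])
    pts = rng.normal(size=(12, 2)) * 10  # geography uncorrelated with features
    sol = constrained_ward(euclid(feats), euclid(pts), alpha=0.0, k=2)
    labels = sol.labels
    assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
    assert labels[0] != labels[6]


def test_alpha_one_recovers_spatial_blobs():
    rng = np.random.default_rng(4)
    blob_a = rng.normal([0, 0], 0.5, size=(10, 2))
    blob_b = rng.normal([20, 20], 0.5, size=(10, 2))
    pts = np.vstack([blob_a, blob_b])
    feats = rng.normal(size=20)  # features pure noise
    sol = constrained_ward(euclid(feats), euclid(pts), alpha=1.0, k=2)
    assert len(set(sol.labels[:10])) == 1
    assert sol.labels[0] != sol.labels[10]


def test_pseudo_inertia_is_conserved():
    """Between + within pseudo-inertia equals the total, in both spaces."""
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(15, 2))
    feats = rng.normal(size=(15, 3))
    D0, D1 = euclid(feats), euclid(pts)
    sol = constrained_ward(D0, D1, alpha=0.4, k=4)
    for D, q in ((D0, sol.q0), (D1, sol.q1)):
        D2 = D**2
        n = len(D)
        total = D2.sum() / (2 * n)
        members = [np.flatnonzero(sol.labels == c) for c in range(4)]
        within = pseudo_inertia(D2, members)
        assert (1 - within / total) == pytest.approx(q, abs=1e-8)
        assert 0.0 <= q <= 1.0


def test_invalid_matrices_rejected():
    D = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(InvalidMatrixError):
        constrained_ward(D, np.zeros((2, 2)), 0.5, 1)
    with pytest.raises(InvalidMatrixError):
        constrained_ward(np.zeros((2, 2)), np.zeros((3, 3)), 0.5, 1)


# ---------------------------------------------------------------------------
# alpha selection


def test_identical_spaces_return_grid_maximum():
    rng = np.random.default_rng(6)
    D = euclid(rng.normal(size=(10, 2)))
    alpha, curves = select_alpha(D, D.copy(), k=3)
    assert alpha == 1.0
    assert np.allclose(curves["q0"], curves["q0"].iloc[0])


def test_zero_tolerance_with_decreasing_q0_returns_zero():
    rng = np.random.default_rng(7)
    feats = np.concatenate([rng.normal(0, 0.05, 5), rng.normal(4, 0.05, 5)])
    pts = rng.permutation(np.linspace(0, 10, 10))  # conflicts with features
    D0, D1 = euclid(feats), euclid(pts)
    alpha, curves = select_alpha(D0, D1, k=2, q0_tolerance=0.0)
    assert curves["q0"].iloc[0] == curves["q0"].max()
    assert alpha == pytest.approx(curves.loc[
        curves["q0"] >= curves["q0"].iloc[0], "alpha"].max())


def test_selection_matches_grid_walk_oracle(small_bundle):
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(20, 2))
    feats = pts[:, 0] * 0.7 + rng.normal(size=20) * 0.5  # correlated spaces
    D0, D1 = euclid(feats), euclid(pts)
    tol = 0.1
    alpha, curves = select_alpha(D0, D1, k=4, q0_tolerance=tol)
    # hand-stepped rule over the returned curves
    base = curves.loc[curves["alpha"].idxmin(), "q0"]
    expect = curves.loc[curves["q0"] >= base - tol, "alpha"].max()
    assert alpha == pytest.approx(expect)


# ---------------------------------------------------------------------------
# IDW


def test_query_at_data_point_returns_its_value():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    vals = np.array([-1.0, -2.0, -3.0])
    out = idw_predict(pts, vals, np.array([[1.0, 0.0]]), IdwParams(2.0, 3))
    assert out[0] == -2.0


def test_equidistant_points_average():
    pts = np.array([[-1.0, 0.0], [1.0, 0.0]])
    vals = np.array([-1.0, -3.0])
    for idp in (0.5, 2.0, 4.0):
        out = idw_predict(pts, vals, np.array([[0.0, 0.0]]),
                          IdwParams(idp, 2))
        assert out[0] == pytest.approx(-2.0)


def test_power_zero_is_unweighted_neighbour_mean():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
    vals = np.array([-1.0, -2.0, -9.0])
    out = idw_predict(pts, vals, np.array([[0.4, 0.0]]), IdwParams(0.0, 2))
    assert out[0] == pytest.approx(-1.5)


def test_prediction_bounded_by_neighbour_values():
    rng = np.random.default_rng(9)
    pts = rng.uniform(0, 10, size=(30, 2))
    vals = rng.normal(-2, 0.5, 30)
    q = rng.uniform(0, 10, size=(50, 2))
    out = idw_predict(pts, vals, q, IdwParams(1.5, 8))
    assert (out >= vals.min() - 1e-12).all()
    assert (out <= vals.max() + 1e-12).all()


def test_empty_point_set_rejected():
    with pytest.raises(InvalidArgumentError):
        idw_predict(np.empty((0, 2)), np.empty(0), np.zeros((1, 2)),
                    IdwParams())


# ---------------------------------------------------------------------------
# LOOCV search


def naive_loocv(pts, vals, params):
    errs = []
    for i in range(len(pts)):
        others = np.ones(len(pts), dtype=bool)
        others[i] = False
        pred = idw_predict(pts[others], vals[others], pts[[i]], params)
        errs.append((pred[0] - vals[i]) ** 2)
    return float(np.sqrt(np.mean(errs)))


def test_loocv_rmse_matches_naive_loop_oracle():
    rng = np.random.default_rng(10)
    pts = rng.uniform(0, 100, size=(40, 2))
    vals = rng.normal(-2, 0.4, 40)
    for params in (IdwParams(0.0, 4), IdwParams(1.0, 8), IdwParams(3.0, 50)):
        assert loocv_rmse(pts, vals, params) == pytest.approx(
            naive_loocv(pts, vals, params), abs=1e-12
        )


def test_constant_values_tie_break_to_smallest_grid_entry():
    rng = np.random.default_rng(11)
    pts = rng.uniform(0, 10, size=(10, 2))
    vals = np.full(10, -2.0)
    params, trace = loocv_search(pts, vals, idp_grid=[0.5, 1.0, 2.0],
                                 nmax_grid=[4, 8])
    np.testing.assert_allclose(trace["rmse"], 0.0, atol=1e-12)
    assert params.idp == 0.5 and params.nmax == 4


def test_search_recovers_generating_parameters():
    """Data produced by IDW with known params; search lands nearby."""
    rng = np.random.default_rng(12)
    anchors = rng.uniform(0, 100, size=(25, 2))
    anchor_vals = rng.normal(-2, 1.0, 25)
    true = IdwParams(2.0, 4)
    pts = rng.uniform(0, 100, size=(80, 2))
    vals = idw_predict(anchors, anchor_vals, pts, true)
    vals += rng.normal(0, 1e-4, len(vals))
    params, trace = loocv_search(pts, vals, idp_grid=np.arange(0, 4.01, 1.0),
                                 nmax_grid=[2, 4, 8, 32])
    best_rmse = trace["rmse"].min()
    rmse_at_true = loocv_rmse(pts, vals, true)
    assert best_rmse <= rmse_at_true * 1.05


def test_degenerate_grids_rejected():
    with pytest.raises(InvalidArgumentError):
        loocv_search(np.zeros((5, 2)), np.zeros(5), idp_grid=[],
                     nmax_grid=[4])


# ---------------------------------------------------------------------------
# fold-averaged surface


def grid_spec():
    return GridSpec(xll=0.0, yll=0.0, cell_size=1.0, nx=20, ny=20)


def scatter(seed, n=30):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 20, size=(n, 2))
    vals = -2.0 + 0.05 * pts[:, 0] + rng.normal(0, 0.1, n)
    folds = rng.integers(0, 3, n)
    return pts, vals, folds


def test_constant_values_survive_smoothing_and_averaging():
    pts, _, folds = scatter(1)
    vals = np.full(len(pts), -2.5)
    surf = fold_averaged_surface(pts, vals, folds, IdwParams(1.0, 8),
                                 grid_spec(), smooth_window=9)
    np.testing.assert_allclose(surf.values, -2.5, atol=1e-12)


def test_window_one_is_identity_smoothing():
    pts, vals, folds = scatter(2)
    raw = fold_averaged_surface(pts, vals, folds, IdwParams(1.0, 8),
                                grid_spec(), smooth_window=1)
    np.testing.assert_allclose(
        raw.values, np.mean(raw.fold_layers, axis=0), atol=1e-12
    )


def test_surface_matches_dense_loop_oracle():
    pts, vals, folds = scatter(3)
    params = IdwParams(1.5, 6)
    g = grid_spec()
    w = 3
    surf = fold_averaged_surface(pts, vals, folds, params, g, smooth_window=w)
    # oracle: three nested loops over folds, cells, window
    xs, ys = g.x_centers(), g.y_centers()
    layers = []
    for f in np.unique(folds):
        train = folds != f
        layer = np.empty((g.ny, g.nx))
        for iy, y in enumerate(ys):
            for ix, x in enumerate(xs):
                layer[iy, ix] = idw_predict(
                    pts[train], vals[train], np.array([[x, y]]), params
                )[0]
        sm = np.empty_like(layer)
        h = w // 2
        for iy in range(g.ny):
            for ix in range(g.nx):
                block = layer[
                    max(0, iy - h): iy + h + 1, max(0, ix - h): ix + h + 1
                ]
                sm[iy, ix] = block.mean()
        layers.append(sm)
    np.testing.assert_allclose(surf.values, np.mean(layers, axis=0),
                               atol=1e-10)


def test_truncated_filter_equals_block_means():
    rng = np.random.default_rng(4)
    a = rng.normal(size=(7, 5))
    sm = _truncated_mean_filter(a, 3)
    assert sm[0, 0] == pytest.approx(a[:2, :2].mean())
    assert sm[3, 2] == pytest.approx(a[2:5, 1:4].mean())


def test_fold_containing_all_points_rejected():
    pts, vals, _ = scatter(5)
    with pytest.raises(InvalidFoldsError):
        fold_averaged_surface(pts, vals, np.zeros(len(pts), dtype=int),
                              IdwParams(), grid_spec())


# ---------------------------------------------------------------------------
# spatial CV


def test_perfect_predictions_bound():
    """Duplicated points across folds make held-out predictions exact hits."""
    pts = np.array([[0, 0], [1, 0], [0, 1], [0, 0], [1, 0], [0, 1]],
                   dtype=float)
    vals = np.array([-1.0, -2.0, -3.0, -1.0, -2.0, -3.0])
    folds = np.array([0, 0, 0, 1, 1, 1])
    rep = spatial_cv(pts, vals, folds, IdwParams(2.0, 1))
    assert rep.pooled_rmse == pytest.approx(0.0, abs=1e-12)
    assert rep.vecv == pytest.approx(100.0)


def test_global_mean_predictions_give_vecv_zero():
    rep_pred = np.array([-2.0, -2.5, -1.5, -2.2, -1.8])
    obs = rep_pred.copy()
    preds = np.full(5, obs.mean())
    sse = np.sum((obs - preds) ** 2)
    sst = np.sum((obs - obs.mean()) ** 2)
    assert (1 - sse / sst) * 100 == pytest.approx(0.0)


def test_cv_matches_naive_fold_loop(small_bundle):
    rng = np.random.default_rng(6)
    pts = rng.uniform(0, 100, size=(40, 2))
    vals = rng.normal(-2, 0.3, 40)
    folds = rng.integers(0, 4, 40)
    params = IdwParams(1.0, 8)
    rep = spatial_cv(pts, vals, folds, params)
    errs = []
    for f in np.unique(folds):
        test = folds == f
        pred = idw_predict(pts[~test], vals[~test], pts[test], params)
        fold_rmse = np.sqrt(np.mean((pred - vals[test]) ** 2))
        assert rep.fold_rmse[f] == pytest.approx(fold_rmse, abs=1e-12)
        errs.extend(vals[test] - pred)
    errs = np.array(errs)
    assert rep.pooled_rmse == pytest.approx(np.sqrt(np.mean(errs**2)))
    sst = np.sum((vals - vals.mean()) ** 2)
    assert rep.vecv == pytest.approx((1 - np.sum(errs**2) / sst) * 100)


def test_vecv_invariant_to_value_shift_rmse_to_translation():
    rng = np.random.default_rng(7)
    pts = rng.uniform(0, 50, size=(30, 2))
    vals = rng.normal(-2, 0.3, 30)
    folds = rng.integers(0, 3, 30)
    params = IdwParams(1.0, 6)
    a = spatial_cv(pts, vals, folds, params)
    b = spatial_cv(pts, vals + 5.0, folds, params)
    assert b.vecv == pytest.approx(a.vecv, abs=1e-9)
    c = spatial_cv(pts + 1000.0, vals, folds, params)
    assert c.pooled_rmse == pytest.approx(a.pooled_rmse, abs=1e-9)


def test_cluster_agreement_uses_convex_hulls():
    rng = np.random.default_rng(8)
    pts = np.vstack([rng.uniform(0, 8, (15, 2)), rng.uniform(12, 20, (15, 2))])
    vals = np.concatenate([np.full(15, -1.0), np.full(15, -3.0)])
    folds = np.array([0] * 15 + [1] * 15)
    g = GridSpec(0.0, 0.0, 1.0, 20, 20)
    surf = fold_averaged_surface(pts, vals, folds, IdwParams(2.0, 5), g,
                                 smooth_window=1, training="all")
    rep = spatial_cv(pts, vals, folds, IdwParams(2.0, 5), surface=surf)
    ag = rep.cluster_agreement.set_index("cluster")
    assert ag.loc[0, "point_average"] == pytest.approx(-1.0)
    # interpolated average inside each hull is dominated by that blob
    assert ag.loc[0, "interpolated_average"] > ag.loc[1, "interpolated_average"]


# ---------------------------------------------------------------------------
# MESS


def test_query_below_reference_minimum_is_negative():
    layer = mess({"v": np.array([1.0, 2.0, 3.0])}, {"v": np.array([0.5])})
    assert layer.scores[0] < 0


def test_query_at_reference_minimum_is_zero():
    layer = mess({"v": np.array([1.0, 2.0, 3.0])}, {"v": np.array([1.0])})
    assert layer.scores[0] == pytest.approx(0.0)


def mess_scalar_oracle(ref, p):
    ref = np.sort(ref)
    n = len(ref)
    f = 100.0 * np.sum(ref < p) / n
    rmin, rmax = ref[0], ref[-1]
    if f == 0:
        return 100.0 * (p - rmin) / (rmax - rmin)
    if f <= 50:
        return 2.0 * f
    if f < 100:
        return 2.0 * (100.0 - f)
    return 100.0 * (rmax - p) / (rmax - rmin)


def test_layer_matches_per_cell_per_variable_oracle():
    rng = np.random.default_rng(9)
    ref = {"a": rng.normal(0, 1, 100), "b": rng.uniform(5, 9, 100)}
    qa = rng.normal(0, 1.5, (6, 7))
    qb = rng.uniform(4, 10, (6, 7))
    layer = mess(ref, {"a": qa, "b": qb})
    for iy in range(6):
        for ix in range(7):
            sa = mess_scalar_oracle(ref["a"], qa[iy, ix])
            sb = mess_scalar_oracle(ref["b"], qb[iy, ix])
            assert layer.scores[iy, ix] == pytest.approx(min(sa, sb))
            assert layer.variables[layer.limiting[iy, ix]] == (
                "a" if sa <= sb else "b"
            )
    assert (layer.scores <= 100.0 + 1e-12).all()


def test_median_query_achieves_the_maximum_interior_score():
    """Even-sized reference, query at the exact half-way rank -> f = 50,
    the formula's maximum; no other query value scores higher."""
    ref = np.arange(1.0, 101.0)  # 100 values
    q_med = 50.5
    layer = mess({"v": ref}, {"v": np.array([q_med])})
    assert layer.scores[0] == pytest.approx(100.0)
    sweep = mess({"v": ref}, {"v": np.linspace(-10, 120, 500)})
    assert sweep.scores.max() <= layer.scores[0] + 1e-9


def test_zero_range_reference_sentinel():
    with pytest.warns(UserWarning):
        layer = mess({"v": np.array([2.0, 2.0])},
                     {"v": np.array([2.0, 3.0])})
    assert layer.scores[0] == pytest.approx(100.0)
    assert layer.scores[1] < -1e6


def test_extrapolation_never_triggers_for_constant_fields_inside():
    from hydromap.simulate import simulate_env_rasters

    grids = simulate_env_rasters((0, 0, 400, 300), 50.0, seed=2,
                                 constant={"mcwd": -300.0, "wtd": 8.0})
    ref = {n: g.sample([100, 200], [100, 150]) for n, g in grids.items()}
    layer = mess(ref, {n: g.values for n, g in grids.items()})
    assert not layer.extrapolating.any()


def test_variable_mismatch_rejected():
    with pytest.raises(InvalidArgumentError):
        mess({"a": np.array([1.0])}, {"b": np.array([1.0])})
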