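"""Masked TF-activity regression, progenitor DEG ranking, dynamics norms."""

import logging

import numpy as np
import pandas as pd
import pytest

from lineagevae import (RegulationMatrix, dynamics_norm_by_fate, fit_tf_weights,
                        lineage_fates, make_regulation_fixture, progenitor_degs,
                        tf_activity)
from lineagevae.trajectory import CellTrajectory, TrajectorySet


# ------------------------------------------------------------ fit_tf_weights
def test_exact_linear_relation_recovered(rng):
    x_tf = rng.normal(size=(30, 1)) + 2.0
    x_tg = 2.0 * x_tf
    W, b = fit_tf_weights(x_tf, x_tg, np.ones((1, 1)), ridge=0.0)
    assert np.isclose(W[0, 0], 2.0, atol=1e-10)
    assert np.isclose(b[0], 0.0, atol=1e-9)


def test_masked_entries_are_structural_zeros(rng):
    x_tf = rng.normal(size=(40, 3))
    x_tg = rng.normal(size=(40, 4))
    R = np.array([[1, 0, 1, 0],
                  [0, 0, 0, 0],     # TF 1 regulates nothing
                  [1, 1, 0, 1]])
    W, _ = fit_tf_weights(x_tf, x_tg, R, ridge=0.1)
    assert np.all(W[R == 0] == 0.0)
    assert np.all(W[1] == 0.0)


def _masked_normal_equations(x_tf, x_tg, R, ridge):
    """Independent oracle: per-target ridge solve by explicit normal
    equations with an unpenalized intercept (via centering)."""
    p, q = R.shape
    W = np.zeros((p, q))
    b = np.zeros(q)
    for j in range(q):
        allowed = np.where(R[:, j] == 1)[0]
        y = x_tg[:, j]
        if allowed.size == 0:
            b[j] = y.mean()
            continue
        X = x_tf[:, allowed]
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        A = Xc.T @ Xc + ridge * np.eye(allowed.size)
        w = np.linalg.solve(A, Xc.T @ yc)
        W[allowed, j] = w
        b[j] = y.mean() - X.mean(axis=0) @ w
    return W, b


def test_matches_normal_equations_oracle(rng):
    x_tf = rng.normal(size=(25, 5)) + 1.0
    x_tg = rng.normal(size=(25, 8))
    R = (rng.random((5, 8)) < 0.6).astype(int)
    R[0] = 1
    W, b = fit_tf_weights(x_tf, x_tg, R, ridge=0.1)
    Wo, bo = _masked_normal_equations(x_tf, x_tg, R, ridge=0.1)
    assert np.allclose(W, Wo, atol=1e-8)
    assert np.allclose(b, bo, atol=1e-8)


def test_allones_mask_ridge_zero_equals_ols(rng):
    x_tf = rng.normal(size=(30, 4))
    x_tg = rng.normal(size=(30, 3))
    W, b = fit_tf_weights(x_tf, x_tg, np.ones((4, 3), dtype=int), ridge=0.0)
    X1 = np.column_stack([np.ones(30), x_tf])
    coef, *_ = np.linalg.lstsq(X1, x_tg, rcond=None)
    assert np.allclose(W, coef[1:], atol=1e-8)
    assert np.allclose(b, coef[0], atol=1e-8)


def test_singular_and_degenerate_inputs(rng):
    x = rng.normal(size=(10, 1))
    dup = np.hstack([x, x])                     # collinear TFs
    y = rng.normal(size=(10, 1))
    with pytest.raises(np.linalg.LinAlgError, match="ridge"):
        fit_tf_weights(dup, y, np.ones((2, 1), dtype=int), ridge=0.0)
    with pytest.raises(ValueError, match="2 samples"):
        fit_tf_weights(x[:1], y[:1], np.ones((1, 1), dtype=int))


# ----------------------------------------------------------------- tf_activity
def test_fixture_noise_free_gain_recovered():
    series, reg, windows = make_regulation_fixture(
        n_tfs=1, n_targets_per_tf=3, n_times=4, n_samples=40, noise=0.0, seed=0)
    genes = reg.tf_names + reg.tg_names
    act = tf_activity(series, genes, reg, ridge=0.0)
    lo, hi = windows["TF_0"]
    for t in range(lo, hi):
        W = act.weights[t]
        assert np.allclose(W[0, :3], 2.0, atol=1e-8)


def test_planted_windows_recovered_and_normalized():
    series, reg, windows = make_regulation_fixture(seed=3)
    genes = reg.tf_names + reg.tg_names
    act = tf_activity(series, genes, reg, ridge=1e-3)
    A = act.activity
    assert ((A.to_numpy() >= 0) & (A.to_numpy() <= 1)).all()
    assert np.allclose(A.to_numpy().max(axis=1), 1.0)
    for tf, (lo, hi) in windows.items():
        peak = int(A[tf].idxmax())
        assert lo <= peak < hi
    # masked entries stay exactly zero in every fitted weight matrix
    for W in act.weights:
        assert np.all(W[reg.R == 0] == 0.0)


def test_single_tf_activity_is_one(rng):
    series = [rng.normal(size=(20, 3)) + 3.0 for _ in range(3)]
    reg = RegulationMatrix(R=np.array([[1, 1]]), tf_names=["TF_0"],
                           tg_names=["TG_0", "TG_1"])
    act = tf_activity(series, ["TF_0", "TG_0", "TG_1"], reg, ridge=1e-3)
    assert np.allclose(act.activity["TF_0"], 1.0)


def test_regulation_matrix_edge_list_and_alignment(caplog):
    edges = pd.DataFrame({"tf": ["A", "A", "B"], "tg": ["x", "y", "zmissing"]})
    reg = RegulationMatrix.from_edge_list(edges)
    assert reg.R.shape == (2, 3)
    with caplog.at_level(logging.WARNING):
        aligned = reg.align_to(["A", "B", "x", "y"])
    assert "zmissing" not in aligned.tg_names
    assert "B" not in aligned.tf_names      # left without permitted targets
    with pytest.raises(ValueError):
        RegulationMatrix(R=np.array([[2]]), tf_names=["A"], tg_names=["x"])


# ------------------------------------------------------------ progenitor_degs
def test_identical_groups_score_zero(rng):
    X = rng.gamma(3.0, 1.0, size=(30, 25))
    table = progenitor_degs(X, X.copy(), [f"g{j}" for j in range(25)], n_bins=5)
    assert np.allclose(table["score"], 0.0)
    assert np.allclose(table["delta_norm_dispersion"], 0.0)


def test_planted_upregulated_gene_ranks_first(rng):
    g = 40
    base = rng.gamma(3.0, 1.0, size=(40, g)) + 0.5
    up = base.copy()
    up[:, 7] *= 10.0
    table = progenitor_degs(up, base, [f"g{j}" for j in range(g)], n_bins=5)
    assert table.iloc[0]["gene"] == "g7"


def test_single_bin_reduces_to_global_zscore(rng):
    X1 = rng.gamma(3.0, 1.0, size=(25, 15))
    X2 = rng.gamma(3.0, 1.2, size=(25, 15))
    table = progenitor_degs(X1, X2, [f"g{j}" for j in range(15)], n_bins=1)

    def global_nd(X):
        mu = X.mean(0)
        disp = X.var(0, ddof=1) / mu
        return (disp - disp.mean()) / disp.std(ddof=1)

    want = global_nd(X1) - global_nd(X2)
    got = table.set_index("gene")["delta_norm_dispersion"]
    for j in range(15):
        assert np.isclose(got[f"g{j}"], want[j], atol=1e-10)


def test_mismatched_gene_sets_rejected(rng):
    with pytest.raises(ValueError):
        progenitor_degs(rng.random((5, 4)), rng.random((5, 3)), list("abcd"))


# ------------------------------------------------------- dynamics_norm_by_fate
def _traj_with_drifts(drift_by_fate):
    cells, chi = [], []
    for i, (fate, mag) in enumerate(drift_by_fate):
        drifts = np.full((3, 2), mag / np.sqrt(2))
        cells.append(CellTrajectory(
            cell_id=f"c{i}", barcode=f"L{i}", day=3,
            chain=np.zeros((3, 2)), drifts=drifts,
            step_scales=np.full((3, 2), 0.1)))
        chi.append(1.0)
    z0 = {f"L{i}": np.zeros((1, 2)) for i in range(len(drift_by_fate))}
    return TrajectorySet(cells=cells, z0=z0, chi=np.array(chi)), {
        f"L{i}": fate for i, (fate, _) in enumerate(drift_by_fate)}


def test_zero_drift_gives_zero_norms():
    traj, fates = _traj_with_drifts([("a", 0.0), ("b", 0.0)])
    out = dynamics_norm_by_fate(traj, fates)
    assert np.allclose(out.to_numpy(), 0.0)


def test_planted_fast_and_slow_fates_ordered_and_rotation_invariant():
    traj, fates = _traj_with_drifts([("fast", 1.0), ("fast", 1.0),
                                     ("slow", 0.1), ("slow", 0.1)])
    out = dynamics_norm_by_fate(traj, fates)
    assert (out["fast"] > out["slow"]).all()
    assert np.allclose(out["fast"], 1.0) and np.allclose(out["slow"], 0.1)
    # rigid rotation of the latent space leaves the norms unchanged
    theta = 0.7
    Rmat = np.array([[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]])
    for cell in traj.cells:
        cell.drifts = cell.drifts @ Rmat.T
    out_rot = dynamics_norm_by_fate(traj, fates)
    assert np.allclose(out.to_numpy(), out_rot.to_numpy(), atol=1e-12)


def test_unlabeled_lineages_excluded_with_warning(caplog):
    traj, fates = _traj_with_drifts([("a", 0.5), ("b", 0.2)])
    del fates["L1"]
    with caplog.at_level(logging.WARNING):
        out = dynamics_norm_by_fate(traj, fates)
    assert list(out.columns) == ["a"]
    assert any("without fate labels" in r.message for r in caplog.records)


def test_lineage_fates_majority_rule():
    barcodes = np.array(["L1"] * 4 + ["L2"] * 4)
    types = np.array(["mono", "mono", "mono", "neut",
                      "mono", "neut", "baso", "eos"])
    fates = lineage_fates(barcodes, types, min_fraction=0.5)
    assert fates == {"L1": "mono"}
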