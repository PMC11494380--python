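"""Embedding-evaluation metrics: k-NN day composition, silhouettes,
cell-type distances, held-out interpolation plumbing."""

import inspect

import numpy as np
import pytest

from lineagevae import (ModelConfig, SimConfig, celltype_distance,
                        heldout_interpolation, knn_day_ratio,
                        silhouette_by_step, simulate)


# ------------------------------------------------------------- knn_day_ratio
def test_queries_on_top_of_one_day(rng):
    ref2 = rng.normal(size=(40, 3)) * 0.1
    ref6 = rng.normal(size=(40, 3)) * 0.1 + 100.0
    refs = np.vstack([ref2, ref6])
    days = np.array([2] * 40 + [6] * 40)
    out = knn_day_ratio(ref2, refs, days, k=10)
    assert out[2] == pytest.approx(1.0)
    assert out[6] == pytest.approx(0.0)
    assert out.sum() == pytest.approx(1.0)


def test_matches_exhaustive_distance_oracle(rng):
    refs = rng.normal(size=(50, 4))
    days = rng.choice([2, 4, 6], size=50)
    queries = rng.normal(size=(20, 4))
    k = 7
    got = knn_day_ratio(queries, refs, days, k=k)
    # brute force: full distance matrix, stable argsort
    fractions = []
    for q in queries:
        d = np.linalg.norm(refs - q, axis=1)
        nearest = np.argsort(d, kind="stable")[:k]
        fractions.append([(days[nearest] == day).mean()
                          for day in np.unique(days)])
    want = np.mean(fractions, axis=0)
    assert np.allclose(got.to_numpy(), want, atol=1e-12)


def test_knn_defaults_and_errors(rng):
    assert inspect.signature(knn_day_ratio).parameters["k"].default == 30
    refs = rng.normal(size=(10, 2))
    with pytest.raises(ValueError, match="k="):
        knn_day_ratio(refs, refs, np.full(10, 2), k=11)


# --------------------------------------------------------- silhouette_by_step
def test_well_separated_blobs_score_high(rng):
    a = rng.normal(size=(30, 2)) * 0.05
    b = rng.normal(size=(30, 2)) * 0.05 + 2.0   # separation 40 x blob sd
    pts = np.vstack([a, b])
    labels = np.array(["a"] * 30 + ["b"] * 30)
    score = silhouette_by_step({1: pts}, {1: labels})
    assert score[1] > 0.8


def test_duplicated_identical_groups_score_near_zero(rng):
    """Zero separation: duplicating one cloud into two labels gives the
    no-structure score.  Each point's other-group mean distance includes its
    exact duplicate, so the standard silhouette is exactly -1/n, i.e. 0 up
    to the finite-sample correction."""
    n = 20
    pts = rng.normal(size=(n, 2))
    both = np.vstack([pts, pts])
    labels = np.array(["a"] * n + ["b"] * n)
    score = silhouette_by_step({1: both}, {1: labels})
    assert score[1] == pytest.approx(-1.0 / n, abs=1e-6)
    assert -1.0 <= score[1] <= 1.0


def test_singleton_groups_skipped_with_warning(rng, caplog):
    import logging

    pts = np.vstack([rng.normal(size=(10, 2)),
                     rng.normal(size=(10, 2)) + 5.0,
                     [[99.0, 99.0]]])
    labels = np.array(["a"] * 10 + ["b"] * 10 + ["lonely"])
    with caplog.at_level(logging.WARNING):
        score = silhouette_by_step({1: pts}, {1: labels})
    assert np.isfinite(score[1])
    assert any("singleton" in r.message for r in caplog.records)


# ----------------------------------------------------------- celltype_distance
def test_identical_point_sets_null_case(rng):
    pts = rng.normal(size=(30, 3))
    dist, pval = celltype_distance({"a": pts, "b": pts.copy()},
                                   n_permutations=200, seed=0)
    assert dist.loc["a", "b"] == pytest.approx(0.0)
    assert pval.loc["a", "b"] > 0.5
    assert np.allclose(dist.to_numpy(), dist.to_numpy().T)
    assert np.allclose(np.diag(dist.to_numpy()), 0.0)


def test_planted_separation_is_significant(rng):
    a = rng.normal(size=(40, 3))
    b = rng.normal(size=(40, 3)) + 10.0
    dist, pval = celltype_distance({"a": a, "b": b}, n_permutations=1000, seed=0)
    assert dist.loc["a", "b"] == pytest.approx(np.linalg.norm(
        a.mean(0) - b.mean(0)))
    assert pval.loc["a", "b"] <= 0.001


def test_small_types_excluded(rng):
    with pytest.raises(ValueError):
        celltype_distance({"a": rng.normal(size=(5, 2)),
                           "b": rng.normal(size=(1, 2))})


# ------------------------------------------------------ heldout_interpolation
def test_heldout_interpolation_contract():
    ds, _ = simulate(SimConfig(n_lineages=4, cells_per_lineage=12,
                               n_genes=60, latent_dim=4, seed=5))
    cfg = ModelConfig(latent_dim=5, epochs_phase1=10, epochs_phase2=15, seed=5)
    with pytest.raises(ValueError, match="not present"):
        heldout_interpolation(ds, cfg, heldout_day=3, k=5)
    table = heldout_interpolation(ds, cfg, heldout_day=4, k=5, seed=5)
    assert np.allclose(table.sum(axis=1), 1.0)
    assert set(table.columns) == {2, 4, 6}
    assert 4.0 in table.index          # the held-out day-equivalent row exists
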