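"""Quantitative evaluation of embeddings and inferred dynamics.

All metrics operate in the model's latent space: the day composition of the
k-nearest observed neighbors around inferred states (k = 30 by default),
per-backward-step silhouette scores, centroid distances between annotated
cell types with permutation p-values, and a held-out-day interpolation
experiment in which the model is retrained without one observation day and
the inferred states at the corresponding backward step are scored against
all observed cells projected through the frozen encoder.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .config import ModelConfig
from .core_model import train
from .io_preprocess import CellDataset
from .trajectory import infer_trajectories

logger = logging.getLogger(__name__)

__all__ = [
    "knn_day_ratio",
    "silhouette_by_step",
    "cohesion_silhouette_by_step",
    "celltype_distance",
    "heldout_interpolation",
]


def knn_day_ratio(query_points: np.ndarray, reference_points: np.ndarray,
                  reference_days: np.ndarray, k: int = 30) -> pd.Series:
    """Average per-day fraction among each query's k nearest reference cells.

    Euclidean distances in latent space; the per-query day composition is
    averaged over queries (each query contributes equally).  Nearest-neighbor
    ties are broken by stable index order.
    """
    query_points = np.atleast_2d(query_points)
    reference_points = np.atleast_2d(reference_points)
    reference_days = np.asarray(reference_days)
    if k > reference_points.shape[0]:
        raise ValueError(
            f"k={k} exceeds the {reference_points.shape[0]} reference points")
    nn = NearestNeighbors(n_neighbors=k, algorithm="brute").fit(reference_points)
    _, idx = nn.kneighbors(query_points)
    days = np.unique(reference_days)
    fractions = np.zeros((query_points.shape[0], len(days)))
    neighbor_days = reference_days[idx]            # (n_query, k)
    for d_i, d in enumerate(days):
        fractions[:, d_i] = (neighbor_days == d).mean(axis=1)
    return pd.Series(fractions.mean(axis=0), index=days, name="fraction")


def silhouette_by_step(points_by_step: dict[int, np.ndarray],
                       labels_by_step: dict[int, np.ndarray]) -> pd.Series:
    """Silhouette score of grouped latent states at each backward step.

    Groups with a single member are skipped with a warning; a step with fewer
    than two surviving groups yields NaN.
    """
    scores = {}
    for step in sorted(points_by_step):
        pts = np.asarray(points_by_step[step])
        labels = np.asarray(labels_by_step[step])
        counts = pd.Series(labels).value_counts()
        singletons = counts.index[counts < 2]
        if len(singletons):
            logger.warning("step %s: skipping %d singleton groups",
                           step, len(singletons))
            keep = ~np.isin(labels, singletons)
            pts, labels = pts[keep], labels[keep]
        if len(np.unique(labels)) < 2:
            scores[step] = np.nan
            continue
        scores[step] = float(silhouette_score(pts, labels))
    return pd.Series(scores, name="silhouette")


def cohesion_silhouette_by_step(traj, observed_latents: np.ndarray) -> pd.Series:
    """Two-group silhouette of inferred states against the observed cells.

    At each backward step the inferred states form one group and all observed
    cells (their encoder means) the other.  As inference goes back in time
    the inferred set contracts toward per-lineage progenitors, so its
    within-group distances shrink and the score rises — the backward-cohesion
    trend.  Chains should be posterior-mean trajectories; sampled chains add
    diffusion noise that grows backward and masks the trend.
    """
    observed_latents = np.atleast_2d(observed_latents)
    max_step = max(c.t0 for c in traj.cells)
    pts, labels = {}, {}
    for step in range(1, max_step + 1):
        states, _ = traj.states_at_step(step)
        pts[step] = np.concatenate([states, observed_latents])
        labels[step] = np.array(["inferred"] * len(states)
                                + ["observed"] * len(observed_latents))
    return silhouette_by_step(pts, labels)


def celltype_distance(latent_by_type: dict[str, np.ndarray],
                      n_permutations: int = 1000,
                      seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise centroid distances between cell types with permutation p-values.

    For each pair of types, the null distribution is obtained by permuting
    the pooled labels and recomputing the centroid distance; the p-value is
    the (add-one-smoothed) fraction of permuted distances at least as large
    as the observed one.  Types with fewer than two cells are excluded.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    usable = {}
    for name, pts in latent_by_type.items():
        pts = np.atleast_2d(pts)
        if pts.shape[0] < 2:
            logger.warning("excluding cell type %r with < 2 cells", name)
            continue
        usable[name] = pts
    names = sorted(usable)
    if len(names) < 2:
        raise ValueError("need at least two cell types with >= 2 cells")
    dist = pd.DataFrame(0.0, index=names, columns=names)
    pval = pd.DataFrame(np.nan, index=names, columns=names)
    for a_i, a in enumerate(names):
        for b in names[a_i + 1:]:
            pa, pb = usable[a], usable[b]
            d_obs = float(np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0)))
            pooled = np.concatenate([pa, pb])
            na = pa.shape[0]
            exceed = 0
            for _ in range(n_permutations):
                perm = rng.permutation(pooled.shape[0])
                d = np.linalg.norm(pooled[perm[:na]].mean(axis=0)
                                   - pooled[perm[na:]].mean(axis=0))
                exceed += d >= d_obs
            p = (1 + exceed) / (1 + n_permutations)
            dist.loc[a, b] = dist.loc[b, a] = d_obs
            pval.loc[a, b] = pval.loc[b, a] = p
    return dist, pval


def heldout_interpolation(ds: CellDataset, model_config: ModelConfig,
                          heldout_day: int, k: int = 30,
                          seed: int = 0) -> pd.DataFrame:
    """Retrain without one day and score inferred states at every step.

    The model is trained on all cells except those observed at
    ``heldout_day``; backward chains are inferred for the remaining cells and
    the latent states at each backward step (day equivalents) are compared —
    via :func:`knn_day_ratio` — against *all* observed cells, including the
    held-out ones, projected through the frozen encoder.  Returns a step ×
    day table of neighbor-day fractions (rows sum to 1).
    """
    if heldout_day not in set(ds.days.tolist()):
        raise ValueError(f"held-out day {heldout_day} is not present in the data")
    keep = ds.day != heldout_day
    train_ds = ds.subset_cells(np.where(keep)[0])
    model, _ = train(train_ds, model_config)
    traj = infer_trajectories(model, train_ds, n_samples=1, seed=seed,
                              use_mean=True)
    ref_mean, _ = model.encode(ds.spliced, ds.chi)
    rows = {}
    max_step = max(c.t0 for c in traj.cells)
    for step in range(1, max_step + 1):
        states, _ = traj.states_at_step(step)
        rows[step / model.config.steps_per_day] = knn_day_ratio(
            states, ref_mean, ds.day, k=k)
    out = pd.DataFrame(rows).T
    out.index.name = "day_equivalent"
    return out
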