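"""Downstream analytics on reconstructed time series.

Three analyses operate on the reconstructed expression along backward
trajectories:

* **TF activity** — a time-lagged masked linear regression: TF expression at
  time ``t`` explains target-gene (TG) expression at ``t+1``, with the
  coefficient ``w_tij`` structurally fixed to zero wherever the binary
  regulation matrix ``R`` has no TF→TG edge.  A TF's activity at ``t`` is the
  sum of its absolute weights, divided by the maximum such sum over TFs at
  that time, so activities lie in [0, 1] with max 1 per time step.
* **Progenitor differential genes** — per-gene mean and dispersion
  (variance/mean) in two groups of reconstructed progenitor expression,
  dispersion z-scored within equal-frequency bins of mean expression, genes
  ranked by the between-group difference of normalized dispersion plus the
  z-scored difference of log mean expression.
* **Dynamics norm by fate** — the mean Euclidean norm of the inferred
  backward drift ``rho * mu'(z_t)`` per step, grouped by each lineage's fate
  (majority observed cell type), a summary of when each fate moves fastest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, Ridge

from .trajectory import TrajectorySet

logger = logging.getLogger(__name__)

__all__ = [
    "RegulationMatrix",
    "TFActivity",
    "fit_tf_weights",
    "tf_activity",
    "progenitor_degs",
    "dynamics_norm_by_fate",
    "lineage_fates",
]


@dataclass
class RegulationMatrix:
    """Binary TF×TG mask of permitted regulatory edges."""

    R: np.ndarray
    tf_names: list[str]
    tg_names: list[str]

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R)
        if not np.isin(self.R, [0, 1]).all():
            raise ValueError("regulation matrix entries must be 0 or 1")
        self.R = self.R.astype(np.int64)
        if self.R.shape != (len(self.tf_names), len(self.tg_names)):
            raise ValueError("R shape inconsistent with TF/TG name lists")
        self.tf_names = list(map(str, self.tf_names))
        self.tg_names = list(map(str, self.tg_names))

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame) -> "RegulationMatrix":
        """Build from a two-column (TF, TG) edge table."""
        tf_col, tg_col = edges.columns[:2]
        tfs = list(pd.unique(edges[tf_col].astype(str)))
        tgs = list(pd.unique(edges[tg_col].astype(str)))
        R = np.zeros((len(tfs), len(tgs)), dtype=np.int64)
        ti = {t: i for i, t in enumerate(tfs)}
        gi = {t: i for i, t in enumerate(tgs)}
        for tf, tg in zip(edges[tf_col].astype(str), edges[tg_col].astype(str)):
            R[ti[tf], gi[tg]] = 1
        return cls(R=R, tf_names=tfs, tg_names=tgs)

    def align_to(self, gene_names) -> "RegulationMatrix":
        """Drop TFs/TGs that do not resolve to dataset genes (with warning),
        and TF rows left without any permitted edge."""
        genes = set(map(str, gene_names))
        keep_tf = [i for i, t in enumerate(self.tf_names) if t in genes]
        keep_tg = [j for j, t in enumerate(self.tg_names) if t in genes]
        dropped = (set(self.tf_names) | set(self.tg_names)) - genes
        dropped &= set(self.tf_names) | set(self.tg_names)
        unresolved = [t for t in self.tf_names + self.tg_names if t not in genes]
        if unresolved:
            logger.warning("dropping %d unresolved TF/TG names: %s",
                           len(unresolved), unresolved[:5])
        R = self.R[np.ix_(keep_tf, keep_tg)]
        tf_names = [self.tf_names[i] for i in keep_tf]
        nonzero = R.sum(axis=1) > 0
        if not nonzero.all():
            logger.warning("dropping %d TFs with no permitted targets",
                           int((~nonzero).sum()))
        return RegulationMatrix(
            R=R[nonzero], tf_names=[t for t, k in zip(tf_names, nonzero) if k],
            tg_names=[self.tg_names[j] for j in keep_tg],
        )


@dataclass
class TFActivity:
    """Normalized per-time TF activities and the underlying weights."""

    activity: pd.DataFrame          # time × TF, values in [0, 1]
    weights: list[np.ndarray]       # per time step: TF × TG matrix

    def __post_init__(self) -> None:
        A = self.activity.to_numpy()
        if A.size and (A.min() < -1e-12 or A.max() > 1 + 1e-12):
            raise ValueError("TF activities must lie in [0, 1]")


def fit_tf_weights(x_tf: np.ndarray, x_tg: np.ndarray, R: np.ndarray,
                   ridge: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Masked linear regression of next-step TG expression on TF expression.

    Solves, independently per target gene ``j``, the least-squares problem
    restricted to the TFs permitted by ``R[:, j]`` with an L2 penalty
    ``ridge * ||w||^2`` (intercept unpenalized); masked coefficients are
    exact structural zeros.  Returns (W, intercept).
    """
    x_tf = np.asarray(x_tf, dtype=np.float64)
    x_tg = np.asarray(x_tg, dtype=np.float64)
    R = np.asarray(R)
    n, p = x_tf.shape
    q = x_tg.shape[1]
    if R.shape != (p, q):
        raise ValueError(f"mask shape {R.shape} != (n_tf={p}, n_tg={q})")
    if x_tg.shape[0] != n:
        raise ValueError("TF and TG matrices must have the same sample count")
    if n < 2:
        raise ValueError("need at least 2 samples for the regression")
    W = np.zeros((p, q))
    intercept = np.zeros(q)
    for j in range(q):
        allowed = np.where(R[:, j] == 1)[0]
        y = x_tg[:, j]
        if allowed.size == 0:
            intercept[j] = y.mean()
            continue
        X = x_tf[:, allowed]
        if ridge == 0:
            Xc = X - X.mean(axis=0)
            if np.linalg.matrix_rank(Xc) < allowed.size:
                raise np.linalg.LinAlgError(
                    f"singular design for target column {j} with ridge=0; "
                    "use ridge > 0"
                )
            fit = LinearRegression().fit(X, y)
        else:
            fit = Ridge(alpha=ridge, solver="cholesky").fit(X, y)
        W[allowed, j] = fit.coef_
        intercept[j] = fit.intercept_
    return W, intercept


def tf_activity(expr_series, gene_names, reg: RegulationMatrix,
                ridge: float = 1e-3) -> TFActivity:
    """Time-lagged TF activity along an expression series.

    ``expr_series`` is a sequence of (samples × genes) matrices, one per
    consecutive time point, with columns named by ``gene_names``.  For every
    pair (t, t+1) the masked regression of TG expression at t+1 on TF
    expression at t is fitted; TF activity is the max-normalized sum of
    absolute weights.
    """
    series = [np.asarray(x, dtype=np.float64) for x in expr_series]
    if len(series) < 2:
        raise ValueError("need at least two consecutive time points")
    gene_index = {str(g): i for i, g in enumerate(gene_names)}
    reg = reg.align_to(list(gene_index))
    tf_idx = np.array([gene_index[t] for t in reg.tf_names])
    tg_idx = np.array([gene_index[t] for t in reg.tg_names])
    rows, weights = [], []
    for t in range(len(series) - 1):
        x_tf = series[t][:, tf_idx]
        x_tg = series[t + 1][:, tg_idx]
        if not np.any(x_tf) :
            logger.warning("all-zero TF expression at time %d; activity row is 0", t)
            rows.append(np.zeros(len(reg.tf_names)))
            weights.append(np.zeros_like(reg.R, dtype=np.float64))
            continue
        W, _ = fit_tf_weights(x_tf, x_tg, reg.R, ridge=ridge)
        sums = np.abs(W).sum(axis=1)
        top = sums.max()
        rows.append(sums / top if top > 0 else sums)
        weights.append(W)
    activity = pd.DataFrame(np.stack(rows), columns=reg.tf_names)
    activity.index.name = "time"
    return TFActivity(activity=activity, weights=weights)


def _binned_normalized_dispersion(expr: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and within-mean-bin z-scored dispersion (var/mean)."""
    mu = expr.mean(axis=0)
    var = expr.var(axis=0, ddof=1) if expr.shape[0] > 1 else np.zeros_like(mu)
    disp = np.divide(var, mu, out=np.zeros_like(var), where=mu > 0)
    q = min(n_bins, len(np.unique(mu)))
    bins = pd.qcut(mu, q=q, duplicates="drop", labels=False)
    normed = np.zeros_like(disp)
    for b in np.unique(bins):
        in_bin = bins == b
        d = disp[in_bin]
        sd = d.std(ddof=1) if in_bin.sum() > 1 else 0.0
        normed[in_bin] = (d - d.mean()) / sd if sd > 0 else 0.0
    return mu, normed


def progenitor_degs(expr_group1: np.ndarray, expr_group2: np.ndarray,
                    gene_names, n_bins: int = 20) -> pd.DataFrame:
    """Rank genes distinguishing two groups of reconstructed expression.

    For each group computes per-gene mean and binned normalized dispersion;
    genes are ranked (descending) by the difference in normalized dispersion
    plus the gene-wise z-scored difference in log1p mean expression, so a
    gene strongly upregulated or hyper-variable in group 1 ranks first.
    """
    expr_group1 = np.asarray(expr_group1, dtype=np.float64)
    expr_group2 = np.asarray(expr_group2, dtype=np.float64)
    if expr_group1.shape[1] != expr_group2.shape[1]:
        raise ValueError("the two groups must share the same gene set")
    if len(gene_names) != expr_group1.shape[1]:
        raise ValueError("gene_names length mismatch")
    mu1, nd1 = _binned_normalized_dispersion(expr_group1, n_bins)
    mu2, nd2 = _binned_normalized_dispersion(expr_group2, n_bins)
    dmean = np.log1p(mu1) - np.log1p(mu2)
    sd = dmean.std(ddof=1)
    dmean_z = (dmean - dmean.mean()) / sd if sd > 0 else np.zeros_like(dmean)
    score = (nd1 - nd2) + dmean_z
    out = pd.DataFrame({
        "gene": list(map(str, gene_names)),
        "mean_1": mu1, "mean_2": mu2,
        "norm_dispersion_1": nd1, "norm_dispersion_2": nd2,
        "delta_norm_dispersion": nd1 - nd2,
        "delta_log_mean_z": dmean_z,
        "score": score,
    })
    return out.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


def lineage_fates(barcodes: np.ndarray, cell_types: np.ndarray,
                  min_fraction: float = 0.5) -> dict[str, str]:
    """Majority cell type per lineage; lineages below ``min_fraction`` get none.

    ``min_fraction=0.5`` mirrors selecting lineages where at least half the
    cells share one differentiated type; presets for reprogramming-style
    enrichment thresholds can be applied by passing a different fraction.
    """
    fates: dict[str, str] = {}
    df = pd.DataFrame({"barcode": barcodes, "cell_type": cell_types})
    for bc, grp in df.groupby("barcode"):
        counts = grp["cell_type"].value_counts()
        if counts.iloc[0] / len(grp) >= min_fraction:
            fates[str(bc)] = str(counts.index[0])
    return fates


def dynamics_norm_by_fate(traj: TrajectorySet,
                          fate_labels: dict[str, str]) -> pd.DataFrame:
    """Mean backward-drift norm ``||rho * mu'(z_t)||`` per step and fate."""
    rows = []
    missing = set()
    for cell in traj.cells:
        fate = fate_labels.get(cell.barcode)
        if fate is None:
            missing.add(cell.barcode)
            continue
        norms = np.linalg.norm(cell.drifts, axis=1)
        for k in range(cell.t0):
            rows.append({"step": cell.t0 - k, "fate": fate, "norm": norms[k]})
    if missing:
        logger.warning("excluding %d lineages without fate labels: %s",
                       len(missing), sorted(missing)[:5])
    if not rows:
        raise ValueError("no lineage has a fate label")
    df = pd.DataFrame(rows)
    return df.pivot_table(index="step", columns="fate", values="norm",
                          aggfunc="mean")
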