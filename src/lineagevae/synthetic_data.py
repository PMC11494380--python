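"""Forward simulator for barcoded clonal scRNA-seq data with ground truth.

The simulator realizes the same generative law the model assumes, at a desk
scale that trains in minutes on one CPU.  Each lineage starts from one of a
few well-separated progenitor states in latent space; its cells then follow
independent stochastic paths drawn toward a fate-specific attractor (a
piecewise-linear drift field), one step per day, emitting Poisson spliced
counts through a fixed softplus-linear rate map and Poisson unspliced counts
through the splicing-kinetics relation on consecutive true latents.

Geometry of the default layout: progenitors sit at zero along the first
latent coordinate and are separated in the remaining coordinates; every fate
attractor is displaced by a common positive offset along the first
coordinate.  Differentiation therefore moves all lineages forward along
coordinate one, and the first gene's rate map loads only on that coordinate
— a planted, monotonically increasing "differentiation marker" used by the
reconstruction tests.  The returned :class:`SimTruth` records every latent
chain, progenitor, fate and kinetic parameter for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preprocess import CellDataset

__all__ = ["SimConfig", "SimTruth", "simulate", "make_regulation_fixture"]


@dataclass
class SimConfig:
    """Study conditions for the clonal simulator."""

    n_lineages: int = 10
    cells_per_lineage: int = 25
    latent_dim: int = 5
    n_genes: int = 200
    observation_days: tuple[int, ...] = (2, 4, 6)
    n_progenitors: int = 4
    progenitor_separation: float = 5.0
    fate_offset: float = 9.0          # forward displacement along coordinate 1
    drift_rate: float = 0.25          # per-day pull toward the fate attractor
    sigma0: float = 0.7               # progenitor draw scale around its mean
    sigma_sim: float = 0.3            # per-day diffusion scale
    library_log_mean: float = 1.0     # chi ~ LogNormal(log_mean, log_sd)
    library_log_sd: float = 0.3
    rate_gain: float = 0.8            # scale of the random linear rate map
    monotone_gene_gain: float = 1.0   # loading of gene 0 on coordinate 1
    beta_log_sd: float = 0.4          # beta, gamma ~ LogNormal(0, log_sd)
    gamma_log_sd: float = 0.4
    delta_t: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.observation_days = tuple(int(d) for d in self.observation_days)
        if sorted(self.observation_days) != list(self.observation_days):
            raise ValueError("observation_days must be sorted ascending")
        if min(self.observation_days) < 1:
            raise ValueError("observation days must be >= 1")
        if self.n_lineages < 1 or self.cells_per_lineage < 1:
            raise ValueError("need at least one lineage and one cell per lineage")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2 (coordinate 1 carries the "
                             "differentiation axis)")

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        d["observation_days"] = list(self.observation_days)
        return d

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        from dataclasses import fields as dc_fields
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated dataset."""

    z0: np.ndarray                  # (n_lineages, m) true progenitor draws
    progenitor_index: np.ndarray    # (n_lineages,) which progenitor mean
    progenitor_means: np.ndarray    # (n_progenitors, m)
    fate: np.ndarray                # (n_lineages,) fate label per lineage
    attractors: np.ndarray          # (n_progenitors, m)
    chains: list[np.ndarray]        # per cell: (day+1, m) latents z_0..z_day
    lineage_of_cell: np.ndarray     # (n_cells,) lineage index
    rate_weights: np.ndarray        # (m, g) softplus-linear emission map
    rate_bias: np.ndarray           # (g,)
    beta: np.ndarray                # (g,) true splicing rates
    gamma: np.ndarray               # (g,) true degradation rates
    monotone_gene: int = 0

    def rates(self, z: np.ndarray) -> np.ndarray:
        """Emission rate map lambda_sim(z) (per-gene, before chi scaling)."""
        a = np.atleast_2d(z) @ self.rate_weights + self.rate_bias
        lam = np.logaddexp(a, 0.0) + 0.05  # softplus with a small floor
        return lam[0] if np.ndim(z) == 1 else lam


def _softplus(a: np.ndarray) -> np.ndarray:
    return np.logaddexp(a, 0.0)


def simulate(cfg: SimConfig | None = None) -> tuple[CellDataset, SimTruth]:
    """Draw a barcoded clonal dataset and its ground truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    m, g = cfg.latent_dim, cfg.n_genes

    # progenitor means: zero on coordinate 1, separated in the rest
    prog = np.zeros((cfg.n_progenitors, m))
    for p in range(cfg.n_progenitors):
        direction = np.zeros(m - 1)
        direction[p % (m - 1)] = 1.0 if (p // (m - 1)) % 2 == 0 else -1.0
        prog[p, 1:] = cfg.progenitor_separation * direction
    # each progenitor's fate attractor: shifted forward along coordinate 1
    attractors = prog.copy()
    attractors[:, 0] += cfg.fate_offset

    # emission map: gene 0 is the planted monotone differentiation marker
    W = rng.normal(0.0, cfg.rate_gain / np.sqrt(m), size=(m, g))
    W[:, 0] = 0.0
    W[0, 0] = cfg.monotone_gene_gain
    b = rng.normal(0.0, 0.3, size=g)
    beta = np.exp(rng.normal(0.0, cfg.beta_log_sd, size=g))
    gamma = np.exp(rng.normal(0.0, cfg.gamma_log_sd, size=g))

    prog_of_lineage = np.arange(cfg.n_lineages) % cfg.n_progenitors
    z0 = prog[prog_of_lineage] + cfg.sigma0 * rng.standard_normal((cfg.n_lineages, m))
    fate_names = np.array([f"fate_{p}" for p in range(cfg.n_progenitors)])
    fate = fate_names[prog_of_lineage]

    truth = SimTruth(
        z0=z0, progenitor_index=prog_of_lineage, progenitor_means=prog,
        fate=fate, attractors=attractors, chains=[],
        lineage_of_cell=np.empty(0, dtype=np.int64),
        rate_weights=W, rate_bias=b, beta=beta, gamma=gamma, monotone_gene=0,
    )

    days_pool = np.array(cfg.observation_days)
    spliced_rows, unspliced_rows = [], []
    barcode, day_col, cell_ids, cell_type, lineage_of_cell = [], [], [], [], []
    for lin in range(cfg.n_lineages):
        target = attractors[prog_of_lineage[lin]]
        for c in range(cfg.cells_per_lineage):
            obs_day = int(days_pool[(lin * cfg.cells_per_lineage + c) % len(days_pool)])
            z = z0[lin].copy()
            chain = [z.copy()]
            for _ in range(obs_day):
                z = z + cfg.drift_rate * (target - z) \
                    + cfg.sigma_sim * rng.standard_normal(m)
                chain.append(z.copy())
            chain = np.stack(chain)
            truth.chains.append(chain)
            chi = float(np.exp(rng.normal(cfg.library_log_mean, cfg.library_log_sd)))
            lam_T = truth.rates(chain[-1])
            s = rng.poisson(chi * lam_T)
            lam_prev = truth.rates(chain[-2])
            u_rate = (lam_T - lam_prev + cfg.delta_t * gamma * lam_T) / (
                beta * cfg.delta_t)
            u = rng.poisson(chi * np.maximum(u_rate, 1e-6))
            spliced_rows.append(s)
            unspliced_rows.append(u)
            barcode.append(f"L{lin:03d}")
            day_col.append(obs_day)
            cell_ids.append(f"cell_{lin:03d}_{c:03d}")
            cell_type.append(str(fate[lin]))
            lineage_of_cell.append(lin)

    truth.lineage_of_cell = np.array(lineage_of_cell, dtype=np.int64)
    ds = CellDataset(
        spliced=np.stack(spliced_rows),
        unspliced=np.stack(unspliced_rows),
        barcode=np.array(barcode, dtype=object),
        day=np.array(day_col),
        cell_type=np.array(cell_type, dtype=object),
        gene_names=np.array([f"gene_{j}" for j in range(g)], dtype=object),
        cell_ids=np.array(cell_ids, dtype=object),
    )
    return ds, truth


def write_simulation(ds: CellDataset, truth: SimTruth, outdir) -> None:
    """Write MTX counts, metadata CSV and a ground-truth archive."""
    import json
    from pathlib import Path

    import scipy.io
    import scipy.sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "counts.mtx", scipy.sparse.csr_matrix(ds.spliced))
    if ds.unspliced is not None:
        scipy.io.mmwrite(outdir / "unspliced.mtx",
                         scipy.sparse.csr_matrix(ds.unspliced))
        (outdir / "unspliced.barcodes.txt").write_text(
            "\n".join(map(str, ds.cell_ids)) + "\n")
    (outdir / "counts.barcodes.txt").write_text("\n".join(map(str, ds.cell_ids)) + "\n")
    (outdir / "counts.genes.txt").write_text("\n".join(map(str, ds.gene_names)) + "\n")
    meta = pd.DataFrame({
        "cell_id": ds.cell_ids, "barcode": ds.barcode, "day": ds.day,
        "cell_type": ds.cell_type if ds.cell_type is not None else "",
    })
    meta.to_csv(outdir / "metadata.csv", index=False)
    np.savez(
        outdir / "truth.npz",
        z0=truth.z0, progenitor_index=truth.progenitor_index,
        progenitor_means=truth.progenitor_means,
        fate=truth.fate.astype(str), attractors=truth.attractors,
        lineage_of_cell=truth.lineage_of_cell,
        rate_weights=truth.rate_weights, rate_bias=truth.rate_bias,
        beta=truth.beta, gamma=truth.gamma,
        monotone_gene=truth.monotone_gene,
        **{f"chain_{i}": c for i, c in enumerate(truth.chains)},
    )


def make_regulation_fixture(
    n_tfs: int = 2,
    n_targets_per_tf: int = 4,
    n_times: int = 8,
    n_samples: int = 60,
    noise: float = 0.05,
    seed: int = 0,
) -> tuple[list[np.ndarray], "RegulationMatrix", dict[str, tuple[int, int]]]:
    """Planted TF→target time series for the TF-activity regression.

    Each TF linearly drives its own disjoint target block with a gain that is
    nonzero only inside a TF-specific time window (TF ``k`` active in the
    ``k``-th of ``n_tfs`` equal slices of the series).  Returns the expression
    series (one samples × genes matrix per time point, TFs first), the binary
    regulation matrix, and the planted active window per TF.
    """
    from .downstream import RegulationMatrix

    rng = np.random.default_rng(seed)
    n_tg = n_tfs * n_targets_per_tf
    tf_names = [f"TF_{k}" for k in range(n_tfs)]
    tg_names = [f"TG_{j}" for j in range(n_tg)]
    R = np.zeros((n_tfs, n_tg), dtype=np.int64)
    for k in range(n_tfs):
        R[k, k * n_targets_per_tf:(k + 1) * n_targets_per_tf] = 1

    windows: dict[str, tuple[int, int]] = {}
    slice_len = (n_times - 1) // n_tfs
    for k in range(n_tfs):
        lo = k * slice_len
        hi = (k + 1) * slice_len if k < n_tfs - 1 else n_times - 1
        windows[tf_names[k]] = (lo, hi)

    series: list[np.ndarray] = []
    tf_expr = rng.lognormal(0.0, 0.5, size=(n_times, n_samples, n_tfs))
    for t in range(n_times):
        tg = rng.normal(0.0, noise, size=(n_samples, n_tg))
        if t > 0:
            for k in range(n_tfs):
                lo, hi = windows[tf_names[k]]
                gain = 2.0 if lo <= t - 1 < hi else 0.0
                block = slice(k * n_targets_per_tf, (k + 1) * n_targets_per_tf)
                tg[:, block] += gain * tf_expr[t - 1, :, k][:, None]
        series.append(np.concatenate([tf_expr[t], tg], axis=1))
    reg = RegulationMatrix(R=R, tf_names=tf_names, tg_names=tg_names)
    return series, reg, windows
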