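"""Post-training inference of backward trajectories and historical expression.

For every cell, sample the backward chain ``[z_{T0}, ..., z_1]`` from the
trained encoder and dynamics networks (one step per observed day), then for
every lineage draw progenitor states ``z_0`` from the mixture-of-experts
posterior over its cells' one-step-back components.  The decoder then turns
any latent state into expected expression ``chi * lambda_theta(z)`` or into
sampled Poisson counts, which is how historical transcriptomes at unobserved
time points are reconstructed.  The observed per-cell scale ``chi`` is reused
along the whole chain: it is a technical library-size factor, not part of the
biological state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import LineageVAE
from .io_preprocess import CellDataset

__all__ = ["TrajectorySet", "infer_trajectories", "reconstruct_expression"]


@dataclass
class CellTrajectory:
    """One sampled backward chain for one cell."""

    cell_id: str
    barcode: str
    day: int
    chain: np.ndarray        # (t0, m): z_{t0}, z_{t0-1}, ..., z_1
    drifts: np.ndarray       # (t0, m): rho * mu'(z_t) evaluated along the chain
    step_scales: np.ndarray  # (t0, m): rho * sigma'(z_t)

    @property
    def t0(self) -> int:
        return self.chain.shape[0]

    def state_at_step(self, step: int) -> np.ndarray:
        """Latent state at backward step ``step`` (step t0 = observed)."""
        if not 1 <= step <= self.t0:
            raise ValueError(f"step must be in [1, {self.t0}]")
        return self.chain[self.t0 - step]


@dataclass
class TrajectorySet:
    """Backward chains for all cells plus per-lineage progenitor draws."""

    cells: list[CellTrajectory]
    z0: dict[str, np.ndarray]            # barcode -> (n_samples, m)
    chi: np.ndarray                      # per cell, aligned with `cells`
    n_samples: int = 1
    steps_per_day: int = 1

    def __iter__(self):
        return iter(self.cells)

    @property
    def barcodes(self) -> list[str]:
        return sorted(self.z0)

    def states_at_step(self, step: int) -> tuple[np.ndarray, np.ndarray]:
        """All cells' latent states at backward step ``step``.

        Returns (states, cell_index); cells with shorter chains are skipped.
        """
        states, index = [], []
        for i, cell in enumerate(self.cells):
            if cell.t0 >= step:
                states.append(cell.state_at_step(step))
                index.append(i)
        if not states:
            raise ValueError(f"no cell has a chain reaching step {step}")
        return np.stack(states), np.array(index)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per cell per backward step."""
        rows = []
        for cell in self.cells:
            for k in range(cell.t0):
                step = cell.t0 - k
                rows.append({
                    "cell_id": cell.cell_id, "lineage": cell.barcode,
                    "step": step,
                    "day_equivalent": step / self.steps_per_day,
                    **{f"z_{d + 1}": cell.chain[k, d]
                       for d in range(cell.chain.shape[1])},
                })
        for bc, draws in self.z0.items():
            for s in range(draws.shape[0]):
                rows.append({
                    "cell_id": f"{bc}:z0:{s}", "lineage": bc, "step": 0,
                    "day_equivalent": 0.0,
                    **{f"z_{d + 1}": draws[s, d] for d in range(draws.shape[1])},
                })
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def infer_trajectories(model: LineageVAE, ds: CellDataset, n_samples: int = 1,
                       seed: int = 0, use_mean: bool = False) -> TrajectorySet:
    """Sample backward chains for every cell and z_0 draws for every lineage.

    With ``use_mean=True`` the chains are the posterior-mean trajectories:
    the encoder mean followed by noise-free advection steps
    ``z_{t-1} = z_t - rho * mu'(z_t)`` — the same posterior-mean convention
    used to represent latent states in downstream visualization and
    reconstruction analyses.  Progenitor draws still come from the mixture
    posterior (its component means when ``use_mean``).
    """
    if model.trained_phases < 2:
        raise ValueError("model must be trained (both phases) before inference")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    chi = ds.chi
    steps = model.config.steps_per_day
    mean, scale = model.encode(ds.spliced, chi)
    if use_mean:
        scale = np.zeros_like(scale)
    cells: list[CellTrajectory] = []
    # chains are sampled jointly per step count so one rng stream stays
    # deterministic regardless of cell order within a day cohort
    t0_all = ds.day * steps
    if np.any(t0_all < 1):
        raise ValueError("cells observed at day 0 have no backward step")
    chains: dict[int, np.ndarray] = {}
    for t0 in np.unique(t0_all):
        idx = np.where(t0_all == t0)[0]
        z = mean[idx] + scale[idx] * rng.standard_normal((len(idx), mean.shape[1]))
        states = [z]
        drifts, scales_ = [], []
        for _ in range(int(t0)):
            mu, sc = model.dynamics_posterior(states[-1])
            drifts.append(model.rho * mu)
            scales_.append(model.rho * sc)
            if len(states) < t0:
                eps = (np.zeros(z.shape) if use_mean
                       else rng.standard_normal(z.shape))
                states.append(states[-1] - (model.rho * mu
                                            + model.rho * sc * eps))
        chains[int(t0)] = (idx, np.stack(states, axis=1),
                           np.stack(drifts, axis=1), np.stack(scales_, axis=1))
    by_cell: dict[int, CellTrajectory] = {}
    for t0, (idx, states, drifts, scales_) in chains.items():
        for k, i in enumerate(idx):
            by_cell[i] = CellTrajectory(
                cell_id=str(ds.cell_ids[i]), barcode=str(ds.barcode[i]),
                day=int(ds.day[i]), chain=states[k], drifts=drifts[k],
                step_scales=scales_[k],
            )
    cells = [by_cell[i] for i in range(ds.n_cells)]

    z0: dict[str, np.ndarray] = {}
    for bc in sorted(set(map(str, ds.barcode))):
        z1 = np.stack([c.state_at_step(1) for c in cells if c.barcode == bc])
        moe = model.progenitor_posterior(z1)
        if use_mean:
            z0[bc] = np.repeat(moe.means.mean(axis=0, keepdims=True),
                               n_samples, axis=0)
        else:
            z0[bc] = np.stack([moe.sample(rng)[0] for _ in range(n_samples)])
    return TrajectorySet(cells=cells, z0=z0, chi=chi, n_samples=n_samples,
                         steps_per_day=steps)


def reconstruct_expression(traj: TrajectorySet, model: LineageVAE,
                           mode: str = "rate", seed: int = 0) -> pd.DataFrame:
    """Decode every trajectory state into expression.

    ``mode='rate'`` returns the expected expression ``chi * lambda_theta(z)``;
    ``mode='sample'`` draws Poisson counts from it.  The result is a long
    table with one row per cell per time point (including t=0 through the
    lineage progenitor draw), expression in columns ``g0..g{G-1}``.
    """
    if mode not in {"rate", "sample"}:
        raise ValueError("mode must be 'rate' or 'sample'")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows, meta = [], []
    for i, cell in enumerate(traj.cells):
        lam = model.decode_rate(cell.chain)          # (t0, g)
        xhat = traj.chi[i] * lam
        z0_mean = traj.z0[cell.barcode].mean(axis=0)
        xhat0 = traj.chi[i] * model.decode_rate(z0_mean)
        for k in range(cell.t0):
            step = cell.t0 - k
            meta.append((cell.cell_id, cell.barcode, step,
                         step / traj.steps_per_day))
            rows.append(xhat[k])
        meta.append((cell.cell_id, cell.barcode, 0, 0.0))
        rows.append(xhat0)
    X = np.stack(rows)
    if mode == "sample":
        X = rng.poisson(X).astype(np.float64)
    out = pd.DataFrame(X, columns=[f"g{j}" for j in range(X.shape[1])])
    out.insert(0, "day_equivalent", [m[3] for m in meta])
    out.insert(0, "step", [m[2] for m in meta])
    out.insert(0, "lineage", [m[1] for m in meta])
    out.insert(0, "cell_id", [m[0] for m in meta])
    return out
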