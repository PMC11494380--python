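"""The probabilistic model and its two-phase training procedure.

Generative model (one lineage, cells indexed by ``i``):

* a common progenitor state ``z_0 ~ N(0, sigma0^2 I)`` in an m-dimensional
  latent space (optionally anchored at the centroid of the earliest observed
  cells),
* a drift-free Wiener-process transition ``z_t | z_{t-1} ~ N(z_{t-1},
  sigma^2 I)`` — one step per observed day,
* Poisson emission ``x | z ~ Poisson(chi * lambda_theta(z))`` where ``chi``
  is the cell's mean count across genes and ``lambda_theta`` a decoder
  network with strictly positive output.

Inference runs backward in time.  An encoder network produces the posterior
of the observed-state latent ``q(z_T | x)``; a dynamics network produces the
advection–diffusion backward step

    z_{t-1} = z_t - (rho * mu'(z_t) + rho * sigma'(z_t) * eps),

and the progenitor posterior is an equal-weight mixture of experts over the
per-cell one-step-back posteriors ``q(z_0 | z_1^{(i)})``, from which a single
component is chosen.  The lineage ELBO combines transition and progenitor
log-priors, Poisson reconstruction at the observed states, and the entropy
terms of all variational factors; optionally a splicing-kinetics likelihood
of unspliced counts constrains the final backward step (see
:mod:`lineagevae.velocity`).

Training is two-phase: phase 1 fits encoder and decoder as a plain VAE on
all cells; phase 2 freezes the encoder and fits the dynamics network,
decoder and the scalar parameters on single-lineage minibatches with
Adam+AMSGrad.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp as np_logsumexp

from ._tensor import Tensor, concatenate, logsumexp
from .config import ModelConfig
from .io_preprocess import CellDataset
from .nn import MLP, Adam, gaussian_log_density, inverse_softplus

logger = logging.getLogger(__name__)

__all__ = [
    "LineageVAE",
    "LineageBatch",
    "MixtureOfExperts",
    "poisson_loglik",
    "train",
]

_RATE_FLOOR = 1e-6
_SCALE_FLOOR = 1e-4


def poisson_loglik(x: np.ndarray, rate: np.ndarray) -> np.ndarray | float:
    """Poisson log-likelihood ``sum_g [x log r - r - log(x!)]``.

    Summed over the last axis (genes); returns a float for 1-D inputs and a
    per-row array for 2-D inputs.
    """
    x = np.asarray(x, dtype=np.float64)
    rate = np.asarray(rate, dtype=np.float64)
    if np.any(x < 0) or not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError("x must contain non-negative integers")
    if np.any(rate <= 0):
        raise ValueError("Poisson rates must be strictly positive")
    terms = x * np.log(rate) - rate - gammaln(x + 1.0)
    out = terms.sum(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class MixtureOfExperts:
    """Equal-weight Gaussian mixture over per-cell progenitor posteriors."""

    means: np.ndarray   # (n_components, m)
    scales: np.ndarray  # (n_components, m), strictly positive

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.scales = np.atleast_2d(np.asarray(self.scales, dtype=np.float64))
        if self.means.shape != self.scales.shape:
            raise ValueError("means and scales must have identical shape")
        if self.means.shape[0] == 0:
            raise ValueError("mixture needs at least one component")
        if np.any(self.scales <= 0):
            raise ValueError("mixture scales must be strictly positive")

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    def log_density(self, z: np.ndarray) -> float:
        """Mixture log-density at a point (log-mean-exp of components)."""
        z = np.asarray(z, dtype=np.float64)
        comp = (
            -0.5 * np.log(2 * np.pi)
            - np.log(self.scales)
            - 0.5 * ((z[None, :] - self.means) / self.scales) ** 2
        ).sum(axis=1)
        return float(np_logsumexp(comp) - np.log(self.n_components))

    def sample(self, rng: np.random.Generator, strategy: str = "uniform",
               index: int | None = None) -> tuple[np.ndarray, int]:
        """Draw one progenitor sample from a single chosen component."""
        if index is not None:
            j = int(index) % self.n_components
        elif strategy == "uniform":
            j = int(rng.integers(self.n_components))
        elif strategy == "stratified":
            # deterministic cycling is handled via `index`; without one,
            # stratify by drawing a random starting offset
            j = int(rng.integers(self.n_components))
        else:
            raise ValueError(f"unknown sampling strategy: {strategy}")
        eps = rng.standard_normal(self.means.shape[1])
        return self.means[j] + self.scales[j] * eps, j


@dataclass
class LineageBatch:
    """The cells of one lineage presented to the lineage ELBO."""

    spliced: np.ndarray          # (n, g) raw counts
    chi: np.ndarray              # (n,) per-cell scale
    day: np.ndarray              # (n,) observed day
    t0: np.ndarray               # (n,) backward step counts (>= 1)
    barcode: str = ""
    unspliced: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spliced = np.asarray(self.spliced, dtype=np.float64)
        self.chi = np.asarray(self.chi, dtype=np.float64)
        self.day = np.asarray(self.day)
        self.t0 = np.asarray(self.t0, dtype=np.int64)
        if np.any(self.t0 < 1):
            raise ValueError("every cell needs at least one backward step (t0 >= 1)")
        if np.any(self.chi <= 0):
            raise ValueError("chi must be strictly positive")

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]


class LineageVAE:
    """Encoder / decoder / backward-dynamics model with learnable scalars."""

    def __init__(self, n_genes: int, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.n_genes = int(n_genes)
        m = self.config.latent_dim
        rng = np.random.default_rng(self.config.seed)
        ln = self.config.layer_norm
        self.encoder = MLP(self.n_genes, self.config.hidden, 2 * m, rng, layer_norm=ln)
        self.decoder = MLP(m, self.config.hidden, self.n_genes, rng, layer_norm=ln)
        self.dynamics = MLP(m, self.config.hidden, 2 * m, rng, layer_norm=ln)
        # positivity through softplus of raw parameters
        self._raw_rho = Tensor(inverse_softplus(0.1), requires_grad=True)
        self._raw_sigma0 = Tensor(inverse_softplus(1.0), requires_grad=True)
        self._raw_sigma = Tensor(inverse_softplus(0.5), requires_grad=True)
        self._raw_beta = Tensor(
            np.full(self.n_genes, inverse_softplus(1.0)), requires_grad=True)
        self._raw_gamma = Tensor(
            np.full(self.n_genes, inverse_softplus(1.0)), requires_grad=True)
        self.z_anchor: np.ndarray | None = None
        self.trained_phases = 0
        self.history: pd.DataFrame | None = None
        self._moe_counter = 0

    # -- learnable scalars -------------------------------------------------
    @property
    def rho(self) -> float:
        return float(self._raw_rho.softplus().data)

    @property
    def sigma0(self) -> float:
        return float(self._raw_sigma0.softplus().data)

    @property
    def sigma(self) -> float:
        return float(self._raw_sigma.softplus().data)

    @property
    def beta(self) -> np.ndarray:
        return np.asarray(self._raw_beta.softplus().data)

    @property
    def gamma(self) -> np.ndarray:
        return np.asarray(self._raw_gamma.softplus().data)

    # -- graph-building internals -------------------------------------------
    def _encoder_input(self, x: np.ndarray, chi: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        chi = np.atleast_1d(np.asarray(chi, dtype=np.float64))
        if self.config.encoder_input == "log1p":
            return np.log1p(x / chi[:, None])
        return x

    def _encode_t(self, x: np.ndarray, chi: np.ndarray) -> tuple[Tensor, Tensor]:
        m = self.config.latent_dim
        out = self.encoder(Tensor(self._encoder_input(x, chi)))
        mean = out[:, :m]
        scale = out[:, m:].softplus() + _SCALE_FLOOR
        return mean, scale

    def _decode_rate_t(self, z: Tensor) -> Tensor:
        return self.decoder(z).softplus() + _RATE_FLOOR

    def _dynamics_t(self, z: Tensor) -> tuple[Tensor, Tensor]:
        m = self.config.latent_dim
        out = self.dynamics(z)
        return out[:, :m], out[:, m:].softplus() + _SCALE_FLOOR

    # -- public (numpy) operations ------------------------------------------
    def encode(self, x: np.ndarray, chi: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """Variational posterior parameters q(z|x): (mean, scale)."""
        single = np.ndim(x) == 1
        mean, scale = self._encode_t(x, np.atleast_1d(chi))
        mean, scale = mean.data, scale.data
        if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(scale))):
            bad = np.where(~np.isfinite(mean).all(axis=1))[0]
            raise FloatingPointError(f"non-finite encoder output for rows {bad[:5]}")
        return (mean[0], scale[0]) if single else (mean, scale)

    def decode_mean(self, z: np.ndarray, chi: np.ndarray | float) -> np.ndarray:
        """Expected expression x_hat = chi * lambda_theta(z)."""
        chi = np.asarray(chi, dtype=np.float64)
        if np.any(chi <= 0):
            raise ValueError("chi must be strictly positive")
        single = np.ndim(z) == 1
        lam = self._decode_rate_t(Tensor(np.atleast_2d(z))).data
        out = np.atleast_1d(chi)[:, None] * lam if not single else float(chi) * lam[0]
        return out

    def decode_rate(self, z: np.ndarray) -> np.ndarray:
        """Per-gene decoder rate lambda_theta(z) (no cell scaling)."""
        single = np.ndim(z) == 1
        lam = self._decode_rate_t(Tensor(np.atleast_2d(z))).data
        return lam[0] if single else lam

    def dynamics_posterior(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backward-step drift mu'(z) and fluctuation sigma'(z)."""
        single = np.ndim(z) == 1
        mu, sc = self._dynamics_t(Tensor(np.atleast_2d(z)))
        mu, sc = mu.data, sc.data
        return (mu[0], sc[0]) if single else (mu, sc)

    def backward_step(self, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One sampled backward step z -> z_prev."""
        mu, sc = self.dynamics_posterior(z)
        eps = rng.standard_normal(np.shape(z))
        return z - (self.rho * mu + self.rho * sc * eps)

    def backward_chain(self, x: np.ndarray, chi: float, t0: int,
                       rng: np.random.Generator) -> np.ndarray:
        """Sample the chain [z_{t0}, z_{t0-1}, ..., z_1] for one cell."""
        if t0 < 1:
            raise ValueError("t0 must be >= 1")
        mean, scale = self.encode(x, chi)
        z = mean + scale * rng.standard_normal(mean.shape)
        chain = [z]
        for _ in range(t0 - 1):
            z = self.backward_step(z, rng)
            chain.append(z)
        return np.stack(chain)

    def progenitor_posterior(self, z1: np.ndarray) -> MixtureOfExperts:
        """Mixture-of-experts posterior of z_0 given the lineage's z_1 states."""
        z1 = np.atleast_2d(np.asarray(z1, dtype=np.float64))
        if z1.shape[0] == 0:
            raise ValueError("progenitor posterior needs at least one z_1 state")
        mu, sc = self.dynamics_posterior(z1)
        return MixtureOfExperts(means=z1 - self.rho * mu, scales=self.rho * sc)

    def sample_z0(self, z1: np.ndarray, rng: np.random.Generator,
                  strategy: str = "uniform") -> np.ndarray:
        z0, _ = self.progenitor_posterior(z1).sample(rng, strategy=strategy)
        return z0

    # -- objectives ----------------------------------------------------------
    def _phase1_loss_t(self, x: np.ndarray, chi: np.ndarray,
                       rng: np.random.Generator) -> tuple[Tensor, float]:
        """Negative standard VAE ELBO (per cell) on a plain minibatch."""
        mean, scale = self._encode_t(x, chi)
        eps = rng.standard_normal(mean.shape)
        z = mean + scale * eps
        lam = self._decode_rate_t(z)
        xhat = Tensor(chi[:, None]) * lam
        x_const = np.asarray(x, dtype=np.float64)
        recon = (Tensor(x_const) * xhat.log() - xhat).sum()
        recon_const = -float(gammaln(x_const + 1.0).sum())
        kl = 0.5 * (scale**2 + mean**2 - 1.0 - 2.0 * scale.log()).sum()
        n = x.shape[0]
        loss = (kl - recon) * (1.0 / n)
        elbo_value = (float(recon.data) + recon_const - float(kl.data)) / n
        return loss, elbo_value

    def _lineage_elbo_t(self, batch: LineageBatch, rng: np.random.Generator,
                        z0_strategy: str = "uniform") -> tuple[Tensor, dict[str, float]]:
        """Single-sample reparameterized lineage ELBO as a graph node."""
        cfg = self.config
        m = cfg.latent_dim
        rho = self._raw_rho.softplus()
        sigma = self._raw_sigma.softplus()
        sigma0 = self._raw_sigma0.softplus()

        enc_mean, enc_scale = self._encode_t(batch.spliced, batch.chi)
        eps = rng.standard_normal(enc_mean.shape)
        z_obs = enc_mean + enc_scale * eps
        log_q_enc = gaussian_log_density(z_obs, enc_mean, enc_scale).sum()

        # backward chains, vectorized per cohort of equal step count
        order: list[np.ndarray] = []
        z1_parts: list[Tensor] = []
        zprev_first: list[Tensor] = []   # z_{T0-1} per cohort (cells with t0>=2)
        zprev_idx: list[np.ndarray] = []
        log_q_steps = Tensor(0.0)
        log_p_trans = Tensor(0.0)
        for t0 in np.unique(batch.t0):
            idx = np.where(batch.t0 == t0)[0]
            order.append(idx)
            zt = z_obs[idx]
            for step, t in enumerate(range(int(t0), 1, -1)):
                mu, sc = self._dynamics_t(zt)
                step_scale = rho * sc
                step_mean = zt - rho * mu
                e = rng.standard_normal((len(idx), m))
                z_prev = step_mean + step_scale * e
                log_q_steps = log_q_steps + gaussian_log_density(
                    z_prev, step_mean, step_scale).sum()
                log_p_trans = log_p_trans + gaussian_log_density(
                    zt, z_prev, sigma).sum()
                if step == 0:
                    zprev_first.append(z_prev)
                    zprev_idx.append(idx)
                zt = z_prev
            z1_parts.append(zt)

        z1 = concatenate(z1_parts, axis=0)
        perm = np.concatenate(order)

        # progenitor mixture of experts over one-step-back posteriors
        mu1, sc1 = self._dynamics_t(z1)
        comp_mean = z1 - rho * mu1
        comp_scale = rho * sc1
        n = batch.n_cells
        if z0_strategy == "stratified":
            j = self._moe_counter % n
            self._moe_counter += 1
        else:
            j = int(rng.integers(n))
        eps0 = rng.standard_normal(m)
        z0 = comp_mean[j] + comp_scale[j] * eps0
        comp_ll = gaussian_log_density(z0.reshape(1, m), comp_mean, comp_scale)
        log_q_moe = logsumexp(comp_ll, axis=0) - float(np.log(n))

        if cfg.prior_mode == "anchored" and self.z_anchor is not None:
            log_p_z0 = gaussian_log_density(z0, Tensor(self.z_anchor), sigma0)
        else:
            log_p_z0 = gaussian_log_density(z0, Tensor(np.zeros(m)), sigma0)
        log_p_z1 = gaussian_log_density(z1, z0.reshape(1, m), sigma).sum()

        # Poisson reconstruction at the observed states
        lam_obs = self._decode_rate_t(z_obs)
        xhat = Tensor(batch.chi[:, None]) * lam_obs
        x_const = batch.spliced
        recon = (Tensor(x_const) * xhat.log() - xhat).sum()
        recon_const = -float(gammaln(x_const + 1.0).sum())

        terms: dict[str, float] = {}
        elbo = (log_p_z0 + log_p_z1 + log_p_trans + recon
                - log_q_moe - log_q_steps - log_q_enc)

        if cfg.velocity:
            if batch.unspliced is None:
                raise ValueError(
                    "velocity is enabled but the dataset has no unspliced "
                    "layer; set velocity=off or provide unspliced counts"
                )
            from .velocity import velocity_elbo_term_t
            velo = Tensor(0.0)
            for idx, z_prev in zip(zprev_idx, zprev_first):
                lam_t = lam_obs[idx]
                lam_prev = self._decode_rate_t(z_prev)
                velo = velo + velocity_elbo_term_t(
                    batch.unspliced[idx], lam_t, lam_prev,
                    batch.chi[idx],
                    self._raw_beta.softplus(), self._raw_gamma.softplus(),
                    cfg.delta_t,
                )
            elbo = elbo + velo
            terms["velocity"] = float(velo.data)

        elbo = elbo + recon_const
        terms.update(
            log_p_z0=float(log_p_z0.data),
            log_p_z1=float(log_p_z1.data),
            log_p_trans=float(log_p_trans.data),
            recon=float(recon.data) + recon_const,
            log_q_moe=float(log_q_moe.data),
            log_q_steps=float(log_q_steps.data),
            log_q_enc=float(log_q_enc.data),
        )
        if not np.isfinite(float(elbo.data)):
            raise FloatingPointError(
                f"non-finite lineage ELBO for barcode {batch.barcode!r}; "
                f"term breakdown: {terms}"
            )
        return elbo, terms

    def lineage_elbo(self, batch: LineageBatch,
                     rng: np.random.Generator | None = None,
                     return_terms: bool = False):
        """Single-sample Monte-Carlo estimate of the lineage ELBO."""
        rng = rng or np.random.default_rng(self.config.seed)
        elbo, terms = self._lineage_elbo_t(batch, rng)
        value = float(elbo.data)
        return (value, terms) if return_terms else value

    # -- parameter bookkeeping ------------------------------------------------
    def _scalar_params(self) -> dict[str, Tensor]:
        return {
            "raw_rho": self._raw_rho,
            "raw_sigma0": self._raw_sigma0,
            "raw_sigma": self._raw_sigma,
            "raw_beta": self._raw_beta,
            "raw_gamma": self._raw_gamma,
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        state.update(self.encoder.state_dict("encoder."))
        state.update(self.decoder.state_dict("decoder."))
        state.update(self.dynamics.state_dict("dynamics."))
        for name, t in self._scalar_params().items():
            state[name] = np.asarray(t.data).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.encoder.load_state_dict(state, "encoder.")
        self.decoder.load_state_dict(state, "decoder.")
        self.dynamics.load_state_dict(state, "dynamics.")
        for name, t in self._scalar_params().items():
            t.data = np.array(state[name], dtype=np.float64)

    def save(self, path) -> None:
        """Write a single-file checkpoint (parameters + config + seed)."""
        import json

        payload = dict(self.state_dict())
        payload["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        payload["__n_genes__"] = np.array(self.n_genes)
        payload["__trained_phases__"] = np.array(self.trained_phases)
        if self.z_anchor is not None:
            payload["__z_anchor__"] = self.z_anchor
        with open(path, "wb") as fh:  # exact filename (savez would add .npz)
            np.savez(fh, **payload)

    @classmethod
    def load(cls, path) -> "LineageVAE":
        import json

        with np.load(path) as archive:
            data = {k: archive[k] for k in archive.files}
        cfg = ModelConfig.from_mapping(
            json.loads(bytes(data.pop("__config__")).decode()))
        model = cls(int(data.pop("__n_genes__")), cfg)
        model.trained_phases = int(data.pop("__trained_phases__"))
        if "__z_anchor__" in data:
            model.z_anchor = data.pop("__z_anchor__")
        model.load_state_dict(data)
        return model


def make_lineage_batches(ds: CellDataset, config: ModelConfig,
                         rng: np.random.Generator) -> list[LineageBatch]:
    """Single-lineage minibatches; lineages above batch_size are subsampled."""
    batches = []
    chi = ds.chi
    for bc in pd.unique(pd.Series(ds.barcode)):
        idx = np.where(ds.barcode == bc)[0]
        if len(idx) > config.batch_size:
            idx = rng.choice(idx, size=config.batch_size, replace=False)
        t0 = ds.day[idx] * config.steps_per_day
        batches.append(LineageBatch(
            spliced=ds.spliced[idx],
            unspliced=None if ds.unspliced is None else ds.unspliced[idx],
            chi=chi[idx],
            day=ds.day[idx],
            t0=t0,
            barcode=str(bc),
        ))
    return batches


def train(ds: CellDataset, config: ModelConfig | None = None,
          model: LineageVAE | None = None) -> tuple[LineageVAE, pd.DataFrame]:
    """Two-phase training; returns the model and a per-epoch ELBO trace."""
    config = config or ModelConfig()
    if np.any(ds.day * config.steps_per_day < 1):
        raise ValueError(
            "every cell needs at least one backward step; cells observed at "
            "day 0 cannot be used for dynamics training"
        )
    model = model or LineageVAE(ds.n_genes, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chi = ds.chi
    records: list[dict] = []

    # ----- phase 1: plain VAE on all cells ---------------------------------
    opt1 = Adam(model.encoder.parameters() + model.decoder.parameters(),
                lr=config.lr)
    n = ds.n_cells
    for epoch in range(config.epochs_phase1):
        perm = rng.permutation(n)
        elbos = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            loss, elbo = model._phase1_loss_t(ds.spliced[idx], chi[idx], rng)
            opt1.zero_grad()
            loss.backward()
            opt1.step()
            elbos.append(elbo)
        records.append({"phase": 1, "epoch": epoch,
                        "elbo_per_cell": float(np.mean(elbos))})
        if epoch % 50 == 0:
            logger.info("phase 1 epoch %d: ELBO/cell %.3f", epoch, records[-1]["elbo_per_cell"])
    model.trained_phases = max(model.trained_phases, 1)

    if config.prior_mode == "anchored":
        first_day = ds.day.min()
        early = np.where(ds.day == first_day)[0]
        mean, _ = model.encode(ds.spliced[early], chi[early])
        model.z_anchor = mean.mean(axis=0)

    # ----- phase 2: lineage dynamics ---------------------------------------
    lineages = pd.unique(pd.Series(ds.barcode))
    if len(lineages) == 0:
        raise ValueError("no lineages available for dynamics training")
    phase2_params = (model.dynamics.parameters() + model.decoder.parameters()
                     + [model._raw_rho, model._raw_sigma0, model._raw_sigma])
    if config.velocity and config.learn_kinetics:
        phase2_params += [model._raw_beta, model._raw_gamma]
    opt2 = Adam(phase2_params, lr=config.lr)
    for epoch in range(config.epochs_phase2):
        batches = make_lineage_batches(ds, config, rng)
        rng.shuffle(batches)
        elbos, term_sums = [], {}
        for batch in batches:
            elbo_t, terms = model._lineage_elbo_t(batch, rng)
            loss = elbo_t * (-1.0 / batch.n_cells)
            opt2.zero_grad()
            loss.backward()
            opt2.step()
            elbos.append(float(elbo_t.data) / batch.n_cells)
            for k, v in terms.items():
                term_sums[k] = term_sums.get(k, 0.0) + v / batch.n_cells
        rec = {"phase": 2, "epoch": epoch,
               "elbo_per_cell": float(np.mean(elbos))}
        rec.update({k: v / len(batches) for k, v in term_sums.items()})
        records.append(rec)
        if epoch % 50 == 0:
            logger.info("phase 2 epoch %d: ELBO/cell %.3f", epoch, rec["elbo_per_cell"])
    model.trained_phases = 2
    model.history = pd.DataFrame(records)
    return model, model.history
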