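"""Splicing-kinetics constraint on the final backward step.

Mature (spliced) mRNA ``s`` obeys ``ds/dt = beta * u - gamma * s`` with
gene-specific splicing rates ``beta`` and degradation rates ``gamma``.
Approximating ``ds/dt`` by the finite difference of the decoder rate across
one backward step of duration ``delta_t`` yields the expected unspliced
count

    u_hat = [lambda(z_T) - lambda(z_{T-1}) + delta_t * gamma * lambda(z_T)]
            / (beta * delta_t)

scaled by the same per-cell factor ``chi`` as the spliced mean.  The raw
expression can be negative (the kinetics give no such guarantee), so it is
clamped below at 1e-6 to stay a valid Poisson mean; clamp events are counted
so heavy clamping is visible.  The resulting Poisson log-likelihood of the
observed unspliced counts is added to the lineage ELBO when velocity is
enabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor
from .core_model import poisson_loglik

logger = logging.getLogger(__name__)

__all__ = ["KineticParams", "unspliced_mean", "velocity_elbo_term"]

_U_FLOOR = 1e-6

#: running tally of clamped entries / total entries, for diagnostics
clamp_counter = {"clamped": 0, "total": 0}


@dataclass
class KineticParams:
    """Gene-wise splicing/degradation rates and the micro time interval."""

    beta: np.ndarray
    gamma: np.ndarray
    delta_t: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        if np.any(self.beta <= 0) or np.any(self.gamma <= 0) or self.delta_t <= 0:
            raise ValueError("kinetic parameters must be strictly positive")


def unspliced_mean(lam_t: np.ndarray, lam_prev: np.ndarray,
                   chi: np.ndarray | float, params: KineticParams) -> np.ndarray:
    """Expected unspliced counts from decoder rates across one backward step.

    ``lam_t`` and ``lam_prev`` are decoder rates at the observed state and one
    step earlier; ``chi`` scales gene rates to counts as for the spliced mean.
    """
    lam_t = np.asarray(lam_t, dtype=np.float64)
    lam_prev = np.asarray(lam_prev, dtype=np.float64)
    if not (np.all(np.isfinite(lam_t)) and np.all(np.isfinite(lam_prev))):
        raise ValueError("decoder rates must be finite")
    raw = (lam_t - lam_prev + params.delta_t * params.gamma * lam_t) / (
        params.beta * params.delta_t)
    clamped = raw < _U_FLOOR
    clamp_counter["clamped"] += int(clamped.sum())
    clamp_counter["total"] += int(raw.size)
    if clamped.any():
        logger.debug("unspliced mean clamped for %d/%d entries",
                     int(clamped.sum()), raw.size)
    u_rate = np.where(clamped, _U_FLOOR, raw)
    chi = np.asarray(chi, dtype=np.float64)
    return (chi[..., None] * u_rate) if chi.ndim else float(chi) * u_rate


def velocity_elbo_term(u: np.ndarray, lam_t: np.ndarray, lam_prev: np.ndarray,
                       chi: np.ndarray | float, params: KineticParams) -> float:
    """Poisson log-likelihood of unspliced counts under the kinetic mean."""
    if u is None:
        raise ValueError(
            "dataset has no unspliced counts; disable velocity (velocity=off)")
    u_hat = unspliced_mean(lam_t, lam_prev, chi, params)
    ll = poisson_loglik(u, u_hat)
    return float(np.sum(ll))


def velocity_elbo_term_t(u: np.ndarray, lam_t: Tensor, lam_prev: Tensor,
                         chi: np.ndarray, beta: Tensor, gamma: Tensor,
                         delta_t: float) -> Tensor:
    """Autodiff version of the kinetic likelihood used inside the ELBO.

    Mirrors :func:`unspliced_mean` / :func:`velocity_elbo_term` on graph
    tensors; the clamp passes no gradient where active.
    """
    raw = (lam_t - lam_prev + delta_t * gamma * lam_t) / (beta * delta_t)
    u_rate = raw.clip_min(_U_FLOOR)
    clamp_counter["clamped"] += int((raw.data < _U_FLOOR).sum())
    clamp_counter["total"] += int(raw.data.size)
    u_hat = Tensor(np.asarray(chi, dtype=np.float64)[:, None]) * u_rate
    u_const = np.asarray(u, dtype=np.float64)
    from scipy.special import gammaln

    ll = (Tensor(u_const) * u_hat.log() - u_hat).sum()
    return ll - float(gammaln(u_const + 1.0).sum())
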