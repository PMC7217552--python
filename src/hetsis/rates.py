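"""Per-node recovery-rate vectors and the spreading-rate schemes.

Recovery of node i is a Poisson process with rate ``delta_i``; transmission
along a directed edge i→j is a Poisson process with rate ``lambda_ij``.
Two spreading schemes are supported: *uniform* SIS (``lambda_ij = lambda``)
and the *contact process* (``lambda_ij = lambda / k_i``, with ``k_i`` the
degree of the transmitting node), whose mean-field threshold is 1 on any
connected structure.

Empirical infectious periods are well described by gamma distributions; the
corresponding recovery *rates* are then inverse-gamma distributed, which is
the heterogeneous scenario sampled here.  All samplers enforce a unit mean
analytically (scale ``beta = alpha - 1``) rather than by rescaling draws,
so the distribution shape is untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .netgen import Network, sample_discrete_powerlaw

logger = logging.getLogger(__name__)

__all__ = [
    "RecoveryRates",
    "SpreadingScheme",
    "inverse_gamma_rates",
    "degree_correlated_rates",
    "powerlaw_shuffled_rates",
    "homogeneous_rates",
]


@dataclass(frozen=True)
class RecoveryRates:
    """Positive per-node recovery rates with sampling provenance."""

    delta: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        delta = np.asarray(self.delta, dtype=np.float64)
        object.__setattr__(self, "delta", delta)
        if delta.ndim != 1:
            raise ValueError("delta must be a 1-d vector")
        if not np.all(np.isfinite(delta)) or np.any(delta <= 0):
            raise ValueError("recovery rates must be strictly positive and finite")

    @property
    def n_nodes(self) -> int:
        return len(self.delta)


@dataclass(frozen=True)
class SpreadingScheme:
    """Per-edge spreading rates: uniform lambda or contact-process lambda/k_i."""

    kind: str = "uniform"
    lam: float = 1.0

    def __post_init__(self):
        if self.kind not in ("uniform", "contact_process"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.lam <= 0:
            raise ValueError("lam must be positive")

    def edge_rates_out(self, degrees: np.ndarray) -> np.ndarray:
        """Rate on each edge leaving node i, as a per-source-node vector."""
        degrees = np.asarray(degrees, dtype=np.float64)
        if self.kind == "uniform":
            return np.full_like(degrees, self.lam)
        with np.errstate(divide="ignore"):
            out = self.lam / degrees
        out[degrees == 0] = 0.0
        return out


def inverse_gamma_rates(n_nodes: int, alpha: float, seed: int) -> RecoveryRates:
    """I.i.d. inverse-gamma recovery rates with unit mean.

    Shape ``alpha`` and scale ``beta = alpha - 1`` give mean
    ``beta/(alpha-1) = 1`` exactly.  The variance ``beta^2/((alpha-1)^2 (alpha-2))``
    exists only for ``alpha > 2``; smaller shapes are allowed (heavy-tail
    regime) but logged as infinite-variance.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1 for the mean to exist")
    if alpha <= 2:
        logger.warning("alpha=%g <= 2: recovery-rate variance is infinite", alpha)
    beta = alpha - 1.0
    rng = np.random.default_rng(seed)
    # X ~ Gamma(shape=alpha, scale=1/beta)  =>  1/X ~ InvGamma(alpha, beta)
    delta = 1.0 / rng.gamma(shape=alpha, scale=1.0 / beta, size=n_nodes)
    return RecoveryRates(
        delta,
        provenance={"scheme": "inverse_gamma", "alpha": alpha, "beta": beta, "seed": seed},
    )


def degree_correlated_rates(net: Network) -> RecoveryRates:
    """delta_i = k_i exactly: the structure-cancelling correlated assignment.

    With these rates the mean-field matrix Q equals the random-walk
    transition matrix P, so the predicted threshold is 1 regardless of the
    degree distribution.
    """
    k = net.degrees
    isolated = np.flatnonzero(k == 0)
    if len(isolated):
        raise ValueError(f"isolated node(s) {isolated[:5].tolist()} have zero degree")
    return RecoveryRates(k.astype(np.float64), provenance={"scheme": "degree"})


def powerlaw_shuffled_rates(
    n_nodes: int,
    gamma: float,
    k_min: int,
    k_max: int,
    seed: int,
    sequence: np.ndarray | None = None,
) -> RecoveryRates:
    """Heavy-tailed rates on a homogeneous substrate: delta = shuffled k^PL.

    Draws ``delta_i`` i.i.d. from the discrete power law P(k) ∝ k^(-gamma)
    on [k_min, k_max], or, when ``sequence`` is supplied (e.g. the degree
    sequence of a matching power-law network), assigns those values to the
    nodes by a seeded random permutation.  Either way the rates carry no
    correlation with the degrees of the network they are paired with.
    """
    rng = np.random.default_rng(seed)
    if sequence is not None:
        sequence = np.asarray(sequence)
        if len(sequence) != n_nodes:
            raise ValueError(
                f"supplied sequence has length {len(sequence)}, expected {n_nodes}"
            )
        delta = sequence[rng.permutation(n_nodes)].astype(np.float64)
        prov = {"scheme": "powerlaw_shuffled", "source": "sequence", "seed": seed}
    else:
        delta = sample_discrete_powerlaw(n_nodes, gamma, k_min, k_max, seed).astype(
            np.float64
        )
        prov = {
            "scheme": "powerlaw_shuffled",
            "gamma": gamma,
            "k_min": k_min,
            "k_max": k_max,
            "seed": seed,
        }
    return RecoveryRates(delta, provenance=prov)


def homogeneous_rates(n_nodes: int, delta: float = 1.0) -> RecoveryRates:
    """Constant recovery rate: the standard SIS baseline."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    return RecoveryRates(
        np.full(n_nodes, float(delta)), provenance={"scheme": "homogeneous", "delta": delta}
    )
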