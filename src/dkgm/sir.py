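"""Discrete-time SIR spreading simulator and the mean-field epidemic threshold.

The spreading influence of a node is estimated by seeding a
susceptible-infected-recovered epidemic at that node alone and measuring the
final outbreak size.  Dynamics are synchronous: in each step every infected
node independently infects each susceptible neighbor with probability
``beta``, then recovers with probability ``lam`` (default 1, i.e. exactly one
infectious step).  The process stops when no infected nodes remain, and the
influence is

    F(i) = N_r / N

averaged over many independent realizations, N_r being the recovered count.
The simulation is typically run near the heterogeneous mean-field epidemic
threshold beta_c = <k>/(<k^2> - <k>), below which outbreaks stay local and
far above which every seed saturates the network (both regimes wash out
rank differences between seeds).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network

__all__ = [
    "SIRConfig",
    "InfluenceVector",
    "simulate_outbreak",
    "influence",
    "epidemic_threshold",
]


@dataclass
class SIRConfig:
    """Parameters of the SIR influence estimate.

    Attributes
    ----------
    beta : float
        Infection probability per infected-susceptible contact per step,
        in [0, 1].
    lam : float
        Recovery probability per step; 1 (one infectious step) unless
        explicitly overridden.
    realizations : int
        Independent outbreaks per seed node (default 1000).
    rng_seed : int
        Master seed; per-outbreak substreams are derived from it
        deterministically, so results do not depend on iteration order.
    """

    beta: float
    lam: float = 1.0
    realizations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must be in (0, 1]")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")


@dataclass
class InfluenceVector:
    """Per-node mean outbreak fraction F(i) with simulation metadata."""

    influence: np.ndarray
    config: SIRConfig
    realizations_used: int = field(default=0)

    def __post_init__(self) -> None:
        if self.realizations_used == 0:
            self.realizations_used = self.config.realizations


def simulate_outbreak(
    net: Network,
    seed_node: int,
    cfg: SIRConfig,
    rng: np.random.Generator,
) -> int:
    """Run one outbreak seeded at ``seed_node``; return the recovered count N_r.

    Synchronous updating: all infection attempts of a step happen before
    that step's recoveries, so with ``lam=1`` the epidemic is a stochastic
    BFS wave in which each node is infectious for exactly one step.
    """
    if not 0 <= seed_node < net.N:
        raise IndexError(f"node index {seed_node} out of range for N={net.N}")
    indptr, indices = net.csr()
    susceptible = np.ones(net.N, dtype=bool)
    susceptible[seed_node] = False
    infected = np.array([seed_node], dtype=np.int64)
    beta, lam = cfg.beta, cfg.lam
    while infected.size:
        if beta > 0.0:
            parts = [indices[indptr[u] : indptr[u + 1]] for u in infected]
            contacts = np.concatenate(parts) if parts else indices[:0]
            if beta >= 1.0:
                hits = contacts[susceptible[contacts]]
            else:
                hits = contacts[
                    (rng.random(contacts.size) < beta) & susceptible[contacts]
                ]
            new = np.unique(hits)
        else:
            new = indices[:0]
        susceptible[new] = False
        if lam >= 1.0:
            infected = new
        else:
            stay = infected[rng.random(infected.size) >= lam]
            infected = np.concatenate([stay, new])
    return int(net.N - np.count_nonzero(susceptible))


def _outbreak_rng(master_seed: int, rep: int, node: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(rep, node))
    return np.random.default_rng(ss)


def influence(net: Network, cfg: SIRConfig) -> InfluenceVector:
    """Estimate F(i) for every node by repeated single-seed outbreaks.

    Each realization index runs one outbreak from every node; substream
    seeds depend only on ``(rng_seed, realization, node)``, so the result
    is bit-reproducible and independent of loop order.
    """
    totals = np.zeros(net.N)
    for rep in range(cfg.realizations):
        for node in range(net.N):
            rng = _outbreak_rng(cfg.rng_seed, rep, node)
            totals[node] += simulate_outbreak(net, node, cfg, rng)
    f = totals / (cfg.realizations * net.N)
    return InfluenceVector(influence=f, config=cfg)


def epidemic_threshold(net: Network) -> float:
    """Mean-field SIR threshold beta_c = <k>/(<k^2> - <k>) for lam = 1."""
    deg = net.degrees.astype(float)
    mean_k = deg.mean()
    second = float((deg**2).mean())
    if second <= mean_k:
        raise ValueError("epidemic threshold undefined: <k^2> <= <k>")
    return float(mean_k / (second - mean_k))
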