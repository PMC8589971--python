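"""Ranking evaluation: Kendall's tau accuracy and monotonicity resolution.

Kendall's tau here counts concordant (n+) and discordant (n-) unordered
pairs, ties counting as neither, and normalizes by the total pair count:

    tau = 2 (n+ - n-) / (N (N - 1))

(the tau-a-style denominator; a tau-b variant with the tie-corrected
denominator is available behind a flag for comparison).  Monotonicity
measures how well a score list resolves ranks: with tie classes of sizes
N_t,

    M_r = [1 - sum_t N_t (N_t - 1) / (N (N - 1))]^2

is 1 when all scores are distinct and 0 when all are equal.  Because both
metrics are tie-sensitive, floating scores are compared after rounding to
10 significant digits, keeping tie classes stable across summation orders.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .network import Network, ScoreVector
from .sir import InfluenceVector

__all__ = ["EvaluationReport", "kendall_tau", "monotonicity", "evaluate_method"]

_TIE_SIG_DIGITS = 10


def _round_sig(a: np.ndarray, sig: int = _TIE_SIG_DIGITS) -> np.ndarray:
    out = np.asarray(a, dtype=float).copy()
    nz = (out != 0) & np.isfinite(out)
    mag = np.floor(np.log10(np.abs(out[nz])))
    factor = 10.0 ** (sig - 1 - mag)
    out[nz] = np.round(out[nz] * factor) / factor
    return out


def kendall_tau(x, y, *, variant: str = "a") -> float:
    """Rank concordance of two equal-length score sequences.

    ``variant="a"`` (default) is 2(n+ - n-)/(N(N-1)) with tied pairs
    excluded from the numerator only; ``variant="b"`` delegates to the
    tie-corrected scipy estimator.
    """
    x = _round_sig(x)
    y = _round_sig(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if variant == "b":
        return float(scipy.stats.kendalltau(x, y).statistic)
    if variant != "a":
        raise ValueError(f"unknown variant {variant!r}")
    num = 0.0
    block = 256
    for start in range(0, n, block):  # ordered pairs double-count n+ - n-
        sx = np.sign(x[start : start + block, None] - x[None, :])
        sy = np.sign(y[start : start + block, None] - y[None, :])
        num += float(np.sum(sx * sy))
    return num / (n * (n - 1))


def monotonicity(scores) -> float:
    """Resolution of a score list: M_r = [1 - sum N_t(N_t-1)/(N(N-1))]^2."""
    s = _round_sig(scores)
    n = s.size
    if n < 2:
        raise ValueError("need at least 2 scores")
    _, counts = np.unique(s, return_counts=True)
    tied = float(np.sum(counts * (counts - 1)))
    return float((1.0 - tied / (n * (n - 1))) ** 2)


@dataclass
class EvaluationReport:
    """Tau and monotonicity of one method against the SIR standard ranking."""

    method_name: str
    tau: float
    monotonicity: float
    beta_used: float
    n_nodes: int


def evaluate_method(
    net: Network, scores: ScoreVector, standard: InfluenceVector
) -> EvaluationReport:
    """Score ``scores`` against the SIR influence vector ``standard``.

    Tau is computed between the two per-node sequences in internal index
    order (tau is order-invariant); monotonicity on the method's scores.
    """
    if len(scores) != net.N or standard.influence.size != net.N:
        raise ValueError("score vector and influence vector must cover all nodes")
    return EvaluationReport(
        method_name=scores.method,
        tau=kendall_tau(scores.values, standard.influence),
        monotonicity=monotonicity(scores.values),
        beta_used=standard.config.beta,
        n_nodes=net.N,
    )
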