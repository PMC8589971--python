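"""Benchmark centralities: degree, k-shell, H-index, betweenness, closeness."""
from __future__ import annotations

import networkx as nx
import numpy as np

from .kshell import decompose
from .network import Network, ScoreVector

__all__ = [
    "degree_centrality",
    "kshell_centrality",
    "h_index",
    "betweenness_centrality",
    "closeness_centrality",
]


def degree_centrality(net: Network) -> ScoreVector:
    """DC(i) = k(i)."""
    return ScoreVector(net.degrees.astype(float), method="dc")


def kshell_centrality(net: Network) -> ScoreVector:
    """Classic k-shell value k_s(i) as a score."""
    return ScoreVector(decompose(net).shell.astype(float), method="ks")


def h_index(net: Network) -> ScoreVector:
    """H(i): largest h such that i has >= h neighbors of degree >= h."""
    deg = net.degrees
    out = np.zeros(net.N)
    for i in range(net.N):
        nd = np.sort(deg[net.adjacency[i]])[::-1]
        h = 0
        for rank, d in enumerate(nd, start=1):
            if d >= rank:
                h = rank
            else:
                break
        out[i] = h
    return ScoreVector(out, method="hindex")


def betweenness_centrality(net: Network) -> ScoreVector:
    """Unnormalized shortest-path betweenness over unordered pairs {s,t}."""
    bc = nx.betweenness_centrality(net.to_networkx(), normalized=False)
    return ScoreVector([bc[i] for i in range(net.N)], method="bc")


def closeness_centrality(net: Network) -> ScoreVector:
    """CC(i) = (N-1)/sum_j d(i,j) on connected graphs.

    On disconnected graphs the sum runs over the n_i nodes i can reach and
    the value is scaled by n_i/(N-1), which penalizes small components;
    degree-0 nodes score 0.
    """
    if net.N < 2:
        raise ValueError("need at least 2 nodes")
    cc = nx.closeness_centrality(net.to_networkx())  # Wasserman-Faust scaling
    return ScoreVector([cc[i] for i in range(net.N)], method="cc")
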