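"""Deterministic fixtures and synthetic graph generators.

``toy_network`` is the 9-node worked example used throughout the package
documentation: three degree-1 leaves, a 2-shell pair that classic k-shell
decomposition cannot separate, and a 4-node 3-core.  The random generators
cover the regimes relevant for spreading experiments: Erdos-Renyi (er),
Barabasi-Albert (ba, heterogeneous), Watts-Strogatz (ws, small-world) and
uniform random labeled trees (tree, the sparse near-acyclic regime where
neighborhood- and path-based centralities struggle).
"""
from __future__ import annotations

from pathlib import Path

import networkx as nx

from .network import Network

__all__ = ["toy_network", "TOY_EDGES", "random_graph", "write_edge_list"]

#: Edge list of the 9-node toy network (labels "1".."9").
TOY_EDGES: tuple[tuple[str, str], ...] = (
    ("1", "2"),
    ("2", "3"),
    ("2", "7"),
    ("3", "4"),
    ("3", "7"),
    ("4", "5"),
    ("4", "6"),
    ("4", "7"),
    ("5", "6"),
    ("5", "7"),
    ("6", "7"),
    ("5", "8"),
    ("6", "9"),
)


def toy_network() -> Network:
    """The fixed 9-node toy network (N=9, M=13, degrees 1,3,3,4,4,4,5,1,1)."""
    return Network.from_edges(TOY_EDGES)


def random_graph(kind: str, n: int, rng_seed: int = 0, **params) -> Network:
    """Seed-deterministic synthetic graph of the given ``kind``.

    Parameters
    ----------
    kind : {"er", "ba", "ws", "tree"}
        er takes ``p`` (edge probability); ba takes ``m`` (edges per new
        node; the seed graph is the complete graph K_m); ws takes ``k``
        (even ring degree) and ``p`` (rewiring probability); tree takes no
        parameters and yields a uniform random labeled tree.
    n : int
        Node count, >= 2.
    rng_seed : int
        Generator seed; identical seeds give identical edge sets.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if kind == "er":
        g = nx.gnp_random_graph(n, float(params["p"]), seed=rng_seed)
    elif kind == "ba":
        m = int(params["m"])
        if not 1 <= m < n:
            raise ValueError("ba requires 1 <= m < n")
        g = nx.barabasi_albert_graph(
            n, m, seed=rng_seed, initial_graph=nx.complete_graph(m)
        )
    elif kind == "ws":
        g = nx.watts_strogatz_graph(
            n, int(params["k"]), float(params["p"]), seed=rng_seed
        )
    elif kind == "tree":
        g = nx.random_labeled_tree(n, seed=rng_seed)
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    return Network.from_networkx(g)


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write ``net`` as a plain-text edge list (labels, one pair per line).

    Round-trips through :func:`dkgm.network.load_edge_list` with identical
    labels; isolated nodes are recorded as ``# node <label>`` comments and
    are not restored by a plain edge-list read.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for i, j in net.edges():
            fh.write(f"{net.node_labels[i]} {net.node_labels[j]}\n")
        for i in range(net.N):
            if len(net.adjacency[i]) == 0:
                fh.write(f"# node {net.node_labels[i]}\n")
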