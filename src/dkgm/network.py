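"""Graph container, edge-list I/O, BFS machinery and descriptive statistics.

Networks are undirected, unweighted and simple: self-loops are dropped and
duplicate edges collapsed on construction.  Node labels are opaque strings
preserved in first-appearance order; internally every node is a contiguous
integer index ``0..N-1``.
"""
from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "NetworkStats",
    "ScoreVector",
    "load_edge_list",
    "bfs_distances",
    "network_stats",
]


@dataclass
class ScoreVector:
    """Per-node real-valued centrality scores, aligned to node indices.

    Attributes
    ----------
    values : numpy.ndarray
        ``values[i]`` is the score of node index ``i``.
    method : str
        Name of the producing method (``"dkgm"``, ``"dc"``, ...).
    """

    values: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, i: int) -> float:
        return float(self.values[i])

    def as_dict(self, net: "Network") -> dict[str, float]:
        """Map original node labels to scores."""
        return {lab: float(v) for lab, v in zip(net.node_labels, self.values)}


@dataclass
class Network:
    """Undirected simple graph with string labels and index adjacency.

    Attributes
    ----------
    node_labels : list of str
        Original labels; position is the internal node index.
    adjacency : list of numpy.ndarray
        ``adjacency[i]`` holds the sorted neighbor indices of node ``i``.
    """

    node_labels: list[str]
    adjacency: list[np.ndarray]
    _csr: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if len(self.node_labels) != len(self.adjacency):
            raise ValueError("labels and adjacency length mismatch")
        for i, nbrs in enumerate(self.adjacency):
            a = np.asarray(nbrs, dtype=np.int64)
            if a.size and (a.min() < 0 or a.max() >= len(self.adjacency)):
                raise ValueError("neighbor index out of range")
            if np.any(a == i):
                raise ValueError("self-loop in adjacency")
            self.adjacency[i] = np.sort(a)

    # -- basic quantities -------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.node_labels)

    @property
    def M(self) -> int:
        return sum(len(a) for a in self.adjacency) // 2

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency], dtype=np.int64)

    def index_of(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Compressed neighbor arrays ``(indptr, indices)`` for fast sweeps."""
        if self._csr is None:
            deg = self.degrees
            indptr = np.zeros(self.N + 1, dtype=np.int64)
            np.cumsum(deg, out=indptr[1:])
            indices = (
                np.concatenate(self.adjacency)
                if self.N and indptr[-1] > 0
                else np.empty(0, dtype=np.int64)
            )
            self._csr = (indptr, indices)
        return self._csr

    def edges(self) -> Iterable[tuple[int, int]]:
        """Unordered edges as index pairs with ``i < j``."""
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if i < j:
                    yield i, int(j)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "Network":
        """Build from labeled edges; self-loops dropped, duplicates collapsed."""
        labels: list[str] = []
        index: dict[str, int] = {}

        def idx(lab: str) -> int:
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
            return index[lab]

        pairs: set[tuple[int, int]] = set()
        for u, v in edges:
            iu, iv = idx(str(u)), idx(str(v))
            if iu == iv:
                continue
            pairs.add((min(iu, iv), max(iu, iv)))
        for lab in extra_nodes:
            idx(str(lab))
        adj: list[list[int]] = [[] for _ in labels]
        for i, j in pairs:
            adj[i].append(j)
            adj[j].append(i)
        return cls(labels, [np.array(a, dtype=np.int64) for a in adj])

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        nodes = list(g.nodes())
        return cls.from_edges(
            ((str(u), str(v)) for u, v in g.edges()),
            extra_nodes=(str(u) for u in nodes),
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(self.edges())
        return g


def load_edge_list(path: str | Path) -> Network:
    """Read a plain-text edge list into a :class:`Network`.

    One whitespace-separated node pair per line; extra tokens are ignored,
    blank lines and lines starting with ``#`` are skipped.  Labels are kept
    in first-appearance order; self-loops are dropped and duplicate edges
    collapsed.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If a non-comment line carries a single token (the message names the
        offending line number).
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two node labels, got {line!r}"
                )
            edges.append((tokens[0], tokens[1]))
    return Network.from_edges(edges)


def bfs_distances(
    net: Network, source: int, radius: int | None = None
) -> dict[int, int]:
    """Hop distances from ``source`` to every node within ``radius``.

    Parameters
    ----------
    net : Network
    source : int
        Node index of the BFS root.
    radius : int or None
        Maximum hop distance; ``None`` means unbounded.

    Returns
    -------
    dict
        ``{node index: distance}`` for every reachable node with
        ``d <= radius``; includes ``{source: 0}``.  Unreachable or
        beyond-radius nodes are absent.
    """
    if not 0 <= source < net.N:
        raise IndexError(f"node index {source} out of range for N={net.N}")
    dist = {source: 0}
    queue: deque[int] = deque([source])
    while queue:
        u = queue.popleft()
        du = dist[u]
        if radius is not None and du >= radius:
            continue
        for v in net.adjacency[u]:
            v = int(v)
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


@dataclass
class NetworkStats:
    """Descriptive topology summary of a network.

    ``mean_distance`` averages over unordered reachable pairs only, so it is
    finite on disconnected graphs.  ``heterogeneity`` is the degree
    heterogeneity index H = <k^2>/<k>^2 (1 for regular graphs).
    ``epidemic_threshold`` is the heterogeneous mean-field SIR threshold
    <k>/(<k^2> - <k>) for recovery probability 1.
    """

    N: int
    M: int
    mean_degree: float
    mean_distance: float
    clustering: float
    assortativity: float
    heterogeneity: float
    epidemic_threshold: float
    second_moment: float

    def row(self) -> tuple:
        """Values in conventional reporting order (N, M, <k>, <d>, C, r, H, beta_c)."""
        return (
            self.N,
            self.M,
            self.mean_degree,
            self.mean_distance,
            self.clustering,
            self.assortativity,
            self.heterogeneity,
            self.epidemic_threshold,
        )


def _mean_distance(net: Network) -> float:
    # Average hop distance over unordered reachable pairs (each pair seen
    # twice across the N BFS runs, so ordered totals give the same mean).
    total = 0
    count = 0
    for i in range(net.N):
        d = bfs_distances(net, i)
        total += sum(d.values())
        count += len(d) - 1
    if count == 0:
        return math.nan
    return total / count


def network_stats(net: Network) -> NetworkStats:
    """Compute the standard topology summary of ``net``.

    Local clustering of degree-0/1 nodes counts as 0 and is included in the
    average.  Assortativity is the Pearson correlation of degrees over edge
    endpoints (both orientations); on graphs where it is undefined (no edges,
    or zero degree variance over endpoints) it is NaN with a warning, as is
    the epidemic threshold when ``<k^2> <= <k>``.
    """
    if net.N < 2:
        raise ValueError("need at least 2 nodes")
    deg = net.degrees.astype(float)
    mean_k = deg.mean()
    second = float((deg**2).mean())
    g = net.to_networkx()
    clustering = float(nx.average_clustering(g)) if net.M else 0.0
    if net.M == 0:
        warnings.warn("graph has no edges: assortativity and beta_c undefined")
        assort = math.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # 0/0 on regular graphs
            assort = float(nx.degree_assortativity_coefficient(g))
    heterogeneity = second / mean_k**2 if mean_k > 0 else math.nan
    if second > mean_k:
        beta_c = mean_k / (second - mean_k)
    else:
        if net.M:
            warnings.warn("epidemic threshold undefined: <k^2> <= <k>")
        beta_c = math.nan
    return NetworkStats(
        N=net.N,
        M=net.M,
        mean_degree=float(mean_k),
        mean_distance=_mean_distance(net),
        clustering=clustering,
        assortativity=assort,
        heterogeneity=float(heterogeneity),
        epidemic_threshold=float(beta_c),
        second_moment=second,
    )
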