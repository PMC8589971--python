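"""Name-keyed registry of ranking methods used by the CLI and harness."""
from __future__ import annotations

from .centrality import (
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
    h_index,
    kshell_centrality,
)
from .gravity import dkgm, gravity_centrality, local_gravity_model, optimal_radius
from .kshell import decompose, dk_index, improved_kshell
from .network import Network, ScoreVector, network_stats

__all__ = ["METHOD_NAMES", "compute_scores", "resolve_radius"]

_RADIUS_METHODS = ("dkgm", "lgm")

METHOD_NAMES = (
    "dc",
    "ks",
    "ksstar",
    "dk",
    "hindex",
    "bc",
    "cc",
    "gc",
    "lgm",
    "dkgm",
)


def resolve_radius(net: Network, radius: int | str | None) -> int:
    """Turn ``"auto"``/None into the <d>/2 heuristic radius for this graph."""
    if radius is None or radius == "auto":
        return optimal_radius(network_stats(net).mean_distance)
    r = int(radius)
    if r < 1:
        raise ValueError("radius must be >= 1")
    return r


def compute_scores(
    net: Network, method: str, radius: int | str | None = None
) -> ScoreVector:
    """Score every node of ``net`` with the named method.

    ``radius`` applies to dkgm and lgm only (``"auto"``/None resolves via
    the <d>/2 heuristic); gc always uses radius 3.
    """
    if method == "dc":
        return degree_centrality(net)
    if method == "ks":
        return kshell_centrality(net)
    if method == "ksstar":
        return improved_kshell(decompose(net))
    if method == "dk":
        return dk_index(net, improved_kshell(decompose(net)))
    if method == "hindex":
        return h_index(net)
    if method == "bc":
        return betweenness_centrality(net)
    if method == "cc":
        return closeness_centrality(net)
    if method == "gc":
        return gravity_centrality(net, radius=3)
    if method in _RADIUS_METHODS:
        r = resolve_radius(net, radius)
        return dkgm(net, r) if method == "dkgm" else local_gravity_model(net, r)
    raise ValueError(f"unknown method {method!r} (choose from {METHOD_NAMES})")
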