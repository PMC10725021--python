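"""Centrality, bridge centrality and shortest-pathway analytics.

Given an estimated conditional-dependence network whose nodes are grouped
into communities (one questionnaire = one community):

- strength        s_i  = sum_j |w_ij|
- expected influence (1-step)  ei_i = sum_j w_ij
- bridge strength bs_i = sum over cross-community neighbors of |w_ij|
- bridge expected influence    bei_i = signed cross-community sum

Edges whose sign is undefined (an endpoint is categorical) contribute their
magnitude to the expected-influence sums, since no sign exists for them.

Shortest pathways use Dijkstra on the distance d_ij = 1/|w_ij| over nonzero
edges (stronger conditional association = shorter distance); a literal
hop-count mode is also available.  Ties are broken deterministically by the
lexicographically smallest node sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data import NetworkModel
from .exceptions import SpecError


def centrality(network: NetworkModel) -> pd.DataFrame:
    """Strength, expected influence and bridge variants for every node.

    Returns a DataFrame indexed by node (network order) with columns
    ``community, strength, expected_influence, bridge_strength, bridge_ei``.
    """
    w = network.weights
    signed = np.where(network.sign_defined, w, np.abs(w))
    comms = np.array([network.communities[v] for v in network.nodes])
    cross = comms[:, None] != comms[None, :]

    strength = np.abs(w).sum(axis=1)
    ei = signed.sum(axis=1)
    bridge_strength = (np.abs(w) * cross).sum(axis=1)
    bridge_ei = (signed * cross).sum(axis=1)

    return pd.DataFrame(
        {
            "community": comms,
            "strength": strength,
            "expected_influence": ei,
            "bridge_strength": bridge_strength,
            "bridge_ei": bridge_ei,
        },
        index=pd.Index(network.nodes, name="node"),
    )


@dataclass
class PathwayResult:
    """One shortest pathway between two nodes (or its absence)."""

    source: str
    target: str
    path: list[str] = field(default_factory=list)
    total_distance: float = np.inf
    exists: bool = False


def _graph(network: NetworkModel, metric: str) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for a, b, w, _ in network.edge_list():
        dist = 1.0 if metric == "hops" else 1.0 / abs(w)
        g.add_edge(a, b, distance=dist)
    return g


def shortest_path(
    network: NetworkModel, source: str, target: str, *, metric: str = "weighted"
) -> PathwayResult:
    """Minimal-distance pathway between two nodes.

    ``metric="weighted"`` (default) uses d = 1/|w|; ``metric="hops"`` counts
    edges.  Among equal-distance paths the lexicographically smallest node
    sequence is returned.
    """
    for v in (source, target):
        if v not in network.nodes:
            raise SpecError(f"unknown node {v!r}")
    if source == target:
        raise SpecError("source and target must differ")
    g = _graph(network, metric)
    try:
        paths = list(nx.all_shortest_paths(g, source, target, weight="distance"))
    except nx.NetworkXNoPath:
        return PathwayResult(source=source, target=target)
    best = min(paths)
    dist = sum(g[u][v]["distance"] for u, v in zip(best, best[1:]))
    return PathwayResult(source, target, best, float(dist), True)


@dataclass
class PathwaySubnetwork:
    """Union of pairwise shortest paths between two node sets."""

    pathways: list[PathwayResult]
    edges: set[tuple[str, str]]
    intermediaries: set[str]


def pathway_subnetwork(
    network: NetworkModel,
    sources: list[str],
    targets: list[str],
    *,
    metric: str = "weighted",
) -> PathwaySubnetwork:
    """All source x target shortest paths, their edge union, and the
    intermediary nodes (nodes interior to at least one path)."""
    if not sources or not targets:
        raise SpecError("source and target sets must be non-empty")
    if set(sources) & set(targets):
        raise SpecError("source and target sets must be disjoint")
    pathways = []
    edges: set[tuple[str, str]] = set()
    intermediaries: set[str] = set()
    for s, t in itertools.product(sources, targets):
        res = shortest_path(network, s, t, metric=metric)
        pathways.append(res)
        if res.exists:
            for u, v in zip(res.path, res.path[1:]):
                edges.add(tuple(sorted((u, v))))
            intermediaries.update(res.path[1:-1])
    return PathwaySubnetwork(pathways, edges, intermediaries)


def select_domains(
    domain_networks: dict[str, NetworkModel], symptom_community: str
) -> list[str]:
    """Screen factor domains for inclusion in the integrated network.

    Each input network contains the symptom community plus one factor
    domain; a domain is retained iff at least one nonzero edge connects any
    of its nodes to any symptom node.
    """
    retained = []
    for domain, net in domain_networks.items():
        comms = net.communities
        hit = any(
            (comms[a] == symptom_community) != (comms[b] == symptom_community)
            and domain in (comms[a], comms[b])
            for a, b, _, _ in net.edge_list()
        )
        if hit:
            retained.append(domain)
    return retained


__all__ = [
    "centrality",
    "shortest_path",
    "pathway_subnetwork",
    "select_domains",
    "PathwayResult",
    "PathwaySubnetwork",
]
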