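"""Topology statistics for layered networks."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .model import LayeredNetwork

__all__ = ["TopologyStats", "topology_stats"]


@dataclass(frozen=True)
class TopologyStats:
    n_components: int
    n_interactions: int
    mean_unique_neighbors: float
    mean_shortest_path: float


def topology_stats(net: LayeredNetwork, direction: str = "undirected") -> TopologyStats:
    """Compute node/edge counts, mean unique-neighbor degree and mean shortest path.

    Neighbor counting collapses reciprocal edges, multi-layer duplicates and
    direction to a single adjacency and ignores self-loops.  The mean
    shortest path averages hop counts over all ordered pairs of distinct
    nodes that are reachable under the chosen ``direction`` mode
    (``"undirected"`` or ``"directed"``).
    """
    if net.n_components == 0:
        raise ValueError("topology_stats requires a nonempty network")
    if direction not in ("undirected", "directed"):
        raise ValueError(f"unknown direction mode {direction!r}")

    digraph = nx.DiGraph()
    digraph.add_nodes_from(net.component_ids)
    for inter in net.interactions:
        if inter.source != inter.target:
            digraph.add_edge(inter.source, inter.target)
    undirected = digraph.to_undirected()

    degrees = [undirected.degree(n) for n in undirected.nodes]
    mean_neighbors = sum(degrees) / len(degrees)

    graph = digraph if direction == "directed" else undirected
    total = 0
    n_pairs = 0
    for source, dists in nx.all_pairs_shortest_path_length(graph):
        for target, dist in dists.items():
            if target == source:
                continue
            total += dist
            n_pairs += 1
    mean_path = total / n_pairs if n_pairs else float("nan")

    return TopologyStats(
        n_components=net.n_components,
        n_interactions=net.n_interactions,
        mean_unique_neighbors=mean_neighbors,
        mean_shortest_path=mean_path,
    )
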