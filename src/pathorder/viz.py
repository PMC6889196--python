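"""Partial-order plot construction: thresholded order graph, exact
correlation clustering, layered ranks, DOT export.

The summary graph draws an edge A -> B with weight P(A<B) (tail altered
first); edges below the pruning threshold (default 0.4) are removed.
Pathways whose mutual order is indeterminate — high P(A=B) — are grouped by
exact correlation clustering, and layers are assigned by longest-path rank on
the majority-direction tournament after deterministic cycle-breaking, so the
earliest-altered pathways sit at rank 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
from sympy.utilities.iterables import multiset_partitions

from .ordering import OrderProbabilities

__all__ = [
    "OrderGraph",
    "build_order_graph",
    "correlation_cluster",
    "assign_layers",
    "export_dot",
]

DEFAULT_EDGE_THRESHOLD = 0.4
MAX_EXACT_CLUSTER_NODES = 12

_CLUSTER_COLORS = [
    "black", "firebrick", "royalblue", "forestgreen", "darkorange",
    "purple", "teal", "saddlebrown", "deeppink", "gold", "slategray", "navy",
]


@dataclass
class OrderGraph:
    """Directed pathway graph; edge (tail, head) weight = P(tail altered
    before head)."""

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    layers: dict[str, int] = field(default_factory=dict)
    clusters: dict[str, int] = field(default_factory=dict)


def _edge_weights(
    order_probs: Mapping[frozenset, OrderProbabilities]
) -> tuple[tuple[str, ...], dict[tuple[str, str], float]]:
    nodes = sorted({name for pair in order_probs for name in pair})
    weights: dict[tuple[str, str], float] = {}
    for op in order_probs.values():
        a, b = op.pair
        weights[(a, b)] = op.p_before
        weights[(b, a)] = op.p_after
    return tuple(nodes), weights


def build_order_graph(
    order_probs: Mapping[frozenset, OrderProbabilities],
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> OrderGraph:
    """Build the summary graph, dropping edges with weight below the
    threshold (both directions of a near-tie may survive)."""
    nodes, weights = _edge_weights(order_probs)
    edges = {e: w for e, w in weights.items() if w >= threshold}
    graph = OrderGraph(nodes, edges)
    graph.clusters = correlation_cluster(order_probs)
    graph.layers = assign_layers(graph)
    return graph


def _partition_objective(
    partition: list[list[str]],
    s: Mapping[frozenset, float],
    d: Mapping[frozenset, float],
) -> float:
    member = {}
    for ci, cluster in enumerate(partition):
        for node in cluster:
            member[node] = ci
    nodes = sorted(member)
    total = 0.0
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            key = frozenset((nodes[i], nodes[j]))
            if key not in s:
                continue
            total += s[key] if member[nodes[i]] == member[nodes[j]] else d[key]
    return total


def correlation_cluster(
    order_probs: Mapping[frozenset, OrderProbabilities],
    greedy: bool = False,
) -> dict[str, int]:
    """Exact correlation clustering of pathways.

    Similarity s(A,B) = P(A=B) (the order cannot be determined); dissimilarity
    d(A,B) = P(A<B) + P(A>B).  Returns the partition maximising within-cluster
    similarity plus between-cluster dissimilarity over all set partitions;
    ties broken toward fewer clusters, then lexicographically.
    """
    nodes = sorted({name for pair in order_probs for name in pair})
    if not nodes:
        return {}
    s = {frozenset(op.pair): op.p_equal for op in order_probs.values()}
    d = {
        frozenset(op.pair): op.p_before + op.p_after
        for op in order_probs.values()
    }
    if len(nodes) > MAX_EXACT_CLUSTER_NODES and not greedy:
        raise ValueError(
            f"exact clustering limited to {MAX_EXACT_CLUSTER_NODES} pathways; "
            "pass greedy=True"
        )
    if greedy and len(nodes) > MAX_EXACT_CLUSTER_NODES:
        partition = [[n] for n in nodes]
        improved = True
        while improved and len(partition) > 1:
            improved = False
            base = _partition_objective(partition, s, d)
            best = None
            for i in range(len(partition)):
                for j in range(i + 1, len(partition)):
                    merged = [
                        c for k, c in enumerate(partition) if k not in (i, j)
                    ] + [sorted(partition[i] + partition[j])]
                    val = _partition_objective(merged, s, d)
                    if val > base and (best is None or val > best[0]):
                        best = (val, merged)
            if best is not None:
                partition = best[1]
                improved = True
        best_partition = partition
    else:
        best_partition = None
        best_key = None
        for raw in multiset_partitions(nodes):
            partition = sorted([sorted(c) for c in raw])
            val = _partition_objective(partition, s, d)
            key = (-val, len(partition), partition)
            if best_key is None or key < best_key:
                best_key = key
                best_partition = partition
    clusters = {}
    for ci, cluster in enumerate(sorted(best_partition)):
        for node in cluster:
            clusters[node] = ci
    return clusters


def assign_layers(graph: OrderGraph) -> dict[str, int]:
    """Longest-path layer ranks from the majority-direction tournament.

    Edges with weight > 0.5 define the tournament; any directed cycle is
    broken by removing its lowest-weight edge (deterministic); ranks then
    follow the longest path from the sources, earliest-altered at 0.
    """
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for (tail, head), w in sorted(graph.edges.items()):
        if w > 0.5:
            g.add_edge(tail, head, weight=w)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        drop = min(cycle, key=lambda e: (g.edges[e]["weight"], e))
        g.remove_edge(drop[0], drop[1])
    layers = {n: 0 for n in graph.nodes}
    for node in nx.topological_sort(g):
        for pred in g.predecessors(node):
            layers[node] = max(layers[node], layers[pred] + 1)
    return layers


def export_dot(graph: OrderGraph) -> str:
    """Serialise to DOT: same-rank groups from layers, node border colours
    from clusters, penwidth proportional to edge weight.  Deterministic."""
    lines = ["digraph pathway_order {", "  rankdir=TB;", '  node [shape=ellipse];']
    by_layer: dict[int, list[str]] = {}
    for node in sorted(graph.nodes):
        by_layer.setdefault(graph.layers.get(node, 0), []).append(node)
    for node in sorted(graph.nodes):
        color = _CLUSTER_COLORS[
            graph.clusters.get(node, 0) % len(_CLUSTER_COLORS)
        ]
        lines.append(f'  "{node}" [color={color}];')
    for layer in sorted(by_layer):
        members = " ".join(f'"{n}";' for n in by_layer[layer])
        lines.append(f"  {{ rank=same; {members} }}")
    for (tail, head), w in sorted(graph.edges.items()):
        lines.append(
            f'  "{tail}" -> "{head}" [penwidth={1 + 4 * w:.2f}, '
            f'label="{w:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
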