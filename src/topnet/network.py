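"""Condition-specific weighted networks and top-perturbed subnetwork mining.

Fold changes from a two-group contrast are mapped onto a directed gene
interaction network. Per node the perturbation weight is the fold change
itself (``active`` mode, test/reference) or its reciprocal (``repressed``
mode, reference/test); per edge the weight is the inverse square root of the
product of its endpoint node weights, so edges between strongly perturbed
genes are cheap. All-vs-all Dijkstra shortest paths are ranked by their cost
normalized over path length (cost / number of edges); the union of the
top-ranked paths in each mode is the TopNet.

Determinism contract: among equal-cost shortest paths the lexicographically
smallest node sequence wins, making outputs platform-independent.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

MODES = ("active", "repressed")


@dataclass
class InteractionNetwork:
    """A directed gene interaction network; self-loops are dropped on load."""

    graph: nx.DiGraph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        g = nx.DiGraph()
        dropped = 0
        for u, v in edges:
            if u == v:
                dropped += 1
                continue
            g.add_edge(u, v)
        if dropped:
            logger.info("dropped %d self-loop edges on load", dropped)
        return cls(g)

    @classmethod
    def from_sif(cls, path) -> "InteractionNetwork":
        from .io import read_sif

        return cls.from_edges(read_sif(path))

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def undirected(self) -> "InteractionNetwork":
        """Symmetrized copy (each edge present in both directions)."""
        g = nx.DiGraph()
        for u, v in self.graph.edges:
            g.add_edge(u, v)
            g.add_edge(v, u)
        return InteractionNetwork(g)


def compute_node_weights(fold_changes: Mapping[str, float], mode: str) -> dict[str, float]:
    """Perturbation node weights: FC in ``active`` mode, 1/FC in ``repressed``.

    Fold changes are on the ratio scale (test over reference) and must be
    strictly positive.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    weights = {}
    for gene, fc in fold_changes.items():
        if not (fc > 0) or not math.isfinite(fc):
            raise ValueError(f"non-positive or non-finite fold change for gene {gene!r}")
        weights[gene] = fc if mode == "active" else 1.0 / fc
    return weights


def compute_edge_weight(w_u: float, w_v: float) -> float:
    """Edge weight 1/sqrt(w_u * w_v); symmetric, monotone decreasing in both."""
    if not (w_u > 0 and w_v > 0):
        raise ValueError("node weights must be strictly positive")
    return 1.0 / math.sqrt(w_u * w_v)


@dataclass
class ConditionNetwork:
    """An interaction network weighted for one contrast in one mode."""

    graph: nx.DiGraph = field(repr=False)
    mode: str = "active"
    node_weight: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def edge_weight(self) -> dict[tuple[str, str], float]:
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}


def build_condition_network(
    network: InteractionNetwork,
    fold_changes: Mapping[str, float],
    mode: str,
) -> ConditionNetwork:
    """Weight a network for one contrast; nodes without a fold change are dropped."""
    node_weight = compute_node_weights(fold_changes, mode)
    keep = [n for n in network.graph.nodes if n in node_weight]
    missing = network.graph.number_of_nodes() - len(keep)
    if missing:
        logger.info("dropped %d network nodes without expression data", missing)
    g = nx.DiGraph()
    g.add_nodes_from(keep)
    for u, v in network.graph.edges:
        if u in node_weight and v in node_weight:
            g.add_edge(u, v, weight=compute_edge_weight(node_weight[u], node_weight[v]))
    return ConditionNetwork(graph=g, mode=mode,
                            node_weight={n: node_weight[n] for n in keep})


@dataclass(frozen=True, slots=True)
class PathRecord:
    """One minimum-cost path: node sequence, total cost, cost per edge."""

    nodes: tuple[str, ...]
    cost: float

    @property
    def normalized_cost(self) -> float:
        return self.cost / (len(self.nodes) - 1)


def _dijkstra_from(graph: nx.DiGraph, source: str) -> list[PathRecord]:
    """Single-source Dijkstra returning lexicographically-smallest min-cost paths.

    The heap is keyed on (cost, node sequence); tuple comparison breaks cost
    ties by the lexicographically smaller sequence, so the first settlement
    of a node carries the contract-required path.
    """
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    settled: set[str] = set()
    out: list[PathRecord] = []
    adj = graph.adj
    while heap:
        cost, path = heapq.heappop(heap)
        u = path[-1]
        if u in settled:
            continue
        settled.add(u)
        if u != source:
            out.append(PathRecord(nodes=path, cost=cost))
        for v, data in adj[u].items():
            if v not in settled:
                heapq.heappush(heap, (cost + data["weight"], path + (v,)))
    return out


def shortest_paths_all_pairs(net: ConditionNetwork) -> list[PathRecord]:
    """All-vs-all Dijkstra: one minimum-cost path per ordered reachable pair.

    Unreachable pairs are omitted; trivial source==target pairs are not paths.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty condition network")
    records: list[PathRecord] = []
    for source in sorted(net.graph.nodes):
        records.extend(_dijkstra_from(net.graph, source))
    return records


def rank_paths(paths: Iterable[PathRecord]) -> list[PathRecord]:
    """Ascending by normalized cost (most perturbed first); ties by (cost, nodes)."""
    return sorted(paths, key=lambda p: (p.normalized_cost, p.cost, p.nodes))


def select_top_paths(
    ranked_paths: Sequence[PathRecord],
    *,
    fraction: float | None = 0.005,
    threshold: float | None = None,
) -> list[PathRecord]:
    """Keep the ceil(fraction * n) lowest-normalized-cost paths, or all below a threshold."""
    if threshold is not None:
        kept = [p for p in ranked_paths if p.normalized_cost < threshold]
        if not kept:
            logger.warning("threshold %.4g below the minimum path cost; empty selection", threshold)
        return kept
    if fraction is None or not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    k = math.ceil(fraction * len(ranked_paths))
    return list(ranked_paths[:k])


def permutation_threshold(
    net: ConditionNetwork,
    k: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Null normalized-cost quantile from node-weight permutations.

    Node weights are shuffled over nodes ``k`` times; edge weights are
    recomputed and all-pairs normalized costs pooled; the ``alpha`` quantile
    of that pooled null is returned as a selection threshold.
    """
    if k < 10:
        raise ValueError("need at least 10 permutations")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.graph.nodes)
    weights = np.array([net.node_weight[n] for n in nodes])
    pooled: list[float] = []
    for _ in range(k):
        perm = dict(zip(nodes, rng.permutation(weights)))
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for u, v in net.graph.edges:
            g.add_edge(u, v, weight=compute_edge_weight(perm[u], perm[v]))
        null_net = ConditionNetwork(graph=g, mode=net.mode, node_weight=perm)
        pooled.extend(p.normalized_cost for p in shortest_paths_all_pairs(null_net))
    return float(np.quantile(pooled, alpha))


@dataclass
class TopNet:
    """Union of the top-ranked perturbation paths of both modes of one contrast."""

    comparison: str
    active_nodes: set[str]
    active_edges: set[tuple[str, str]]
    repressed_nodes: set[str]
    repressed_edges: set[tuple[str, str]]
    captured_degs: dict[str, str]  # gene -> direction
    selection: dict = field(default_factory=dict)

    @property
    def common_nodes(self) -> set[str]:
        return self.active_nodes & self.repressed_nodes

    @property
    def nodes(self) -> set[str]:
        return self.active_nodes | self.repressed_nodes

    @property
    def edges(self) -> set[tuple[str, str]]:
        return self.active_edges | self.repressed_edges


def _path_union(paths: Iterable[PathRecord]) -> tuple[set[str], set[tuple[str, str]]]:
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for p in paths:
        nodes.update(p.nodes)
        edges.update(zip(p.nodes[:-1], p.nodes[1:]))
    return nodes, edges


def build_topnet(
    active_paths: Sequence[PathRecord],
    repressed_paths: Sequence[PathRecord],
    degs: Mapping[str, str],
    *,
    comparison: str = "",
    selection: dict | None = None,
) -> TopNet:
    """Assemble a TopNet from selected paths and the contrast's DEG directions."""
    if not active_paths and not repressed_paths:
        logger.warning("both path sets empty; TopNet for %s is empty", comparison)
    a_nodes, a_edges = _path_union(active_paths)
    r_nodes, r_edges = _path_union(repressed_paths)
    all_nodes = a_nodes | r_nodes
    captured = {g: d for g, d in degs.items() if g in all_nodes}
    return TopNet(
        comparison=comparison,
        active_nodes=a_nodes,
        active_edges=a_edges,
        repressed_nodes=r_nodes,
        repressed_edges=r_edges,
        captured_degs=captured,
        selection=dict(selection or {}),
    )


def mine_topnet(
    network: InteractionNetwork,
    fold_changes: Mapping[str, float],
    degs: Mapping[str, str],
    *,
    comparison: str = "",
    fraction: float | None = 0.005,
    threshold: float | None = None,
) -> TopNet:
    """End-to-end TopNet for one contrast: weight, mine, rank, select, assemble."""
    selected = {}
    for mode in MODES:
        cnet = build_condition_network(network, fold_changes, mode)
        ranked = rank_paths(shortest_paths_all_pairs(cnet))
        selected[mode] = select_top_paths(ranked, fraction=fraction, threshold=threshold)
    return build_topnet(
        selected["active"], selected["repressed"], degs,
        comparison=comparison,
        selection={"fraction": fraction, "threshold": threshold},
    )
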