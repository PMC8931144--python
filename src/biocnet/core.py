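"""Core-network extraction and cascading-impact (ego network) analysis.

The *core network* keeps only the strongest fraction (default 5%) of
co-occurrence links and drops every node left without a retained link.
Vulnerability of values to the loss of a biophysical element is then read
off the core as k-step directed reachability out of that element: an edge
``element -> value`` means the value depends directly on the element
(k = 1), and paths of length two expose cascading, indirect dependence
(k = 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .corpus import BIOPHYSICAL, VALUE
from .errors import AnalysisError
from .network import BiculturalNetwork

STRONG_EDGE_CUTOFF = 0.5  # display convention: std_weight > 0.5 is "strong"


@dataclass
class CoreNetwork:
    """The thresholded subgraph of strongest links plus threshold metadata."""

    network: BiculturalNetwork
    fraction: float
    cutoff_weight: float
    n_edges_kept: int
    n_edges_total: int
    tie_policy: str

    @property
    def realized_fraction(self) -> float:
        return self.n_edges_kept / self.n_edges_total

    @property
    def graph(self) -> nx.DiGraph:
        return self.network.graph

    def summary(self) -> dict:
        return {
            "fraction": self.fraction,
            "cutoff_weight": self.cutoff_weight,
            "n_edges_kept": self.n_edges_kept,
            "n_edges_total": self.n_edges_total,
            "realized_fraction": self.realized_fraction,
            "tie_policy": self.tie_policy,
            "n_value_nodes": len(self.network.value_nodes),
            "n_biophysical_nodes": len(self.network.biophysical_nodes),
        }


@dataclass
class EgoNetwork:
    """Induced subgraph of everything within ``k`` directed steps of ``ego``."""

    ego: str
    k: int
    graph: nx.DiGraph = field(repr=False)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def value_nodes(self) -> set[str]:
        return {n for n, c in self.graph.nodes(data="cls") if c == VALUE}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class PathLengthSummary:
    """Mean unweighted shortest-path length over pairs with a finite path."""

    mean: float
    n_finite_pairs: int
    n_unreachable_pairs: int
    direction: str


def _as_graph(network: BiculturalNetwork | CoreNetwork) -> nx.DiGraph:
    if isinstance(network, CoreNetwork):
        return network.network.graph
    return network.graph


def _edge_weight_key(network: BiculturalNetwork) -> str:
    return "std_weight" if network.is_standardized else "raw_weight"


def extract_core(
    network: BiculturalNetwork,
    fraction: float = 0.05,
    tie_policy: str = "include_ties",
) -> CoreNetwork:
    """Keep the strongest ``fraction`` of links and their incident nodes.

    The target count is ``k = ceil(fraction * n_edges)``.  With
    ``include_ties`` (default) every edge whose weight equals the k-th
    largest is retained, so boundary ties never depend on edge order; with
    ``strict_count`` exactly k edges are kept, breaking ties by
    (source, target) lexicographic order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if tie_policy not in ("include_ties", "strict_count"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    if network.n_edges == 0:
        raise AnalysisError("cannot extract a core from an edgeless network")

    key = _edge_weight_key(network)
    edges = sorted(
        network.graph.edges(data=True),
        key=lambda e: (-e[2][key], e[0], e[1]),
    )
    # ceil(fraction * E), guarded against float noise on exact multiples
    n_target = math.ceil(fraction * len(edges) - 1e-9)
    n_target = int(min(max(n_target, 1), len(edges)))
    cutoff = edges[n_target - 1][2][key]
    if tie_policy == "include_ties":
        kept = [e for e in edges if e[2][key] >= cutoff]
    else:
        kept = edges[:n_target]

    sub = nx.DiGraph()
    for u, v, d in kept:
        for n in (u, v):
            if n not in sub:
                sub.add_node(n, **network.graph.nodes[n])
        sub.add_edge(u, v, **d)
    prov = dict(network.provenance)
    prov["core_fraction"] = fraction
    prov["core_tie_policy"] = tie_policy
    core_net = BiculturalNetwork(sub, provenance=prov)
    return CoreNetwork(
        network=core_net,
        fraction=fraction,
        cutoff_weight=cutoff,
        n_edges_kept=len(kept),
        n_edges_total=len(edges),
        tie_policy=tie_policy,
    )


def _reachable(g: nx.DiGraph, ego: str, k: int) -> set[str]:
    lengths = nx.single_source_shortest_path_length(g, ego, cutoff=k)
    return set(lengths)


def ego_network(
    network: BiculturalNetwork | CoreNetwork, ego: str, k: int = 1
) -> EgoNetwork:
    """The induced subgraph of all nodes within ``k`` directed steps of a
    biophysical ego node, flagged with ``strong`` edge markers
    (std_weight > 0.5) where standardized weights are present."""
    if k not in (1, 2):
        raise ValueError(f"ego path length k must be 1 or 2, got {k}")
    g = _as_graph(network)
    if ego not in g:
        raise AnalysisError(f"ego {ego!r} not present in the network")
    if g.nodes[ego]["cls"] != BIOPHYSICAL:
        raise AnalysisError(f"ego must be biophysical, {ego!r} is a value code")
    nodes = _reachable(g, ego, k)
    sub = g.subgraph(nodes).copy()
    for _, _, d in sub.edges(data=True):
        if "std_weight" in d:
            d["strong"] = bool(d["std_weight"] > STRONG_EDGE_CUTOFF)
    return EgoNetwork(ego=ego, k=k, graph=sub)


def reachable_values(
    network: BiculturalNetwork | CoreNetwork, ego: str, k: int
) -> set[str]:
    """Value codes reachable from a biophysical ego within ``k`` directed
    steps (the values at risk if the element is lost); ``k=0`` is empty."""
    if k < 0:
        raise ValueError("k must be non-negative")
    g = _as_graph(network)
    if ego not in g:
        raise AnalysisError(f"ego {ego!r} not present in the network")
    if g.nodes[ego]["cls"] != BIOPHYSICAL:
        raise AnalysisError(f"ego must be biophysical, {ego!r} is a value code")
    if k == 0:
        return set()
    nodes = _reachable(g, ego, k)
    return {n for n in nodes if n != ego and g.nodes[n]["cls"] == VALUE}


def direct_biophysical_support(core: CoreNetwork) -> pd.DataFrame:
    """Per core value, the number of distinct biophysical elements with a
    direct supporting edge element -> value.  Values with zero incoming
    biophysical links are listed too.  Columns: value, n_biophysical."""
    g = core.graph
    rows = []
    for v in core.network.value_nodes:
        n = sum(1 for u in g.predecessors(v) if g.nodes[u]["cls"] == BIOPHYSICAL)
        rows.append({"value": v, "n_biophysical": n})
    frame = pd.DataFrame(rows, columns=["value", "n_biophysical"])
    return frame.sort_values(
        ["n_biophysical", "value"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def average_path_length(
    network: BiculturalNetwork | CoreNetwork, direction: str = "directed"
) -> PathLengthSummary:
    """Mean unweighted shortest-path length over all node pairs with a
    finite path; unreachable pairs are counted, not imputed.

    ``directed``: ordered pairs following edge direction.  ``undirected``:
    unordered pairs on the underlying undirected graph.
    """
    if direction not in ("directed", "undirected"):
        raise ValueError(f"unknown direction mode {direction!r}")
    g = _as_graph(network)
    n = g.number_of_nodes()
    if n < 2:
        raise AnalysisError("average path length needs at least 2 nodes")
    if direction == "undirected":
        g = g.to_undirected(as_view=True)
        n_pairs = n * (n - 1) // 2
    else:
        n_pairs = n * (n - 1)
    total = 0
    finite = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if target == source:
                continue
            total += dist
            finite += 1
    if direction == "undirected":
        total //= 2
        finite //= 2
    if finite == 0:
        raise AnalysisError("no finite paths between distinct nodes")
    return PathLengthSummary(
        mean=total / finite,
        n_finite_pairs=finite,
        n_unreachable_pairs=n_pairs - finite,
        direction=direction,
    )


def ego_table(core: CoreNetwork, include_ego: bool = True) -> pd.DataFrame:
    """One row per biophysical core node: ego-network node counts at path
    lengths 1 and 2 (ego itself included iff ``include_ego``) and the
    values-reached counts at each length.  Sorted by the k=1 node count
    descending, then element code."""
    elements = core.network.biophysical_nodes
    if not elements:
        raise AnalysisError("core network has no biophysical nodes")
    offset = 1 if include_ego else 0
    rows = []
    for b in elements:
        g = core.graph
        n1 = len(_reachable(g, b, 1)) - 1 + offset
        n2 = len(_reachable(g, b, 2)) - 1 + offset
        rows.append(
            {
                "element": b,
                "k1_nodes": n1,
                "k2_nodes": n2,
                "k1_values": len(reachable_values(core, b, 1)),
                "k2_values": len(reachable_values(core, b, 2)),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["element", "k1_nodes", "k2_nodes", "k1_values", "k2_values"]
    )
    return frame.sort_values(
        ["k1_nodes", "element"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
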