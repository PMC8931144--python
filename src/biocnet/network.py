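"""Directed weighted biocultural values networks.

An edge ``a -> b`` means "b depends on a", weighted by the number of coded
segments in which the dependency was mentioned (co-occurrence frequency).
Raw integer weights are kept alongside standardized [0, 1] weights so the
original counts are never lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .corpus import BIOPHYSICAL, VALUE, Corpus, NodeClass, Vocabulary
from .errors import AnalysisError, ValidationError


@dataclass
class BiculturalNetwork:
    """A directed two-node-class co-occurrence network.

    Thin wrapper around a :class:`networkx.DiGraph` whose nodes carry a
    ``cls`` attribute (``value`` | ``biophysical``) and whose edges carry
    ``raw_weight`` (positive int) and, after standardization, ``std_weight``
    in [0, 1].  ``provenance`` records how the network was produced.
    """

    graph: nx.DiGraph
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assert_valid()

    # -- views --------------------------------------------------------------
    @property
    def value_nodes(self) -> list[str]:
        return sorted(n for n, c in self.graph.nodes(data="cls") if c == VALUE)

    @property
    def biophysical_nodes(self) -> list[str]:
        return sorted(n for n, c in self.graph.nodes(data="cls") if c == BIOPHYSICAL)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def is_standardized(self) -> bool:
        return all("std_weight" in d for _, _, d in self.graph.edges(data=True))

    def class_of(self, code: str) -> NodeClass:
        return self.graph.nodes[code]["cls"]

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "raw_weight": d["raw_weight"],
                "std_weight": d.get("std_weight", float("nan")),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        frame = pd.DataFrame(
            rows, columns=["source", "target", "raw_weight", "std_weight"]
        )
        return frame.sort_values(["source", "target"], kind="mergesort").reset_index(
            drop=True
        )

    # -- invariants ----------------------------------------------------------
    def assert_valid(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if (
                self.graph.nodes[u]["cls"] == BIOPHYSICAL
                and self.graph.nodes[v]["cls"] == BIOPHYSICAL
            ):
                raise ValidationError(f"biophysical->biophysical edge {u} -> {v}")
            if d.get("raw_weight", 1) < 1:
                raise ValidationError(f"edge {u} -> {v}: raw_weight < 1")
            std = d.get("std_weight")
            if std is not None and not 0.0 <= std <= 1.0:
                raise ValidationError(f"edge {u} -> {v}: std_weight {std} not in [0,1]")

    # -- construction helpers -----------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        classes: Mapping[str, NodeClass],
        provenance: dict | None = None,
    ) -> "BiculturalNetwork":
        """Build from (source, target, raw_weight) triples and a code->class map."""
        g = nx.DiGraph()
        edges = list(edges)
        nodes = sorted({n for u, v, _ in edges for n in (u, v)})
        for n in nodes:
            g.add_node(n, cls=classes[n])
        for u, v, w in sorted(edges):
            g.add_edge(u, v, raw_weight=int(w))
        return cls(g, provenance=dict(provenance or {}))

    @classmethod
    def from_adjacency_frame(
        cls, frame: pd.DataFrame, classes: Mapping[str, NodeClass]
    ) -> "BiculturalNetwork":
        """Build from a square adjacency matrix (rows = sources, columns =
        targets, entries = raw co-occurrence counts; zero means no edge)."""
        edges = [
            (str(u), str(v), int(frame.loc[u, v]))
            for u in frame.index
            for v in frame.columns
            if int(frame.loc[u, v]) > 0
        ]
        return cls.from_edges(edges, classes, provenance={"source": "adjacency"})

    # -- export ---------------------------------------------------------------
    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def write_edge_list(self, path: str | Path) -> None:
        self.edges_frame().to_csv(path, index=False)


def build_network(corpus: Corpus, keep_isolated: bool = False) -> BiculturalNetwork:
    """Count per-segment co-occurrence into a directed weighted network.

    ``raw_weight(a, b)`` = number of segments whose mention set contains the
    directed dependency ``a -> b``.  Within a segment a mention counts once
    (set semantics upstream).  With ``keep_isolated`` every vocabulary code
    appears as a node even if never mentioned.
    """
    counts: dict[tuple[str, str], int] = {}
    for seg in corpus.segments:
        for m in seg.mentions:
            counts[(m.source, m.target)] = counts.get((m.source, m.target), 0) + 1
    if not counts:
        raise AnalysisError("no co-occurrence data: corpus contains no mentions")

    vocab = corpus.vocabulary
    classes = {c: VALUE for c in vocab.value_codes}
    classes.update({c: BIOPHYSICAL for c in vocab.biophysical_codes})
    net = BiculturalNetwork.from_edges(
        [(u, v, w) for (u, v), w in counts.items()],
        classes,
        provenance={
            "counting": "per-segment co-occurrence",
            "n_segments": len(corpus),
            "n_mentions": corpus.n_mentions,
            "keep_isolated": keep_isolated,
        },
    )
    if keep_isolated:
        for code in sorted(vocab.value_codes | vocab.biophysical_codes):
            if code not in net.graph:
                net.graph.add_node(code, cls=classes[code])
    return net


def standardize_weights(
    network: BiculturalNetwork, mode: str = "divide_by_max"
) -> BiculturalNetwork:
    """Map raw weights onto [0, 1], preserving their rank order.

    ``divide_by_max`` (default): ``std = raw / max(raw)``, so every observed
    link keeps positive weight.  ``min_max``: ``std = (raw - min) / (max - min)``,
    mapping the weakest observed link(s) to exactly 0; when all weights are
    equal every edge maps to 1.
    """
    if network.n_edges == 0:
        raise AnalysisError("cannot standardize a network with no edges")
    if mode not in ("divide_by_max", "min_max"):
        raise ValueError(f"unknown standardization mode {mode!r}")
    g = network.graph.copy()
    raws = [d["raw_weight"] for _, _, d in g.edges(data=True)]
    hi, lo = max(raws), min(raws)
    for _, _, d in g.edges(data=True):
        if mode == "divide_by_max":
            d["std_weight"] = d["raw_weight"] / hi
        elif hi == lo:
            d["std_weight"] = 1.0
        else:
            d["std_weight"] = (d["raw_weight"] - lo) / (hi - lo)
    prov = dict(network.provenance)
    prov["standardization"] = mode
    prov["max_raw_weight"] = hi
    prov["min_raw_weight"] = lo
    return BiculturalNetwork(g, provenance=prov)


def value_frequencies(corpus: Corpus, unit: str = "segment") -> pd.DataFrame:
    """How often each value code occurs in the corpus.

    ``unit="segment"`` (default): a value counts once per segment in which
    it appears in any mention, matching the co-occurrence unit.
    ``unit="mention"``: every value endpoint of every mention counts.
    Relative frequencies are fractions of all value occurrences and sum
    to 1.  Sorted by count descending, then code.
    """
    if unit not in ("segment", "mention"):
        raise ValueError(f"unknown frequency unit {unit!r}")
    value_codes = corpus.vocabulary.value_codes
    counts: dict[str, int] = {}
    for seg in corpus.segments:
        if unit == "segment":
            for code in seg.codes() & value_codes:
                counts[code] = counts.get(code, 0) + 1
        else:
            for m in seg.mentions:
                for code in (m.source, m.target):
                    if code in value_codes:
                        counts[code] = counts.get(code, 0) + 1
    total = sum(counts.values())
    rows = [
        {"value": code, "count": n, "rel_freq": n / total if total else 0.0}
        for code, n in counts.items()
    ]
    frame = pd.DataFrame(rows, columns=["value", "count", "rel_freq"])
    return frame.sort_values(
        ["count", "value"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def connectivity_summary(network: BiculturalNetwork) -> dict:
    """Cross-class connectivity: how many biophysical elements each value is
    associated with, and vice versa.

    "Connected" ignores direction: a value and an element are connected if
    an edge exists between them in either direction.  Returns a per-node
    table and the aggregate statistics used to summarize the full network.
    """
    und = network.graph.to_undirected(as_view=True)
    values = network.value_nodes
    elements = network.biophysical_nodes
    per_value = {
        v: sum(1 for n in und.neighbors(v) if network.class_of(n) == BIOPHYSICAL)
        for v in values
    }
    per_element = {
        b: sum(1 for n in und.neighbors(b) if network.class_of(n) == VALUE)
        for b in elements
    }
    rows = [{"node": v, "class": VALUE, "n_connected": per_value[v]} for v in values]
    rows += [
        {"node": b, "class": BIOPHYSICAL, "n_connected": per_element[b]}
        for b in elements
    ]
    table = pd.DataFrame(rows, columns=["node", "class", "n_connected"])
    table = table.sort_values(
        ["class", "n_connected", "node"], ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    n_values = len(values)
    aggregates = {
        "mean_elements_per_value": (
            sum(per_value.values()) / len(values) if values else 0.0
        ),
        "mean_values_per_element": (
            sum(per_element.values()) / len(elements) if elements else 0.0
        ),
        "n_elements_with_10_or_more_values": sum(
            1 for n in per_element.values() if n >= 10
        ),
        "n_elements_connected_to_all_values": sum(
            1 for n in per_element.values() if n_values and n == n_values
        ),
        "n_values_with_10_or_more_elements": sum(
            1 for n in per_value.values() if n >= 10
        ),
    }
    return {"per_node": table, "aggregates": aggregates}
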