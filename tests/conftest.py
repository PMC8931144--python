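"""Shared fixtures: a small hand-checkable vocabulary/corpus and random
generators for oracle-based tests."""

from __future__ import annotations

import numpy as np
import pytest

from biocnet.corpus import (
    BIOPHYSICAL,
    VALUE,
    BiophysicalCode,
    CodedSegment,
    Corpus,
    DependencyMention,
    ValueCode,
    Vocabulary,
)
from biocnet.network import BiculturalNetwork


@pytest.fixture
def toy_vocab() -> Vocabulary:
    return Vocabulary(
        values=(
            ValueCode("PTP", "people to people"),
            ValueCode("STE", "stewardship"),
            ValueCode("PTL", "people to location"),
        ),
        biophysical=(
            BiophysicalCode("SEA", "sea"),
            BiophysicalCode("ROCKS", "rocks"),
        ),
    )


@pytest.fixture
def toy_corpus(toy_vocab) -> Corpus:
    """Three segments: SEA->PTP appears in all three, PTP->STE and SEA->PTL
    once each."""

    def seg(iv, sg, pairs):
        return CodedSegment(iv, sg, frozenset(DependencyMention(s, t) for s, t in pairs))

    return Corpus(
        toy_vocab,
        [
            seg("I1", "S1", [("SEA", "PTP"), ("PTP", "STE")]),
            seg("I1", "S2", [("SEA", "PTP"), ("SEA", "PTL")]),
            seg("I2", "S3", [("SEA", "PTP")]),
        ],
    )


def random_corpus(rng: np.random.Generator, max_segments: int = 20) -> Corpus:
    """A random valid corpus over <= 8 codes (5 values, 3 elements)."""
    values = ["A", "B", "C", "D", "E"]
    elements = ["X", "Y", "Z"]
    vocab = Vocabulary(
        values=tuple(ValueCode(v, v.lower()) for v in values),
        biophysical=tuple(BiophysicalCode(b, b.lower()) for b in elements),
    )
    pairs = [(a, b) for a in values for b in values if a != b]
    pairs += [(b, v) for b in elements for v in values]
    pairs += [(v, b) for v in values for b in elements]  # value->bio is legal input
    n_segments = int(rng.integers(1, max_segments + 1))
    segments = []
    for i in range(n_segments):
        n = int(rng.integers(0, 6))
        idx = rng.choice(len(pairs), size=n, replace=True)
        mentions = frozenset(DependencyMention(*pairs[j]) for j in idx)
        segments.append(CodedSegment(f"I{i % 4}", f"S{i}", mentions))
    return Corpus(vocab, segments)


def random_network(
    rng: np.random.Generator, max_nodes: int = 15, max_weight: int = 30
) -> BiculturalNetwork:
    """A random two-class digraph with integer weights and no
    biophysical->biophysical edge."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"N{i}" for i in range(n)]
    classes = {
        name: (VALUE if rng.random() < 0.6 else BIOPHYSICAL) for name in names
    }
    if all(c == BIOPHYSICAL for c in classes.values()):
        classes[names[0]] = VALUE  # admissible edges need a value endpoint
    edges = []
    for u in names:
        for v in names:
            if u == v:
                continue
            if classes[u] == BIOPHYSICAL and classes[v] == BIOPHYSICAL:
                continue
            if rng.random() < 0.3:
                edges.append((u, v, int(rng.integers(1, max_weight + 1))))
    if not edges:  # guarantee at least one admissible edge
        u = next(name for name in names if classes[name] == VALUE)
        v = next(name for name in names if name != u)
        if classes[v] == BIOPHYSICAL and classes[u] == BIOPHYSICAL:
            raise AssertionError("unreachable")
        edges.append((v, u, 1) if classes[v] == BIOPHYSICAL else (u, v, 1))
    return BiculturalNetwork.from_edges(edges, classes)


def brute_force_cooccurrence(corpus: Corpus) -> dict[tuple[str, str], int]:
    """Independent oracle: for every ordered code pair, count the segments
    whose mention set contains that directed dependency."""
    codes = sorted(
        corpus.vocabulary.value_codes | corpus.vocabulary.biophysical_codes
    )
    counts: dict[tuple[str, str], int] = {}
    for a in codes:
        for b in codes:
            if a == b:
                continue
            n = sum(
                1
                for seg in corpus.segments
                if any(m.source == a and m.target == b for m in seg.mentions)
            )
            if n:
                counts[(a, b)] = n
    return counts


def bfs_reachable(adj: dict[str, set[str]], start: str, k: int) -> set[str]:
    """Independent oracle: breadth-first search limited to k steps."""
    frontier = {start}
    seen = {start}
    for _ in range(k):
        frontier = {w for u in frontier for w in adj.get(u, set())} - seen
        seen |= frontier
    return seen


def all_pairs_bfs_mean(adj: dict[str, set[str]], nodes: list[str]) -> tuple[float, int]:
    """Independent oracle: mean finite shortest-path length over ordered
    pairs and the number of unreachable ordered pairs."""
    total, finite = 0, 0
    for s in nodes:
        dist = {s: 0}
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for w in adj.get(u, set()):
                    if w not in dist:
                        dist[w] = d
                        nxt.append(w)
            frontier = nxt
        for t in nodes:
            if t != s and t in dist:
                total += dist[t]
                finite += 1
    n_pairs = len(nodes) * (len(nodes) - 1)
    return (total / finite if finite else float("nan")), n_pairs - finite
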