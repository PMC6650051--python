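"""Weighted PPI networks: STRING-style edge-list I/O, identifier mapping, summaries.

STRING distributes protein-protein association networks as whitespace-delimited
edge lists with integer confidence scores in 0..1000.  Scores are normalized to
(0, 1] on read so that downstream diffusion has nonnegative edge weights on a
common scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

NETWORK_NAMES = (
    "combinedscore",
    "textmining",
    "experimental",
    "database",
    "coexpression",
    "neighborhood",
    "cooccurrence",
    "fusion",
)


class NetworkParseError(ValueError):
    """Raised for malformed edge-list rows (names the offending line)."""


class NetworkValidationError(ValueError):
    """Raised for structurally invalid networks or out-of-range scores."""


@dataclass
class WeightedNetwork:
    """Undirected weighted graph over protein identifiers.

    Invariants: no self-loops, no duplicate edges, all weights in (0, 1],
    node list free of duplicates.  Backed by a :class:`networkx.Graph` whose
    node insertion order fixes the canonical node ordering.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    name: str = "combinedscore"

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for u, v, w in self.graph.edges(data="weight"):
            yield u, v, w

    def validate(self) -> None:
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise NetworkValidationError(f"self-loop on node {u!r}")
            if not (0.0 < w <= 1.0):
                raise NetworkValidationError(
                    f"edge ({u!r}, {v!r}) weight {w} outside (0, 1]"
                )


def _add_edge_max(g: nx.Graph, u: str, v: str, w: float) -> None:
    """Insert an undirected edge, keeping the maximum weight on duplicates."""
    if g.has_edge(u, v):
        if w > g.edges[u, v]["weight"]:
            g.edges[u, v]["weight"] = w
    else:
        g.add_edge(u, v, weight=w)


def read_string_edgelist(
    path, score_scale: int = 1000, name: str = "combinedscore",
    min_score: float | None = None,
) -> WeightedNetwork:
    """Parse a STRING-style edge list ``protein1 protein2 combined_score``.

    Integer scores are divided by ``score_scale`` into (0, 1].  A single
    header row is detected by a non-numeric third column.  Duplicate pairs
    (STRING lists each pair once per direction) collapse to the maximum
    weight; self-loops are dropped and counted.  ``min_score`` optionally
    drops edges with a raw score below the cutoff (no cutoff by default).
    """
    g = nx.Graph()
    n_self_loops = 0
    n_data_rows = 0
    held_header: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise NetworkParseError(
                    f"line {lineno}: expected 3 columns, got {len(parts)}"
                )
            a, b, raw = parts
            try:
                score = float(raw)
            except ValueError:
                if lineno == 1:
                    # potential header: accepted only if data rows follow
                    held_header = lineno
                    continue
                raise NetworkParseError(
                    f"line {lineno}: non-numeric score {raw!r}"
                ) from None
            n_data_rows += 1
            if not (0 <= score <= score_scale):
                raise NetworkValidationError(
                    f"line {lineno}: score {raw} outside [0, {score_scale}]"
                )
            if min_score is not None and score < min_score:
                continue
            if a == b:
                n_self_loops += 1
                continue
            if score == 0:
                continue
            g.add_node(a)
            g.add_node(b)
            _add_edge_max(g, a, b, score / score_scale)
    if held_header is not None and n_data_rows == 0:
        raise NetworkParseError(
            f"line {held_header}: non-numeric score and no data rows follow"
        )
    if n_self_loops:
        logger.info("dropped %d self-loop rows from %s", n_self_loops, path)
    return WeightedNetwork(graph=g, name=name)


def write_string_edgelist(net: WeightedNetwork, path, score_scale: int = 1000,
                          header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("protein1 protein2 combined_score\n")
        for u, v, w in net.edges():
            fh.write(f"{u} {v} {int(round(w * score_scale))}\n")
        # preserve isolated nodes as zero-weight self rows is not valid STRING;
        # isolated nodes are simply not representable in the edge-list format.


@dataclass
class IdMapping:
    """Many-to-one map from external identifiers to canonical identifiers.

    Idempotent on canonical ids: applying the map twice equals applying once.
    """

    pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # force idempotence: resolve chains source -> target -> target'
        for src in list(self.pairs):
            tgt = self.pairs[src]
            seen = {src}
            while tgt in self.pairs and self.pairs[tgt] != tgt and tgt not in seen:
                seen.add(tgt)
                tgt = self.pairs[tgt]
            self.pairs[src] = tgt

    def canonical(self, identifier: str) -> str:
        return self.pairs.get(identifier, identifier)

    @classmethod
    def from_tsv(cls, path) -> "IdMapping":
        pairs: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2 or not parts[0]:
                    raise NetworkParseError(
                        f"line {lineno}: expected 2 tab-separated columns"
                    )
                pairs[parts[0]] = parts[1]
        return cls(pairs=pairs)


def apply_mapping(net: WeightedNetwork, mapping: IdMapping | Mapping[str, str]) -> WeightedNetwork:
    """Replace node ids with canonical ids, merging collapsed edges by max weight.

    Unmapped ids are kept verbatim (lossy mapping is logged, not fatal).
    """
    if not isinstance(mapping, IdMapping):
        mapping = IdMapping(pairs=dict(mapping))
    g = nx.Graph()
    n_unmapped = 0
    for node in net.graph.nodes:
        canon = mapping.canonical(node)
        if canon == node and node not in mapping.pairs:
            n_unmapped += 1
        g.add_node(canon)
    for u, v, w in net.edges():
        cu, cv = mapping.canonical(u), mapping.canonical(v)
        if cu == cv:
            continue  # mapping collapsed the endpoints into a self-loop
        _add_edge_max(g, cu, cv, w)
    if n_unmapped:
        logger.info("%d node ids had no mapping entry and were kept verbatim",
                    n_unmapped)
    return WeightedNetwork(graph=g, name=net.name)


def network_summary(net: WeightedNetwork, training_ids: set[str]) -> dict:
    """Node/edge counts plus coverage of a training set, as a percentage."""
    if not training_ids:
        raise NetworkValidationError("coverage undefined for an empty training set")
    nodes = set(net.graph.nodes)
    coverage = 100.0 * len(nodes & set(training_ids)) / len(training_ids)
    return {
        "n_proteins": net.n_nodes,
        "n_interactions": net.n_edges,
        "coverage_pct": coverage,
    }
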