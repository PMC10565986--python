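"""Knowledge graphs of molecular networks.

A knowledge graph here is a typed multigraph ``G = (V, E)``: nodes are
molecules (gene symbols, compounds, complexes, biological processes) and each
edge carries a relation label such as ``controls-phosphorylation-of`` or
``Activates``.  Two on-disk dialects are supported:

* SIF — the 3-column, headerless ``node <TAB> relation <TAB> node`` edge list
  distributed by Pathway Commons;
* a normalized 5-column pathway edge TSV
  (``source  target  relation  source_type  target_type``) for curated cancer
  signaling pathways, where node types distinguish proteins, complexes and
  processes.

Relations are namespaced by their source (``pathway_commons`` vs
``cancer_pathway``) so that graphs from different sources can be merged
without conflating relation vocabularies: nodes collapse by identifier,
relation vocabularies and edge sets stay disjoint and therefore additive.
"""

from __future__ import annotations

import gzip
import io
import json
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "RelationLabel",
    "KnowledgeGraph",
    "GraphParseError",
    "GraphValidationError",
    "parse_sif",
    "parse_pathway_edges",
    "merge_graphs",
    "relation_subgraph",
    "graph_stats",
    "write_sif",
    "graph_to_json",
    "graph_from_json",
]

PATHWAY_NODE_KINDS = frozenset({"protein", "complex", "process"})
_PATHWAY_HEADER = ("source", "target", "relation", "source_type", "target_type")


class GraphParseError(ValueError):
    """Raised when an edge-list file is syntactically malformed."""


class GraphValidationError(ValueError):
    """Raised when parsed content violates a graph invariant."""


@dataclass(frozen=True, order=True)
class RelationLabel:
    """An edge label together with the namespace of its source database."""

    name: str
    source_namespace: str

    def __post_init__(self) -> None:
        if not self.name:
            raise GraphValidationError("relation name must be non-empty")
        if not self.source_namespace:
            raise GraphValidationError("relation namespace must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.source_namespace}:{self.name}"


Edge = tuple[str, RelationLabel, str]


@dataclass(frozen=True)
class KnowledgeGraph:
    """Immutable typed multigraph with canonically sorted members.

    ``nodes``, ``relations`` and ``edges`` are sorted tuples, so two graphs
    built from the same triples in any order compare equal and iterate
    identically — the basis for every determinism guarantee downstream.
    Edges are stored directed; undirected interpretation is the encoder's
    choice.  Self-loops are kept.
    """

    nodes: tuple[str, ...]
    relations: tuple[RelationLabel, ...]
    edges: tuple[Edge, ...]
    node_kind: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        edges: Iterable[Edge],
        extra_nodes: Iterable[str] = (),
        node_kind: Mapping[str, str] | None = None,
    ) -> "KnowledgeGraph":
        """Construct a graph from triples, deduplicating and validating."""
        edge_set = set()
        nodes = set(extra_nodes)
        relations = set()
        for u, r, v in edges:
            if not u or not v:
                raise GraphValidationError("node identifiers must be non-empty")
            if not isinstance(r, RelationLabel):
                raise GraphValidationError(f"relation {r!r} is not a RelationLabel")
            edge_set.add((u, r, v))
            nodes.add(u)
            nodes.add(v)
            relations.add(r)
        kind = dict(node_kind or {})
        for n, k in kind.items():
            if n not in nodes:
                raise GraphValidationError(f"node_kind refers to unknown node {n!r}")
            if k not in PATHWAY_NODE_KINDS | {"compound", "unknown"}:
                raise GraphValidationError(f"unknown node kind {k!r} for node {n!r}")
        return cls(
            nodes=tuple(sorted(nodes)),
            relations=tuple(sorted(relations)),
            edges=tuple(sorted(edge_set)),
            node_kind=kind,
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    @property
    def namespaces(self) -> frozenset[str]:
        return frozenset(r.source_namespace for r in self.relations)

    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def relation_index(self) -> dict[RelationLabel, int]:
        return {r: i for i, r in enumerate(self.relations)}

    def has_edge(self, u: str, r: RelationLabel, v: str) -> bool:
        return (u, r, v) in set(self.edges)


def _open_text(source: str | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = str(source)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def parse_sif(source: str | IO[str], namespace: str = "pathway_commons") -> KnowledgeGraph:
    """Parse a 3-column SIF edge list into a :class:`KnowledgeGraph`.

    Duplicate triples collapse; line order never affects the result.  A line
    with a field count other than 3 raises :class:`GraphParseError` naming
    the line; an empty file yields an empty graph with a warning.
    """
    edges: list[Edge] = []
    stream = _open_text(source)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise GraphParseError(
                f"line {lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        u, rel, v = (f.strip() for f in fields)
        if not (u and rel and v):
            raise GraphParseError(f"line {lineno}: empty field")
        edges.append((u, RelationLabel(rel, namespace), v))
    if not edges:
        warnings.warn("SIF input contained no edges; returning an empty graph")
    return KnowledgeGraph.build(edges)


def parse_pathway_edges(
    source: str | IO[str], namespace: str = "cancer_pathway"
) -> KnowledgeGraph:
    """Parse the normalized 5-column pathway edge TSV (header required).

    Columns: ``source  target  relation  source_type  target_type`` with node
    types drawn from {protein, complex, process}.  Relation names such as
    ``Activates`` are preserved verbatim; ``node_kind`` is populated.
    """
    stream = _open_text(source)
    header_line = stream.readline()
    if not header_line:
        raise GraphParseError("pathway edge file is empty (missing header)")
    header = tuple(h.strip() for h in header_line.rstrip("\n").split("\t"))
    if header != _PATHWAY_HEADER:
        raise GraphParseError(
            f"bad header {header!r}; expected {_PATHWAY_HEADER!r}"
        )
    edges: list[Edge] = []
    kinds: dict[str, str] = {}
    for lineno, raw in enumerate(stream, start=2):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise GraphParseError(
                f"line {lineno}: expected 5 tab-separated fields, got {len(fields)}"
            )
        src, tgt, rel, src_type, tgt_type = (f.strip() for f in fields)
        for node, ntype in ((src, src_type), (tgt, tgt_type)):
            if ntype not in PATHWAY_NODE_KINDS:
                raise GraphValidationError(
                    f"line {lineno}: unknown node type {ntype!r} for {node!r}"
                )
            prev = kinds.setdefault(node, ntype)
            if prev != ntype:
                raise GraphValidationError(
                    f"line {lineno}: node {node!r} declared both {prev!r} and {ntype!r}"
                )
        edges.append((src, RelationLabel(rel, namespace), tgt))
    if not edges:
        warnings.warn("pathway edge input contained no edges; returning an empty graph")
    return KnowledgeGraph.build(edges, node_kind=kinds)


def merge_graphs(g1: KnowledgeGraph, g2: KnowledgeGraph) -> KnowledgeGraph:
    """Merge two graphs from distinct relation namespaces.

    Nodes unify by identifier string (shared gene symbols collapse); relation
    vocabularies and edge sets are disjoint unions, so edge and relation
    counts add exactly.
    """
    shared = g1.namespaces & g2.namespaces
    if shared:
        raise GraphValidationError(
            f"cannot merge graphs sharing relation namespace(s) {sorted(shared)}"
        )
    kind = dict(g1.node_kind)
    kind.update(g2.node_kind)
    return KnowledgeGraph.build(
        list(g1.edges) + list(g2.edges),
        extra_nodes=list(g1.nodes) + list(g2.nodes),
        node_kind=kind,
    )


def relation_subgraph(g: KnowledgeGraph, r: RelationLabel) -> KnowledgeGraph:
    """Edges with relation ``r`` over the FULL node set of ``g``.

    Keeping every node (even if isolated under ``r``) keeps embedding tables
    aligned across relation subgraphs.
    """
    if r not in g.relations:
        raise KeyError(f"relation {r} not in graph vocabulary")
    return KnowledgeGraph(
        nodes=g.nodes,
        relations=(r,),
        edges=tuple(e for e in g.edges if e[1] == r),
        node_kind=g.node_kind,
    )


def graph_stats(g: KnowledgeGraph) -> dict:
    """Exact node/edge/relation counts plus per-relation edge counts."""
    per_rel: dict[str, int] = {}
    for _, r, _ in g.edges:
        key = str(r)
        per_rel[key] = per_rel.get(key, 0) + 1
    return {
        "n_nodes": g.n_nodes,
        "n_edges": g.n_edges,
        "n_relations": g.n_relations,
        "per_relation_edge_counts": dict(sorted(per_rel.items())),
    }


def write_sif(g: KnowledgeGraph, stream: IO[str]) -> None:
    """Serialize edges as 3-column SIF (namespaces are not written)."""
    for u, r, v in g.edges:
        stream.write(f"{u}\t{r.name}\t{v}\n")


def graph_to_json(g: KnowledgeGraph) -> str:
    """Canonical JSON: nodes, [name, namespace] relations, [u, r_idx, v] edges."""
    ridx = g.relation_index()
    payload = {
        "nodes": list(g.nodes),
        "relations": [[r.name, r.source_namespace] for r in g.relations],
        "edges": [[u, ridx[r], v] for u, r, v in g.edges],
        "node_kind": dict(g.node_kind) or None,
    }
    return json.dumps(payload, indent=None, separators=(",", ":"))


def graph_from_json(text: str) -> KnowledgeGraph:
    payload = json.loads(text)
    relations = [RelationLabel(name, ns) for name, ns in payload["relations"]]
    edges = [(u, relations[ri], v) for u, ri, v in payload["edges"]]
    return KnowledgeGraph.build(
        edges,
        extra_nodes=payload["nodes"],
        node_kind=payload.get("node_kind") or {},
    )
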