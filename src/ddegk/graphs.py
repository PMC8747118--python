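"""Event-graph data model: rooted, typed, attributed DAGs.

A biomedical event graph encodes one literature-mentioned interaction: a
*trigger* node (the textual anchor of the event, e.g. "promotes") is the
root; its arguments — entities or nested sub-events — hang off role-labeled
directed edges (Theme, Cause, Site, ...). Graphs are directed, unweighted
and acyclic; only triggers have outgoing edges; every node carries a
categorical type and a free-text surface attribute.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import DuplicateNode, MalformedRoot

logger = logging.getLogger(__name__)

__all__ = [
    "NodeRecord", "EdgeRecord", "EventGraph", "TypeVocabulary",
    "ValidationReport", "validate_event_graph", "adjacency", "root_of",
    "graph_to_dict", "graph_from_dict", "write_graphs", "read_graphs",
    "content_key",
]


@dataclass(frozen=True)
class NodeRecord:
    """One vertex: a trigger or entity with type and surface text."""

    node_id: str
    kind: str  # "trigger" | "entity"
    type_label: str
    text: str
    char_span: tuple[int, int] | None = None


@dataclass(frozen=True)
class EdgeRecord:
    """One role-labeled directed edge; the source is always a trigger."""

    source: str
    target: str
    role_label: str


@dataclass
class TypeVocabulary:
    """Ordered node/edge/graph type sets for a dataset.

    Ordering is fixed at construction so one-hot indices are stable across
    serialization round-trips.
    """

    node_types: list[str] = field(default_factory=list)
    edge_types: list[str] = field(default_factory=list)
    graph_types: list[str] = field(default_factory=list)

    @classmethod
    def from_graphs(cls, graphs: "list[EventGraph]") -> "TypeVocabulary":
        nt, et, gt = [], [], []
        for g in graphs:
            for n in g.nodes:
                if n.type_label not in nt:
                    nt.append(n.type_label)
            for e in g.edges:
                if e.role_label not in et:
                    et.append(e.role_label)
            if g.principal_type not in gt:
                gt.append(g.principal_type)
        return cls(nt, et, gt)

    def merge(self, other: "TypeVocabulary") -> "TypeVocabulary":
        def union(a, b):
            out = list(a)
            out.extend(x for x in b if x not in out)
            return out

        return TypeVocabulary(
            union(self.node_types, other.node_types),
            union(self.edge_types, other.edge_types),
            union(self.graph_types, other.graph_types),
        )

    def to_dict(self) -> dict:
        return {"node_types": self.node_types, "edge_types": self.edge_types,
                "graph_types": self.graph_types}

    @classmethod
    def from_dict(cls, d: dict) -> "TypeVocabulary":
        return cls(list(d["node_types"]), list(d["edge_types"]), list(d["graph_types"]))


@dataclass
class EventGraph:
    """A rooted event DAG. Node order is fixed at construction."""

    nodes: list[NodeRecord]
    edges: list[EdgeRecord]
    root_id: str
    principal_type: str
    dataset_tag: str = ""
    doc_id: str = ""

    def __post_init__(self):
        self._index = {n.node_id: i for i, n in enumerate(self.nodes)}

    # -- accessors -------------------------------------------------------
    def node(self, node_id: str) -> NodeRecord:
        return self.nodes[self._index[node_id]]

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def successors(self, node_id: str) -> list[str]:
        return [e.target for e in self.edges if e.source == node_id]

    def node_types(self) -> list[str]:
        return [n.type_label for n in self.nodes]

    def incident_edges(self, node_id: str) -> list[EdgeRecord]:
        """Edges touching the node in either direction."""
        return [e for e in self.edges if node_id in (e.source, e.target)]

    def reordered(self) -> "EventGraph":
        """Return a copy with canonical node order: root first, then
        breadth-first following edge list order. Unreached nodes (if any)
        keep their relative order at the end."""
        order = [self.root_id]
        seen = {self.root_id}
        frontier = [self.root_id]
        while frontier:
            nxt = []
            for u in frontier:
                for e in self.edges:
                    if e.source == u and e.target not in seen:
                        seen.add(e.target)
                        order.append(e.target)
                        nxt.append(e.target)
            frontier = nxt
        order.extend(n.node_id for n in self.nodes if n.node_id not in seen)
        nodes = [self.node(i) for i in order]
        return EventGraph(nodes, list(self.edges), self.root_id,
                          self.principal_type, self.dataset_tag, self.doc_id)


@dataclass
class ValidationReport:
    ok: bool
    issues: list[tuple[str, str]]


def adjacency(g: EventGraph) -> np.ndarray:
    """Binary adjacency matrix in node-list order: A[i, j] = 1 iff i -> j."""
    ids = [n.node_id for n in g.nodes]
    if len(set(ids)) != len(ids):
        raise DuplicateNode(f"duplicate node ids in graph {g.doc_id!r}")
    n = len(ids)
    a = np.zeros((n, n), dtype=np.int64)
    for e in g.edges:
        a[g.index_of(e.source), g.index_of(e.target)] = 1
    return a


def root_of(g: EventGraph) -> str:
    """The unique trigger with in-degree 0 from which all nodes are reachable."""
    targets = {e.target for e in g.edges}
    candidates = [n.node_id for n in g.nodes
                  if n.kind == "trigger" and n.node_id not in targets]
    dg = nx.DiGraph()
    dg.add_nodes_from(n.node_id for n in g.nodes)
    dg.add_edges_from((e.source, e.target) for e in g.edges)
    roots = [c for c in candidates
             if len(nx.descendants(dg, c)) == len(g.nodes) - 1]
    if len(roots) != 1:
        raise MalformedRoot(
            f"expected one covering root trigger, found {len(roots)}")
    return roots[0]


def validate_event_graph(g: EventGraph, vocab: TypeVocabulary) -> ValidationReport:
    """Check every data-model invariant; report (never raise) violations."""
    issues: list[tuple[str, str]] = []
    ids = [n.node_id for n in g.nodes]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        issues.append(("DuplicateNode", f"duplicate node ids: {sorted(dup)}"))
    if len(g.nodes) < 2:
        issues.append(("TooFewNodes", f"|V|={len(g.nodes)} < 2"))
    node_kinds = {}
    for n in g.nodes:
        node_kinds[n.node_id] = n.kind
        if n.kind not in ("trigger", "entity"):
            issues.append(("UnknownKind", f"{n.node_id}: kind {n.kind!r}"))
        if n.type_label not in vocab.node_types:
            issues.append(("UnknownNodeType", f"{n.node_id}: {n.type_label!r}"))
        if not n.text:
            issues.append(("EmptyText", f"{n.node_id} has empty text"))
    seen_pairs = set()
    for e in g.edges:
        if e.source == e.target:
            issues.append(("SelfLoop", f"{e.source} -> itself"))
        if e.source not in node_kinds or e.target not in node_kinds:
            issues.append(("DanglingEdge", f"{e.source} -> {e.target}"))
            continue
        if node_kinds[e.source] != "trigger":
            issues.append(("NonTriggerSource", f"{e.source} is not a trigger"))
        if e.role_label not in vocab.edge_types:
            issues.append(("UnknownRole", f"{e.role_label!r} not in edge vocabulary"))
        if (e.source, e.target) in seen_pairs:
            issues.append(("ParallelEdge", f"{e.source} -> {e.target} repeated"))
        seen_pairs.add((e.source, e.target))
    if not dup and all(e.source in node_kinds and e.target in node_kinds
                       for e in g.edges):
        dg = nx.DiGraph()
        dg.add_nodes_from(ids)
        dg.add_edges_from((e.source, e.target) for e in g.edges)
        if not nx.is_directed_acyclic_graph(dg):
            issues.append(("CycleDetected", "graph contains a directed cycle"))
        if g.root_id not in node_kinds:
            issues.append(("MalformedRoot", f"root {g.root_id!r} not a node"))
        else:
            reach = nx.descendants(dg, g.root_id) | {g.root_id}
            missing = set(ids) - reach
            if missing:
                issues.append(("Unreachable",
                               f"nodes not reachable from root: {sorted(missing)}"))
            if node_kinds[g.root_id] != "trigger":
                issues.append(("MalformedRoot", "root is not a trigger"))
    if g.principal_type not in vocab.graph_types:
        issues.append(("UnknownGraphType", f"{g.principal_type!r}"))
    return ValidationReport(ok=not issues, issues=issues)


# -- JSON interchange ----------------------------------------------------

def graph_to_dict(g: EventGraph) -> dict:
    return {
        "nodes": [{"id": n.node_id, "kind": n.kind, "type": n.type_label,
                   "text": n.text,
                   "span": list(n.char_span) if n.char_span else None}
                  for n in g.nodes],
        "edges": [{"src": e.source, "dst": e.target, "role": e.role_label}
                  for e in g.edges],
        "root": g.root_id,
        "principal_type": g.principal_type,
        "dataset_tag": g.dataset_tag,
        "doc_id": g.doc_id,
    }


def graph_from_dict(d: dict) -> EventGraph:
    nodes = [NodeRecord(n["id"], n["kind"], n["type"], n["text"],
                        tuple(n["span"]) if n.get("span") else None)
             for n in d["nodes"]]
    edges = [EdgeRecord(e["src"], e["dst"], e["role"]) for e in d["edges"]]
    return EventGraph(nodes, edges, d["root"], d["principal_type"],
                      d.get("dataset_tag", ""), d.get("doc_id", ""))


def write_graphs(graphs: list[EventGraph], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([graph_to_dict(g) for g in graphs], fh, ensure_ascii=False,
                  indent=1)


def read_graphs(path) -> list[EventGraph]:
    with open(path, encoding="utf-8") as fh:
        return [graph_from_dict(d) for d in json.load(fh)]


def content_key(g: EventGraph) -> int:
    """Stable 31-bit content hash of a graph's canonical JSON form.

    Used to derive per-(anchor, target) training seeds so byte-identical
    graphs follow identical training trajectories.
    """
    blob = json.dumps(graph_to_dict(g), sort_keys=True).encode()
    return int.from_bytes(hashlib.blake2b(blob, digest_size=4).digest(), "big") % (2**31)
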