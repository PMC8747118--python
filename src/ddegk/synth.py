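"""Seeded synthetic event-graph datasets.

Real biomedical event corpora are small rooted DAGs (2-18 nodes) whose nodes
carry categorical types and short text spans, with optional arguments and
occasional nesting (an event serving as another event's argument). The
generator emulates exactly that statistical shape from a declarative schema
of event *families*, so the whole pipeline is testable offline.

Synonymy is modeled through per-type clusters of surface strings sharing a
character stem: under the hashed-n-gram fallback embedder, same-cluster
strings land close in cosine space without any pre-trained model. With
``noise_scale = 0`` every member of a cluster receives the cluster's
canonical string, hence identical fallback vectors.
"""

from __future__ import annotations

import json
import logging
import string
from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError
from .graphs import EdgeRecord, EventGraph, NodeRecord

logger = logging.getLogger(__name__)

__all__ = ["ArgSpec", "Family", "SyntheticSchema", "default_schema",
           "generate", "isomorphic_variant", "write_dataset"]


@dataclass(frozen=True)
class ArgSpec:
    """One argument slot: role label, target node type, presence probability.

    If ``target_type`` names an entry of the schema's ``event_templates``,
    the slot realizes a nested sub-event (a trigger-trigger edge)."""

    role: str
    target_type: str
    presence: float


@dataclass(frozen=True)
class Family:
    family_id: str
    root_type: str
    nesting_prob: float = 0.0  # scales presence of event-valued slots
    max_depth: int = 1
    weight: float = 1.0


@dataclass
class SyntheticSchema:
    families: list[Family]
    event_templates: dict[str, list[ArgSpec]]
    vocab_clusters: dict[str, list[str]]
    noise_scale: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "families": [vars(f) | {} for f in self.families],
            "event_templates": {k: [vars(a) for a in v]
                                for k, v in self.event_templates.items()},
            "vocab_clusters": self.vocab_clusters,
            "noise_scale": self.noise_scale,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSchema":
        return cls(
            families=[Family(**f) for f in d["families"]],
            event_templates={k: [ArgSpec(**a) for a in v]
                             for k, v in d["event_templates"].items()},
            vocab_clusters={k: list(v) for k, v in d["vocab_clusters"].items()},
            noise_scale=d.get("noise_scale", 0.0),
            seed=d.get("seed", 0),
        )


def default_schema(noise_scale: float = 0.3) -> SyntheticSchema:
    """Three event families sized like the small end of real corpora
    (2-6 nodes, occasional one-level nesting)."""
    return SyntheticSchema(
        families=[
            Family("Gene_expression", "Gene_expression", max_depth=1),
            Family("Binding", "Binding", max_depth=1),
            Family("Positive_regulation", "Positive_regulation",
                   nesting_prob=0.5, max_depth=2),
        ],
        event_templates={
            "Gene_expression": [ArgSpec("Theme", "Protein", 1.0),
                                ArgSpec("Site", "DNA_domain", 0.5)],
            "Binding": [ArgSpec("Theme", "Protein", 1.0),
                        ArgSpec("Theme2", "Protein", 0.8),
                        ArgSpec("Site", "Protein_domain", 0.4)],
            "Positive_regulation": [ArgSpec("Theme", "Gene", 1.0),
                                    ArgSpec("Cause", "Phosphorylation", 0.5)],
            "Phosphorylation": [ArgSpec("Theme", "Protein", 1.0),
                                ArgSpec("Site", "Residue", 0.5)],
        },
        vocab_clusters={
            "Gene_expression": ["expression", "expressed", "expressing"],
            "Binding": ["binding", "binds", "bound"],
            "Positive_regulation": ["activation", "activates", "activated"],
            "Phosphorylation": ["phosphorylation", "phosphorylates",
                                "phosphorylated"],
            "Protein": ["interleukin2", "interleukin-2", "interleukin_2"],
            "Gene": ["bmi1gene", "bmi-1gene", "bmi1_gene"],
            "DNA_domain": ["promoterdna", "promoter-dna", "promoter_dna"],
            "Protein_domain": ["shdomain", "sh-domain", "sh_domain"],
            "Residue": ["serine89", "serine-89", "serine_89"],
        },
        noise_scale=noise_scale,
        seed=0,
    )


def _text_for(type_label: str, schema: SyntheticSchema, rng: np.random.Generator) -> str:
    cluster = schema.vocab_clusters.get(type_label, [type_label.lower()])
    if schema.noise_scale == 0.0:
        return cluster[0]
    text = cluster[int(rng.integers(len(cluster)))]
    if rng.random() < min(1.0, schema.noise_scale):
        text = text + rng.choice(list(string.ascii_lowercase))
    return text


def _expand(event_type: str, depth: int, family: Family,
            schema: SyntheticSchema, rng: np.random.Generator,
            nodes: list[NodeRecord], edges: list[EdgeRecord],
            counter: list[int], gid: int) -> str:
    template = schema.event_templates.get(event_type)
    if not template:
        raise SchemaError(f"no argument template for event type {event_type!r}")
    nid = f"g{gid}_n{counter[0]}"
    counter[0] += 1
    nodes.append(NodeRecord(nid, "trigger", event_type,
                            _text_for(event_type, schema, rng)))
    for arg in template:
        nested = arg.target_type in schema.event_templates
        p = arg.presence * (family.nesting_prob if nested else 1.0)
        if rng.random() >= p:
            continue
        if nested:
            if depth + 1 >= family.max_depth:
                continue
            child = _expand(arg.target_type, depth + 1, family, schema, rng,
                            nodes, edges, counter, gid)
        else:
            child = f"g{gid}_n{counter[0]}"
            counter[0] += 1
            nodes.append(NodeRecord(child, "entity", arg.target_type,
                                    _text_for(arg.target_type, schema, rng)))
        edges.append(EdgeRecord(nid, child, arg.role))
    return nid


def _sample_graph(family: Family, schema: SyntheticSchema,
                  rng: np.random.Generator, gid: int) -> EventGraph:
    nodes: list[NodeRecord] = []
    edges: list[EdgeRecord] = []
    root = _expand(family.root_type, 0, family, schema, rng, nodes, edges,
                   [0], gid)
    if len(nodes) < 2:
        # presence draws can leave a bare trigger; force the first slot
        template = schema.event_templates[family.root_type]
        entity_slots = [a for a in template
                        if a.target_type not in schema.event_templates]
        if not entity_slots:
            raise SchemaError(
                f"family {family.family_id!r} cannot reach |V| >= 2")
        arg = entity_slots[0]
        child = f"g{gid}_n{len(nodes)}"
        nodes.append(NodeRecord(child, "entity", arg.target_type,
                                _text_for(arg.target_type, schema, rng)))
        edges.append(EdgeRecord(root, child, arg.role))
    g = EventGraph(nodes, edges, root, family.family_id,
                   dataset_tag="synthetic", doc_id=f"synth:{gid}")
    return g.reordered()


def generate(schema: SyntheticSchema, n: int,
             seed: int | None = None) -> tuple[list[EventGraph], list[str]]:
    """Draw ``n`` event graphs; returns (graphs, family labels)."""
    if n < 1:
        raise SchemaError("n must be >= 1")
    rng = np.random.default_rng(schema.seed if seed is None else seed)
    weights = np.array([f.weight for f in schema.families], dtype=float)
    weights /= weights.sum()
    graphs, labels = [], []
    for i in range(n):
        family = schema.families[int(rng.choice(len(schema.families), p=weights))]
        graphs.append(_sample_graph(family, schema, rng, i))
        labels.append(family.family_id)
    return graphs, labels


def isomorphic_variant(g: EventGraph, seed: int,
                       schema: SyntheticSchema | None = None) -> EventGraph:
    """Structure- and type-preserving copy with fresh node ids and
    same-cluster synonym texts.

    The node bijection is recorded on the result as ``provenance_mapping``
    (old id -> new id)."""
    schema = schema or default_schema()
    rng = np.random.default_rng(seed)
    mapping = {n.node_id: f"var{seed}_{i}" for i, n in enumerate(g.nodes)}
    nodes = []
    for n in g.nodes:
        cluster = schema.vocab_clusters.get(n.type_label, [])
        options = [s for s in cluster if s != n.text]
        if options:
            text = options[int(rng.integers(len(options)))]
        else:
            text = n.text
            logger.warning("singleton synonym pool for type %s; text kept",
                           n.type_label)
        nodes.append(NodeRecord(mapping[n.node_id], n.kind, n.type_label, text))
    edges = [EdgeRecord(mapping[e.source], mapping[e.target], e.role_label)
             for e in g.edges]
    out = EventGraph(nodes, edges, mapping[g.root_id], g.principal_type,
                     g.dataset_tag, g.doc_id + ":variant")
    out.provenance_mapping = mapping
    return out


def write_dataset(graphs: list[EventGraph], labels: list[str], out_dir) -> None:
    """Write the JSON interchange file plus a labels TSV and the schema-free
    dataset manifest."""
    from pathlib import Path

    from .graphs import write_graphs

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_graphs(graphs, out / "graphs.json")
    with open(out / "labels.tsv", "w", encoding="utf-8") as fh:
        fh.write("doc_id\tlabel\n")
        for g, lab in zip(graphs, labels):
            fh.write(f"{g.doc_id}\t{lab}\n")
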