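"""BioNLP-ST standoff parsing and corpus preprocessing.

A shared-task document is a ``.txt`` file plus two annotation files: ``.a1``
with gold entities and ``.a2`` with event triggers and event frames, all
referencing 0-based half-open character offsets. ``T`` lines carry text-bound
annotations, ``E`` lines event frames (``E1<TAB>Type:T2 Theme:T1 ...``).
Modifier (``M``/``A``), relation (``R``/``N``) and equivalence (``*``) lines
are outside the event-graph model and are skipped with a logged count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import (CyclicEventReference, DanglingReference, DuplicateTag,
                     MalformedLine, SpanMismatch)
from .graphs import EdgeRecord, EventGraph, NodeRecord, TypeVocabulary

logger = logging.getLogger(__name__)

__all__ = ["TextBound", "EventFrame", "StandoffDocument", "SamplingSpec",
           "parse_standoff", "events_to_graphs", "stratified_sample",
           "merge_datasets", "node_count_bin", "sampling_manifest"]

NODE_BINS = ("2", "3", "4", "5", "6", "7+")


@dataclass(frozen=True)
class TextBound:
    ann_id: str
    type_label: str
    fragments: tuple[tuple[int, int], ...]
    surface: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.fragments[0][0], self.fragments[-1][1])


@dataclass(frozen=True)
class EventFrame:
    ann_id: str
    event_type: str
    trigger_id: str
    args: tuple[tuple[str, str], ...]  # (role, target id)


@dataclass
class StandoffDocument:
    doc_id: str
    text: str
    entities: list[TextBound]
    triggers: list[TextBound]
    events: list[EventFrame]

    def text_bound(self, ann_id: str) -> TextBound | None:
        for tb in self.entities + self.triggers:
            if tb.ann_id == ann_id:
                return tb
        return None

    def event(self, ann_id: str) -> EventFrame | None:
        for ev in self.events:
            if ev.ann_id == ann_id:
                return ev
        return None


@dataclass
class SamplingSpec:
    """Stratified sampling over (principal type) x (node-count bin)
    [x dataset tag], mirroring how real corpora are subsampled."""

    target_n: int
    min_type_count: int = 10
    by_dataset: bool = False
    seed: int = 0


def _parse_textbound(line: str, text: str) -> TextBound:
    try:
        ann_id, middle, surface = line.split("\t", 2)
        type_label, span_str = middle.split(" ", 1)
        fragments = tuple(
            (int(s.split()[0]), int(s.split()[1]))
            for s in span_str.split(";"))
    except (ValueError, IndexError) as exc:
        raise MalformedLine(f"cannot parse text-bound line: {line!r}") from exc
    pieces = [text[a:b] for a, b in fragments]
    if " ".join(pieces) != surface:
        raise SpanMismatch(
            f"{ann_id}: annotated surface {surface!r} != text slice "
            f"{' '.join(pieces)!r}")
    return TextBound(ann_id, type_label, fragments, surface)


def _parse_event(line: str) -> EventFrame:
    try:
        ann_id, rest = line.split("\t", 1)
        parts = rest.split()
        event_type, trigger_id = parts[0].split(":", 1)
        args = tuple(tuple(p.split(":", 1)) for p in parts[1:])
    except (ValueError, IndexError) as exc:
        raise MalformedLine(f"cannot parse event line: {line!r}") from exc
    return EventFrame(ann_id, event_type, trigger_id, args)


def parse_standoff(txt: str, a1: str, a2: str, doc_id: str) -> StandoffDocument:
    """Parse one document's (.txt, .a1, .a2) contents."""
    entities: list[TextBound] = []
    triggers: list[TextBound] = []
    events: list[EventFrame] = []
    skipped = 0
    for source, bucket in ((a1, entities), (a2, triggers)):
        for line in source.splitlines():
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tag = line[0]
            if tag == "T":
                bucket.append(_parse_textbound(line, txt))
            elif tag == "E" and source is a2:
                events.append(_parse_event(line))
            elif tag in "MRAN*":
                skipped += 1
            else:
                raise MalformedLine(f"unrecognized annotation line: {line!r}")
    if skipped:
        logger.info("%s: skipped %d modifier/relation/equivalence lines",
                    doc_id, skipped)
    known = ({tb.ann_id for tb in entities} | {tb.ann_id for tb in triggers}
             | {ev.ann_id for ev in events})
    for ev in events:
        if ev.trigger_id not in known:
            raise DanglingReference(f"{ev.ann_id}: trigger {ev.trigger_id}")
        for role, target in ev.args:
            if target not in known:
                raise DanglingReference(f"{ev.ann_id}: {role}:{target}")
    return StandoffDocument(doc_id, txt, entities, triggers, events)


_NUMBERED = re.compile(r"^(.*?)(\d+)$")


def _base_role(role: str) -> str:
    m = _NUMBERED.match(role)
    return m.group(1) if m else role


def events_to_graphs(doc: StandoffDocument,
                     vocab: TypeVocabulary | None = None,
                     collapse_numbered_roles: bool = False) -> list[EventGraph]:
    """One EventGraph per top-level event; nested events are inlined as
    subgraphs via trigger-trigger edges."""
    referenced = {target for ev in doc.events for _, target in ev.args
                  if target.startswith("E")}
    top_level = [ev for ev in doc.events if ev.ann_id not in referenced]

    def expand(ev: EventFrame, nodes: dict[str, NodeRecord],
               edges: list[EdgeRecord], stack: tuple[str, ...]) -> str:
        if ev.ann_id in stack:
            raise CyclicEventReference(" -> ".join(stack + (ev.ann_id,)))
        trig = doc.text_bound(ev.trigger_id)
        if trig is None:
            raise DanglingReference(ev.trigger_id)
        nodes.setdefault(trig.ann_id, NodeRecord(
            trig.ann_id, "trigger", ev.event_type, trig.surface, trig.span))
        for role, target in ev.args:
            if collapse_numbered_roles:
                role = _base_role(role)
            if target.startswith("E"):
                sub = doc.event(target)
                if sub is None:
                    raise DanglingReference(target)
                child = expand(sub, nodes, edges, stack + (ev.ann_id,))
            else:
                tb = doc.text_bound(target)
                if tb is None:
                    raise DanglingReference(target)
                kind = ("trigger" if any(t.ann_id == target for t in doc.triggers)
                        else "entity")
                nodes.setdefault(tb.ann_id, NodeRecord(
                    tb.ann_id, kind, tb.type_label, tb.surface, tb.span))
                child = tb.ann_id
            if any(e.source == trig.ann_id and e.target == child for e in edges):
                logger.warning("%s: parallel edge %s -> %s dropped (first "
                               "role wins)", doc.doc_id, trig.ann_id, child)
                continue
            edges.append(EdgeRecord(trig.ann_id, child, role))
        return trig.ann_id

    graphs = []
    for ev in top_level:
        nodes: dict[str, NodeRecord] = {}
        edges: list[EdgeRecord] = []
        root = expand(ev, nodes, edges, ())
        if len(nodes) < 2:
            logger.warning("%s: event %s has no arguments, skipped",
                           doc.doc_id, ev.ann_id)
            continue
        g = EventGraph(list(nodes.values()), edges, root, ev.event_type,
                       dataset_tag="", doc_id=f"{doc.doc_id}:{ev.ann_id}")
        graphs.append(g.reordered())
    return graphs


def node_count_bin(n: int) -> str:
    """Discretized node count: {2, 3, 4, 5, 6, 7+}."""
    return str(n) if n <= 6 else "7+"


def _stratum(g: EventGraph, by_dataset: bool) -> tuple:
    key = (g.principal_type, node_count_bin(g.n_nodes))
    return key + (g.dataset_tag,) if by_dataset else key


def stratified_sample(graphs: list[EventGraph],
                      spec: SamplingSpec) -> list[EventGraph]:
    """Proportional stratified sampling without replacement, after removing
    principal types with fewer than ``min_type_count`` instances.

    Per-stratum quotas follow population shares with largest-remainder
    rounding; membership is reproducible for a fixed seed.
    """
    if not graphs:
        raise ValueError("no graphs to sample from")
    type_counts: dict[str, int] = {}
    for g in graphs:
        type_counts[g.principal_type] = type_counts.get(g.principal_type, 0) + 1
    eligible = [g for g in graphs
                if type_counts[g.principal_type] >= spec.min_type_count]
    removed = sorted(t for t, c in type_counts.items()
                     if c < spec.min_type_count)
    if removed:
        logger.info("removed %d under-represented event types: %s",
                    len(removed), removed)
    if spec.target_n >= len(eligible):
        if spec.target_n > len(eligible):
            logger.warning("target_n=%d exceeds eligible population %d; "
                           "returning all", spec.target_n, len(eligible))
        return list(eligible)
    strata: dict[tuple, list[int]] = {}
    for i, g in enumerate(eligible):
        strata.setdefault(_stratum(g, spec.by_dataset), []).append(i)
    keys = sorted(strata)
    total = len(eligible)
    exact = {k: spec.target_n * len(strata[k]) / total for k in keys}
    quota = {k: int(exact[k]) for k in keys}
    leftover = spec.target_n - sum(quota.values())
    for k in sorted(keys, key=lambda k: (-(exact[k] - quota[k]), k))[:leftover]:
        quota[k] += 1
    rng = np.random.default_rng(spec.seed)
    chosen: list[int] = []
    for k in keys:
        members = strata[k]
        take = min(quota[k], len(members))
        chosen.extend(rng.choice(members, size=take, replace=False))
    return [eligible[i] for i in sorted(chosen)]


def sampling_manifest(graphs: list[EventGraph], selected: list[EventGraph],
                      spec: SamplingSpec, path) -> None:
    """TSV manifest: doc_id, stratum, selected flag."""
    picked = {id(g) for g in selected}
    sel_docs = {g.doc_id for g in selected}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tstratum\tselected\n")
        for g in graphs:
            flag = int(id(g) in picked or g.doc_id in sel_docs)
            fh.write(f"{g.doc_id}\t{'|'.join(_stratum(g, spec.by_dataset))}\t"
                     f"{flag}\n")


def merge_datasets(datasets: list[tuple[str, list[EventGraph]]]) -> list[EventGraph]:
    """Union of several corpora with the dataset tag stamped on each graph."""
    tags = [t for t, _ in datasets]
    if len(set(tags)) != len(tags):
        raise DuplicateTag(f"duplicate dataset tags in {tags}")
    merged: list[EventGraph] = []
    for tag, graphs in datasets:
        if not graphs:
            logger.warning("dataset %r is empty; skipped", tag)
            continue
        for g in graphs:
            merged.append(EventGraph(list(g.nodes), list(g.edges), g.root_id,
                                     g.principal_type, tag, g.doc_id))
    return merged
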