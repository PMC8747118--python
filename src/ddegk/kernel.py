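"""Anchor selection, all-pairs scoring, and the divergence-vector embedding.

Following the distances-to-kernels (D2KE) construction, a held-out set of M
anchor graphs defines the coordinate system: the embedding of a target graph
is its vector of rectified divergences from each anchor,

    Psi(G_T) = [D(G_T || G_A1), ..., D(G_T || G_AM)],

and the kernel/distance between two graphs is the Euclidean norm of the
difference of their embeddings. Anchors may themselves be embedded as
targets (their own coordinate is 0 by the rectification identity), and new
targets can be scored later against the frozen encoders without touching
existing rows.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .divergence import AnchorEncoder, EncoderConfig, score_pair, \
    symmetric_divergence, train_anchor_encoder
from .errors import ShapeMismatch, TooManyAnchors
from .graphs import EventGraph, content_key
from .spans import embed_texts

logger = logging.getLogger(__name__)

__all__ = ["AnchorSet", "EventEmbedding", "EmbeddingMatrix",
           "select_anchors", "embed_all", "kernel_value",
           "write_embeddings", "write_attention"]


@dataclass
class AnchorSet:
    """Ordered anchors; the order fixes the coordinate order of Psi."""

    anchor_graphs: list[EventGraph]
    strategy: str = "random"
    seed: int = 0

    def __post_init__(self):
        keys = [content_key(g) for g in self.anchor_graphs]
        if len(set(keys)) != len(keys):
            raise ValueError("anchor set contains duplicate graphs")

    @property
    def M(self) -> int:
        return len(self.anchor_graphs)


@dataclass
class EventEmbedding:
    vector: np.ndarray
    target_id: str


@dataclass
class EmbeddingMatrix:
    rows: list[EventEmbedding]
    anchor_set: AnchorSet
    config: EncoderConfig
    encoders: list[AnchorEncoder] = field(default_factory=list, repr=False)
    symmetric: bool = False

    def values(self) -> np.ndarray:
        return np.vstack([r.vector for r in self.rows])

    def extend(self, targets: list[EventGraph]) -> None:
        """Embed new targets against the frozen encoders; existing rows are
        untouched."""
        new_rows = _embed_targets(targets, self.encoders, self.config,
                                  symmetric=self.symmetric)
        self.rows.extend(new_rows)


def select_anchors(graphs: list[EventGraph], M: int, strategy: str = "random",
                   seed: int = 0) -> AnchorSet:
    """Draw M anchors: uniformly at random, or round-robin balanced over
    principal event types ("random_per_type")."""
    if M > len(graphs):
        raise TooManyAnchors(f"M={M} > population {len(graphs)}")
    rng = np.random.default_rng(seed)
    if strategy == "random":
        idx = rng.choice(len(graphs), size=M, replace=False)
        chosen = [graphs[i] for i in sorted(idx)]
    elif strategy == "random_per_type":
        by_type: dict[str, list[int]] = {}
        for i, g in enumerate(graphs):
            by_type.setdefault(g.principal_type, []).append(i)
        types = sorted(by_type)
        if M < len(types):
            raise TooManyAnchors(
                f"M={M} < number of principal types {len(types)}")
        pools = {t: list(rng.permutation(by_type[t])) for t in types}
        chosen_idx: list[int] = []
        t = 0
        while len(chosen_idx) < M:
            pool = pools[types[t % len(types)]]
            if pool:
                chosen_idx.append(int(pool.pop()))
            t += 1
            if all(not p for p in pools.values()):
                break
        chosen = [graphs[i] for i in chosen_idx]
    else:
        raise ValueError(f"unknown anchor strategy {strategy!r}")
    return AnchorSet(chosen, strategy=strategy, seed=seed)


def _embed_targets(targets: list[EventGraph], encoders: list[AnchorEncoder],
                   cfg: EncoderConfig, symmetric: bool = False,
                   text_vectors: dict | None = None) -> list[EventEmbedding]:
    rows = []
    for g in targets:
        coords = np.empty(len(encoders))
        g_enc = train_anchor_encoder(g, cfg) if symmetric else None
        for j, enc in enumerate(encoders):
            _, rec = score_pair(g, enc, cfg, text_vectors=text_vectors)
            if symmetric:
                _, rec_rev = score_pair(enc.graph, g_enc, cfg,
                                        text_vectors=text_vectors)
                coords[j] = symmetric_divergence(rec.rectified,
                                                 rec_rev.rectified)
            else:
                coords[j] = rec.rectified
        rows.append(EventEmbedding(coords, g.doc_id))
    return rows


def embed_all(targets: list[EventGraph], anchors: AnchorSet,
              cfg: EncoderConfig, symmetric: bool = False) -> EmbeddingMatrix:
    """Train one encoder per anchor, then score every target against every
    anchor. Coordinates are rectified (asymmetric) divergences by default;
    ``symmetric=True`` uses the symmetrized variant (twice the work)."""
    texts = [n.text for g in targets for n in g.nodes]
    for a in anchors.anchor_graphs:
        texts.extend(n.text for n in a.nodes)
    text_vectors = embed_texts(texts, h=cfg.text_h, seed=cfg.seed)
    encoders = [train_anchor_encoder(a, cfg) for a in anchors.anchor_graphs]
    rows = _embed_targets(targets, encoders, cfg, symmetric=symmetric,
                          text_vectors=text_vectors)
    return EmbeddingMatrix(rows, anchors, cfg, encoders=encoders,
                           symmetric=symmetric)


def kernel_value(psi1: EventEmbedding | np.ndarray,
                 psi2: EventEmbedding | np.ndarray,
                 squared: bool = False) -> float:
    """Euclidean distance between two embeddings (optionally squared)."""
    v1 = psi1.vector if isinstance(psi1, EventEmbedding) else np.asarray(psi1)
    v2 = psi2.vector if isinstance(psi2, EventEmbedding) else np.asarray(psi2)
    if v1.shape != v2.shape:
        raise ShapeMismatch(f"{v1.shape} vs {v2.shape}")
    d2 = float(((v1 - v2) ** 2).sum())
    return d2 if squared else float(np.sqrt(d2))


def _cfg_hash(cfg: EncoderConfig) -> str:
    return hashlib.blake2b(repr(cfg.fingerprint()).encode(),
                           digest_size=8).hexdigest()


def write_embeddings(matrix: EmbeddingMatrix, tsv_path, sidecar_path=None) -> None:
    """TSV with a header row of anchor ids and one row per target, plus a
    JSON sidecar recording strategy, seed, and config hash."""
    anchor_ids = [a.doc_id or f"anchor{i}"
                  for i, a in enumerate(matrix.anchor_set.anchor_graphs)]
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("target_id\t" + "\t".join(anchor_ids) + "\n")
        for row in matrix.rows:
            fh.write(row.target_id + "\t"
                     + "\t".join(f"{v:.10g}" for v in row.vector) + "\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump({"strategy": matrix.anchor_set.strategy,
                       "seed": matrix.anchor_set.seed,
                       "M": matrix.anchor_set.M,
                       "symmetric": matrix.symmetric,
                       "config_hash": _cfg_hash(matrix.config)}, fh, indent=1)


def write_attention(pair, path) -> None:
    """Export forward attention weights as TSV (target_node, anchor_node,
    probability) for heatmap inspection."""
    probs = pair.forward_probs()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("target_node\tanchor_node\tprobability\n")
        for i, tn in enumerate(pair.target.nodes):
            for j, an in enumerate(pair.anchor.nodes):
                fh.write(f"{tn.node_id}\t{an.node_id}\t{probs[i, j]:.8f}\n")
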