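"""Anchor encoders, cross-graph attention, and divergence scores.

The similarity between two event graphs is measured in two phases:

1. A *Node-to-Edges encoder* is trained on the anchor graph alone: each
   node's one-hot identity is mapped through a linear embedding (width d)
   and a small fully-connected network to per-node sigmoid scores that
   predict the node's successors (multi-label classification against the
   adjacency row). Its parameters are then frozen.

2. For a (target, anchor) pair, two attention networks are trained around
   the frozen encoder: a forward network softly aligning each target node
   to anchor nodes (row softmax), and a reverse network mapping the
   encoder's predicted anchor neighborhood back to target nodes
   (independent sigmoids). Training minimizes the structural negative
   log-likelihood of the target's adjacency under this composition, plus
   attribute-consistency regularizers for node types, edge roles, and node
   text (cosine distance between span embeddings), each weighted by its
   loss coefficient. The same regularizers are attached to the reverse
   network using neighborhood-level attribute distributions (node labels of
   successors, edge roles within 2 hops).

The divergence of a target from an anchor is the summed negative log
probability of the target's edges under the wrapped encoder, rectified by
subtracting the anchor's self-score so that D(A||A) = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ShapeMismatch, TrainingDiverged, UnknownNode, ZeroVector
from .graphs import EventGraph, adjacency, content_key
from .spans import embed_texts

logger = logging.getLogger(__name__)

__all__ = [
    "EncoderConfig", "AnchorEncoder", "AttentionPair", "DivergenceRecord",
    "train_anchor_encoder", "forward_attention", "reverse_attention",
    "node_type_posterior", "node_type_loss", "edge_type_distribution",
    "text_consistency_loss", "raw_divergence", "rectified_divergence",
    "symmetric_divergence", "score_pair",
]


@dataclass
class EncoderConfig:
    """Hyperparameters shared by the encoder and attention training.

    Defaults follow the documented profile: 4 embedding dimensions, 3
    hidden layers, 300 encoding and scoring epochs, learning rate 0.1, and
    loss coefficients (7, 7, 7) for the text / node-type / edge-type
    consistency terms.
    """

    node_embed_dim: int = 4          # d
    hidden_layers: int = 3           # k
    learning_rate: float = 0.1
    encoding_epochs: int = 300
    scoring_epochs: int = 300
    loss_coefficients: tuple[float, float, float] = (7.0, 7.0, 7.0)
    seed: int = 0
    prob_clamp: float = 1e-7         # epsilon inside logs
    text_h: int = 16                 # fallback span-embedder sub-word width
    undirected_neighbors: bool = False

    def __post_init__(self):
        if self.node_embed_dim < 2:
            raise ValueError("node_embed_dim must be >= 2")
        if self.hidden_layers < 1:
            raise ValueError("hidden_layers must be >= 1")
        if not (0.0 < self.prob_clamp <= 0.01):
            raise ValueError("prob_clamp must lie in (0, 0.01]")
        if len(tuple(self.loss_coefficients)) != 3:
            raise ValueError("loss_coefficients must have exactly 3 entries")

    def fingerprint(self) -> tuple:
        return (self.node_embed_dim, self.hidden_layers, self.learning_rate,
                self.encoding_epochs, self.scoring_epochs,
                tuple(self.loss_coefficients), self.seed, self.prob_clamp,
                self.text_h, self.undirected_neighbors)


def _target_adjacency(g: EventGraph, undirected: bool) -> np.ndarray:
    a = adjacency(g).astype(np.float64)
    if undirected:
        a = np.clip(a + a.T, 0.0, 1.0)
    return a


class AnchorEncoder:
    """Frozen Node-to-Edges predictor for one anchor graph."""

    def __init__(self, graph: EventGraph, cfg: EncoderConfig):
        self.graph = graph
        self.cfg = cfg
        n, d = graph.n_nodes, cfg.node_embed_dim
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, content_key(graph), 17]))
        self.embed = nn.parameter(rng.normal(0.0, 0.1, size=(n, d)))
        self.hidden = [(nn.parameter(rng.normal(0.0, 0.1, size=(d, d))),
                        nn.parameter(np.zeros(d)))
                       for _ in range(cfg.hidden_layers)]
        self.out_w = nn.parameter(rng.normal(0.0, 0.1, size=(d, n)))
        self.out_b = nn.parameter(np.zeros(n))
        self.loss_history: list[float] = []
        self.frozen = False
        self._self_terms: dict[tuple, float] = {}

    # -- parameters ------------------------------------------------------
    def parameters(self) -> list[nn.Tensor]:
        ps = [self.embed, self.out_w, self.out_b]
        for w, b in self.hidden:
            ps.extend([w, b])
        return ps

    def freeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = False
        self.frozen = True

    # -- forward passes --------------------------------------------------
    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """Rows of x are (soft) one-hot node encodings; returns sigmoid
        neighbor scores, one row per input row."""
        h = x @ self.embed
        for w, b in self.hidden:
            h = (h @ w + b).leaky_relu(0.1)
        return (h @ self.out_w + self.out_b).sigmoid()

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        h = x @ self.embed.data
        for w, b in self.hidden:
            z = h @ w.data + b.data
            h = np.where(z > 0, z, 0.1 * z)
        z = h @ self.out_w.data + self.out_b.data
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def edge_probability(self, source_id: str, target_id: str) -> float:
        """Pr(target | source) under the trained encoder."""
        x = np.zeros((1, self.graph.n_nodes))
        x[0, self.graph.index_of(source_id)] = 1.0
        return float(self.forward_np(x)[0, self.graph.index_of(target_id)])

    # -- self divergence (cached) ---------------------------------------
    def self_term(self, cfg: EncoderConfig,
                  text_vectors: dict[str, np.ndarray] | None = None) -> float:
        key = cfg.fingerprint()
        if key not in self._self_terms:
            _, record = score_pair(self.graph, self, cfg,
                                   text_vectors=text_vectors,
                                   _compute_self=False)
            self._self_terms[key] = record.raw
        return self._self_terms[key]


def train_anchor_encoder(g: EventGraph, cfg: EncoderConfig) -> AnchorEncoder:
    """Phase 1: train the Node-to-Edges encoder on the anchor graph.

    Each node's output row is trained against its adjacency row with
    binary cross-entropy (the multi-label likelihood whose positive part
    is the summed log-probability of the graph's edges). Deterministic
    for a fixed config seed.
    """
    if g.n_nodes < 2:
        raise ValueError("anchor graph needs at least 2 nodes")
    enc = AnchorEncoder(g, cfg)
    a = _target_adjacency(g, cfg.undirected_neighbors)
    pos = nn.constant(a)
    neg = nn.constant(1.0 - a)
    eye = nn.constant(np.eye(g.n_nodes))
    opt = nn.Adam(enc.parameters(), lr=cfg.learning_rate)
    eps = cfg.prob_clamp
    for _ in range(cfg.encoding_epochs):
        p = enc.forward(eye).clamp(eps, 1.0 - eps)
        loss = -((pos * p.log()).sum() + (neg * (1.0 - p).log()).sum())
        value = loss.item()
        if not np.isfinite(value):
            raise TrainingDiverged("anchor encoder loss is non-finite")
        enc.loss_history.append(value)
        opt.zero_grad()
        loss.backward()
        opt.step()
    enc.freeze()
    return enc


class AttentionPair:
    """Forward and reverse alignment networks for one (target, anchor) pair.

    The forward network holds one logit row per target node, softmaxed over
    anchor nodes; the reverse network is an affine map from the encoder's
    anchor score vector to per-target-node logits, squashed independently.
    Both are zero-initialized: untrained forward attention is uniform and
    untrained reverse outputs are 0.5.
    """

    def __init__(self, target: EventGraph, anchor: EventGraph):
        self.target = target
        self.anchor = anchor
        nt, na = target.n_nodes, anchor.n_nodes
        self.fwd_logits = nn.parameter(np.zeros((nt, na)))
        self.rev_w = nn.parameter(np.zeros((na, nt)))
        self.rev_b = nn.parameter(np.zeros(nt))

    def parameters(self) -> list[nn.Tensor]:
        return [self.fwd_logits, self.rev_w, self.rev_b]

    def forward_probs(self) -> np.ndarray:
        """|V_T| x |V_A| attention matrix (rows sum to 1)."""
        z = self.fwd_logits.data - self.fwd_logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def reverse_probs(self, anchor_scores: np.ndarray) -> np.ndarray:
        z = anchor_scores @ self.rev_w.data + self.rev_b.data
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def forward_attention(t, pair: AttentionPair) -> np.ndarray:
    """Attention distribution over anchor nodes for target node ``t``
    (a node id or node index)."""
    if isinstance(t, str):
        if t not in {n.node_id for n in pair.target.nodes}:
            raise UnknownNode(t)
        t = pair.target.index_of(t)
    elif not 0 <= t < pair.target.n_nodes:
        raise UnknownNode(str(t))
    return pair.forward_probs()[t]


def reverse_attention(anchor_scores: np.ndarray, pair: AttentionPair) -> np.ndarray:
    """Per-target-node probabilities given a vector of anchor node scores."""
    anchor_scores = np.asarray(anchor_scores, dtype=np.float64)
    if anchor_scores.shape[-1] != pair.anchor.n_nodes:
        raise ShapeMismatch(
            f"score width {anchor_scores.shape[-1]} != |V_A| {pair.anchor.n_nodes}")
    return pair.reverse_probs(anchor_scores)


# -- attribute distributions and losses ---------------------------------

def _label_index(labels) -> dict[str, int]:
    return {lab: i for i, lab in enumerate(dict.fromkeys(labels))}


def _onehot_labels(types: list[str], index: dict[str, int]) -> np.ndarray:
    m = np.zeros((len(types), len(index)))
    for i, t in enumerate(types):
        if t in index:
            m[i, index[t]] = 1.0
    return m


def node_type_posterior(t, pair: AttentionPair,
                        anchor: EventGraph | None = None) -> dict[str, float]:
    """Q(y|t): attention-weighted anchor node-type distribution for target
    node ``t``. Sums to 1 over the anchor's labels."""
    anchor = anchor or pair.anchor
    attn = forward_attention(t, pair)
    out: dict[str, float] = {}
    for k, node in enumerate(anchor.nodes):
        out[node.type_label] = out.get(node.type_label, 0.0) + float(attn[k])
    return out


def node_type_loss(P: np.ndarray, Q: np.ndarray, eps: float = 1e-7) -> float:
    """Average cross-entropy between observed label distributions P and
    attention-inferred posteriors Q (rows = nodes, columns = labels)."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.clip(np.asarray(Q, dtype=np.float64), eps, 1.0)
    if P.shape != Q.shape:
        raise ShapeMismatch(f"{P.shape} vs {Q.shape}")
    return float(-(P * np.log(Q)).sum(axis=-1).mean())


def edge_type_distribution(node_id: str, g: EventGraph) -> dict[str, float]:
    """Normalized role counts over the edges incident to a node (either
    direction). An isolated node yields an empty distribution."""
    incident = g.incident_edges(node_id)
    if not incident:
        logger.warning("node %s is isolated; excluded from the edge-type loss",
                       node_id)
        return {}
    out: dict[str, float] = {}
    for e in incident:
        out[e.role_label] = out.get(e.role_label, 0.0) + 1.0
    return {r: c / len(incident) for r, c in out.items()}


def _incident_role_matrix(g: EventGraph, index: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """(per-node normalized incident role histogram, mask of non-isolated)."""
    m = np.zeros((g.n_nodes, len(index)))
    for e in g.edges:
        for nid in (e.source, e.target):
            m[g.index_of(nid), index[e.role_label]] += 1.0
    counts = m.sum(axis=1, keepdims=True)
    mask = (counts[:, 0] > 0).astype(np.float64)
    np.divide(m, counts, out=m, where=counts > 0)
    return m, mask


def _two_hop_role_matrix(g: EventGraph, index: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Role histogram of edges within 2 hops of each node (edges touching
    the node or an undirected neighbor)."""
    a = adjacency(g)
    und = ((a + a.T) > 0)
    m = np.zeros((g.n_nodes, len(index)))
    for v in range(g.n_nodes):
        ball = {v} | {u for u in range(g.n_nodes) if und[v, u]}
        for e in g.edges:
            if g.index_of(e.source) in ball or g.index_of(e.target) in ball:
                m[v, index[e.role_label]] += 1.0
    counts = m.sum(axis=1, keepdims=True)
    mask = (counts[:, 0] > 0).astype(np.float64)
    np.divide(m, counts, out=m, where=counts > 0)
    return m, mask


def _successor_label_matrix(g: EventGraph, index: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Normalized node-type histogram of each node's successors."""
    m = np.zeros((g.n_nodes, len(index)))
    for e in g.edges:
        m[g.index_of(e.source), index[g.node(e.target).type_label]] += 1.0
    counts = m.sum(axis=1, keepdims=True)
    mask = (counts[:, 0] > 0).astype(np.float64)
    np.divide(m, counts, out=m, where=counts > 0)
    return m, mask


def _text_matrix(g: EventGraph, vectors: dict[str, np.ndarray]) -> np.ndarray:
    rows = []
    for n in g.nodes:
        v = np.asarray(vectors[n.text], dtype=np.float64)
        if np.linalg.norm(v) == 0.0:
            raise ZeroVector(f"zero-norm text vector for node {n.node_id}")
        rows.append(v)
    return np.vstack(rows)


def _cosine_distance_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xn = x / np.linalg.norm(x, axis=1, keepdims=True)
    yn = y / np.linalg.norm(y, axis=1, keepdims=True)
    return 1.0 - xn @ yn.T


def text_consistency_loss(target: EventGraph, anchor: EventGraph,
                          attn: np.ndarray,
                          vectors: dict[str, np.ndarray]) -> float:
    """Attention-weighted mean cosine distance between target and anchor
    node text embeddings: (1/(|V_T||V_A|)) sum_j sum_i d(t_j, a_i) Pr(a_i|t_j)."""
    attn = np.asarray(attn, dtype=np.float64)
    if attn.shape != (target.n_nodes, anchor.n_nodes):
        raise ShapeMismatch(f"attention shape {attn.shape}")
    c = _cosine_distance_matrix(_text_matrix(target, vectors),
                                _text_matrix(anchor, vectors))
    return float((c * attn).sum() / (target.n_nodes * anchor.n_nodes))


# -- divergence ----------------------------------------------------------

@dataclass
class DivergenceRecord:
    """Divergence of one target graph from one anchor, with loss traces."""

    raw: float                      # D'(T||A): -log prob summed over edges
    self_term: float                # D'(A||A) under the same protocol
    rectified: float                # raw - self_term (may be negative)
    symmetric: float | None = None  # rectified(T||A) + rectified(A||T)
    traces: dict = field(default_factory=dict)


def raw_divergence(target: EventGraph, encoder: AnchorEncoder,
                   pair: AttentionPair, eps: float = 1e-7) -> float:
    """Sum over directed target edges of -log Pr(v_j | v_i, H_A), where the
    probability composes forward attention, the frozen anchor encoder, and
    reverse attention. Natural log, probabilities clamped to [eps, 1]."""
    attn = pair.forward_probs()                       # |V_T| x |V_A|
    scores = encoder.forward_np(attn)                 # |V_T| x |V_A|
    probs = pair.reverse_probs(scores)                # |V_T| x |V_T|
    total = 0.0
    for e in target.edges:
        p = probs[target.index_of(e.source), target.index_of(e.target)]
        total += -np.log(np.clip(p, eps, 1.0))
    return float(total)


def rectified_divergence(raw: float, self_term: float) -> float:
    """D(T||A) = D'(T||A) - D'(A||A); not floored at zero."""
    value = raw - self_term
    if value < 0:
        logger.debug("negative rectified divergence %.6f", value)
    return value


def symmetric_divergence(d_ta: float, d_at: float) -> float:
    """D(A,T) = D(A||T) + D(T||A)."""
    return d_ta + d_at


def score_pair(target: EventGraph, encoder: AnchorEncoder, cfg: EncoderConfig,
               text_vectors: dict[str, np.ndarray] | None = None,
               _compute_self: bool = True) -> tuple[AttentionPair, DivergenceRecord]:
    """Phase 2: train the attention pair against a frozen anchor encoder and
    return the final divergences.

    The loss is the structural negative log-likelihood of the target's
    adjacency under the wrapped encoder plus the weighted attribute
    consistency terms (text, node type, edge type), mirrored onto the
    reverse network through neighborhood-level distributions.
    """
    if not encoder.frozen:
        raise ValueError("anchor encoder must be trained and frozen first")
    anchor = encoder.graph
    if text_vectors is None:
        texts = [n.text for n in target.nodes] + [n.text for n in anchor.nodes]
        text_vectors = embed_texts(texts, h=cfg.text_h, seed=cfg.seed)
    lam_text, lam_ntype, lam_etype = cfg.loss_coefficients
    eps = cfg.prob_clamp

    pair = AttentionPair(target, anchor)
    a_t = nn.constant(_target_adjacency(target, False))
    neg_t = nn.constant(1.0 - a_t.data)

    # constant attribute structures
    labels = _label_index([n.type_label for n in target.nodes]
                          + [n.type_label for n in anchor.nodes])
    roles = _label_index([e.role_label for e in target.edges]
                         + [e.role_label for e in anchor.edges])
    p_nt = _onehot_labels([n.type_label for n in target.nodes], labels)
    m_anchor_nt = nn.constant(_onehot_labels(
        [n.type_label for n in anchor.nodes], labels))
    p_et, et_mask = _incident_role_matrix(target, roles)
    m_anchor_et, _ = _incident_role_matrix(anchor, roles)
    m_anchor_et = nn.constant(m_anchor_et)
    cos_f = nn.constant(_cosine_distance_matrix(
        _text_matrix(target, text_vectors), _text_matrix(anchor, text_vectors)))

    # reverse-side (anchor -> target) neighborhood structures
    anchor_eye = np.eye(anchor.n_nodes)
    anchor_scores = nn.constant(encoder.forward_np(anchor_eye))
    p_rev_nt, rev_nt_mask = _successor_label_matrix(anchor, labels)
    p_rev_et, rev_et_mask = _two_hop_role_matrix(anchor, roles)
    t_nt = nn.constant(_onehot_labels([n.type_label for n in target.nodes], labels))
    t_et2, _ = _two_hop_role_matrix(target, roles)
    t_et2 = nn.constant(t_et2)
    # mean successor text embedding per anchor node (leaves masked out)
    succ_w = _target_adjacency(anchor, False)
    succ_counts = succ_w.sum(axis=1, keepdims=True)
    np.divide(succ_w, succ_counts, out=succ_w, where=succ_counts > 0)
    anchor_txt = _text_matrix(anchor, text_vectors)
    nbhd_txt = succ_w @ anchor_txt
    nbhd_mask = (succ_counts[:, 0] > 0)
    safe_nbhd = np.where(np.linalg.norm(nbhd_txt, axis=1, keepdims=True) > 0,
                         nbhd_txt, 1.0)
    cos_rev = _cosine_distance_matrix(safe_nbhd, _text_matrix(target, text_vectors))
    cos_rev[~nbhd_mask] = 0.0
    cos_r = nn.constant(cos_rev)

    nt_count = max(1.0, p_nt.sum())          # nodes with a label (= |V_T|)
    et_count = max(1.0, et_mask.sum())
    rev_nt_count = max(1.0, rev_nt_mask.sum())
    rev_et_count = max(1.0, rev_et_mask.sum())
    p_nt_c = nn.constant(p_nt)
    p_et_c = nn.constant(p_et * et_mask[:, None])
    p_rev_nt_c = nn.constant(p_rev_nt * rev_nt_mask[:, None])
    p_rev_et_c = nn.constant(p_rev_et * rev_et_mask[:, None])

    opt = nn.Adam(pair.parameters(), lr=cfg.learning_rate)
    traces: dict[str, float] = {}
    for epoch in range(cfg.scoring_epochs):
        attn = pair.fwd_logits.softmax(axis=1)               # |V_T| x |V_A|
        scores = encoder.forward(attn)                       # |V_T| x |V_A|
        probs = (scores @ pair.rev_w + pair.rev_b).sigmoid().clamp(eps, 1.0 - eps)
        structural = -((a_t * probs.log()).sum()
                       + (neg_t * (1.0 - probs).log()).sum())

        q_nt = (attn @ m_anchor_nt).clamp(eps, 1.0)
        l_nt_f = -(p_nt_c * q_nt.log()).sum() / nt_count
        q_et = (attn @ m_anchor_et).clamp(eps, 1.0)
        l_et_f = -(p_et_c * q_et.log()).sum() / et_count
        l_tx_f = (cos_f * attn).sum() / float(target.n_nodes * anchor.n_nodes)

        rev = (anchor_scores @ pair.rev_w + pair.rev_b).sigmoid()  # |V_A| x |V_T|
        w = rev / rev.sum(axis=1, keepdims=True).clamp(eps, np.inf)
        q_rev_nt = (w @ t_nt).clamp(eps, 1.0)
        l_nt_r = -(p_rev_nt_c * q_rev_nt.log()).sum() / rev_nt_count
        q_rev_et = (w @ t_et2).clamp(eps, 1.0)
        l_et_r = -(p_rev_et_c * q_rev_et.log()).sum() / rev_et_count
        l_tx_r = (cos_r * w).sum() / float(anchor.n_nodes * target.n_nodes)

        loss = (structural
                + lam_text * (l_tx_f + l_tx_r)
                + lam_ntype * (l_nt_f + l_nt_r)
                + lam_etype * (l_et_f + l_et_r))
        value = loss.item()
        if not np.isfinite(value):
            raise TrainingDiverged(
                f"attention loss non-finite at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if epoch == cfg.scoring_epochs - 1:
            traces = {
                "total_loss": value,
                "structural_nll": structural.item(),
                "l_text_forward": l_tx_f.item(),
                "l_text_reverse": l_tx_r.item(),
                "l_ntype_forward": l_nt_f.item(),
                "l_ntype_reverse": l_nt_r.item(),
                "l_etype_forward": l_et_f.item(),
                "l_etype_reverse": l_et_r.item(),
            }

    raw = raw_divergence(target, encoder, pair, eps=eps)
    traces["raw"] = raw
    if _compute_self:
        self_term = encoder.self_term(cfg, text_vectors=None)
        record = DivergenceRecord(raw=raw, self_term=self_term,
                                  rectified=rectified_divergence(raw, self_term),
                                  traces=traces)
    else:
        record = DivergenceRecord(raw=raw, self_term=raw, rectified=0.0,
                                  traces=traces)
    return pair, record
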