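# Methods

## The event-graph model

An event graph `G = (V, E)` is a rooted, directed, unweighted, acyclic
graph. Nodes are *triggers* (textual anchors of events) or *entities*;
only triggers have outgoing edges. Every node carries a categorical type
`τv(v)` and a free-text attribute `γv(v)`; every edge carries an argument
role `τe(e)`. Nested events are realized as trigger–trigger edges, and the
root is the unique trigger with in-degree 0 from which all nodes are
reachable. Node order is fixed at construction (root first, then
breadth-first following edge order) so one-hot indices are reproducible
across serialization. Character offsets follow the standoff convention:
0-based, half-open `[start, end)`. Parallel edges between the same ordered
node pair are rejected (the adjacency matrix is binary); when a corpus
produces one, the first role wins and a warning is logged.

## Anchor encoder (phase 1)

For an anchor graph with `n` nodes, the Node-to-Edges encoder maps a
one-hot node encoding through a linear embedding `E ∈ R^{n×d}`, `k` fully
connected layers of width `d` with leaky-ReLU activations (slope 0.1), and
an output layer of width `n` with per-node sigmoids. The stated objective
is the summed log-probability of the graph's edges; taken alone this is
degenerate (every sigmoid can be driven to 1), so, consistent with its
framing as multi-label classification, each node's output row is trained
against its adjacency row with full binary cross-entropy — edges are
positives, non-edges negatives. The positive part of this likelihood is
exactly the quantity the divergence later reads off.

Two numerical choices matter here and were made after observing failure
modes on minimal graphs:

- **Leaky ReLU rather than tanh or ReLU.** Under Adam's sign-like per
  coordinate steps, tanh layers can saturate while the two embedding rows
  of a 2-node graph are still nearly collinear, collapsing the encoder to
  an input-independent marginal predictor; plain ReLU can die outright on
  small widths. Leaky units keep a gradient everywhere; across the default
  schema's graphs the final training BCE is ≤ 0.01 for every graph and
  seed we test.
- **Initialization** is Gaussian (scale 0.1) from a seed derived from the
  config seed and a stable content hash of the graph's canonical JSON, so
  training is bitwise reproducible and byte-identical graphs share
  trajectories.

## Cross-graph attention and scoring (phase 2)

The forward network holds one logit row per target node, softmaxed over
anchor nodes (1:N); the reverse network is an affine map from the
encoder's `|V_A|`-dimensional sigmoid score vector to per-target-node
logits with independent sigmoids (N:N). Both are zero-initialized:
untrained forward attention is uniform and untrained reverse outputs are
exactly 0.5, which gives the closed-form baseline divergence `m·ln 2` for
an `m`-edge target. The reverse network's input representation for "the
neighborhood of anchor node `a_i`" is the encoder's full score vector —
the encoder's own prediction of `N(a_i)` — rather than a hand-built
indicator, keeping phase 2 end-to-end differentiable.

The training loss for a (target, anchor) pair is

```
L = NLL_struct + λ_γv (L_text^fwd + L_text^rev)
              + λ_τv (L_ntype^fwd + L_ntype^rev)
              + λ_τe (L_etype^fwd + L_etype^rev)
```

where `NLL_struct` is the binary cross-entropy of the target adjacency
under the attention-wrapped encoder, and the regularizers are:

- **Node types (forward):** the attention-inferred label posterior
  `Q(y|t) = Σ_k 1[τv(a_k)=y] Pr(a_k|t)` against the target node's one-hot
  label, as average cross-entropy. The printed form of this loss lacks a
  minus sign; it is implemented as standard nonnegative cross-entropy.
- **Edge roles (forward):** same construction with each node's normalized
  incident-role histogram (a node with incident roles {Theme, Theme,
  Cause} has Theme mass 2/3). Isolated nodes contribute nothing and are
  logged; in valid connected graphs they cannot occur.
- **Node text (forward):** attention-weighted mean cosine distance between
  span embeddings, normalized by `|V_T|·|V_A|` exactly as specified. Since
  attention rows already sum to 1, this carries an extra `1/|V_A|` factor
  relative to a plain mean — it is kept as printed, and the analytic value
  `1/|V_A|` when all pairwise distances are 1 is frozen in the tests.
- **Reverse-side mirrors:** alignment weights are the row-normalized
  reverse outputs for each anchor node's predicted neighborhood; the
  reference distributions are neighborhood-level — the anchor node's
  successor-type histogram for node types, and the role histogram of edges
  within 2 hops (undirected) for edge roles; the text mirror uses the mean
  embedding of the anchor node's successors. Anchor nodes without
  successors are masked out of the corresponding terms.

Optimization is Adam (lr 0.1 by default) for both phases; probabilities
inside logarithms are clamped to `[1e-7, 1]`; logarithms are natural.
Phase 2 contains no randomness (zero init, full batch), so scoring is
deterministic given the trained encoder.

## Divergence, rectification, embedding

`D′(G_T‖G_A)` sums `−log` of the composed edge probabilities over the
target's directed edges. Because the encoder is not a perfect predictor
even of its own graph, the anchor's self-score `D′(G_A‖G_A)` — computed
with the identical protocol and seeds — is subtracted, making the
self-divergence exactly zero and the divergence of a byte-identical copy
zero to machine precision. Rectified divergences are *not* floored:
targets with fewer edges than the anchor can legitimately score below the
self-term, and the sign is informative. For retrieval across differently
sized graphs the symmetric form `D(G_A,G_T) = D(G_A‖G_T) + D(G_T‖G_A)`
compensates the edge-count asymmetry and is the quantity used in the
variant-recovery experiment.

The embedding stacks rectified divergences to the `M` anchors; the kernel
is the (unsquared) Euclidean distance between embeddings, with a flag for
the squared variant. Anchors default to being drawn from the target
population itself (overlapping sets); new targets are embedded against the
frozen encoders without touching existing rows, so the cost of extending a
population is `M` scoring runs, and total training cost scales as `N×M`.

## Span embeddings

`emb(text)` is the concatenation `[first sub-word vector ; mean of all
sub-word vectors ; last sub-word vector]` (width `3h`); a one-word span
uses the same word for all three components, applying the formula
literally. The default backend hashes boundary-padded character 3-grams of
each whitespace word into a signed `h`-dimensional unit vector (`h = 16`
by default) — deterministic, download-free, and surface-form sensitive, so
"IL-2" and "IL2" are close while "IL-2" and "tumorigenesis" are not. A
transformer backend can be registered at runtime (the intended production
backend is a biomedical BERT; the last hidden layer supplies sub-word
vectors, grouped by word); embeddings are frozen features either way and
can be cached on disk keyed by (backend, text).

## Synthetic data

The generator emulates what the method assumes about real corpora: rooted
DAGs of 2–6 nodes drawn from three event families (gene expression,
binding, regulation with optional nested phosphorylation), optional
arguments with fixed presence probabilities, heterogeneous node/edge type
vocabularies, and per-type synonym clusters realized as strings sharing a
character stem — so the fallback embedder sees controllable semantic
similarity without any model download. `noise_scale` (default 0.3) selects
among synonyms and occasionally appends a character; at 0 every member of
a cluster receives the canonical string, hence identical text vectors.
Family draws are uniform; `isomorphic_variant` produces a
structure/type-preserving copy with fresh node ids and same-cluster
synonyms, recording the bijection.

What the generator does **not** emulate: real trigger/argument ambiguity,
corpus-specific role inventories (up to 140 node types in real data),
discontinuous trigger spans, event modifiers (negation/speculation — out
of scope entirely), and natural-language surface text. Passing the
recovery and classification tests therefore shows the machinery learns the
intended structural/semantic signal, not that it attains any particular
accuracy on shared-task corpora.

## Reference conditions and problem sizes

The reference experiments (`ddegk.experiments`, also run by
`scripts/acceptance.py`) use 60 graphs, 12 type-balanced anchors, and the
default profile `d = 4`, `k = 3`, 300/300 epochs, lr 0.1, coefficients
(7, 7, 7) — the recommended production setting, under which the semantic
terms jointly outweigh the structural one by roughly 20:1. The
variant-recovery experiment runs 10 probe trials, each comparing one
graph's symmetric divergence to its variant against the median over 5
other-family graphs. These sizes complete in a few minutes on one CPU
while leaving the statistics stable; larger populations only tighten them.

## Known limitations

- Divergence magnitude grows with target edge count; asymmetric
  coordinates are therefore size-confounded (mitigated by rectification
  and, where needed, symmetrization). Downstream classifiers handle this;
  raw thresholds on single coordinates would not.
- The attention networks are single linear maps; alignment granularity is
  node-to-node only.
- Anchor choice is random (optionally type-balanced); no learned anchor
  selection.
- The SVM consumes embedding vectors with standard kernel functions; a
  precomputed kernel from the embedding distance is an alternative reading
  of the evaluation protocol and is not implemented.
- No event modifiers, no extraction from raw text (gold or predicted
  annotations are assumed), and no approximate nearest-neighbor index.
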