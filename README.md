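# ddegk — deep divergence event graph kernels

Biomedical text-mining pipelines extract *events* from the literature:
small typed structures such as "overexpression of Bmi-1 promotes
tumorigenesis", annotated as a trigger word with role-labeled arguments
(Theme, Cause, Site, ...) that may themselves be events. Each event is
naturally a rooted, directed, acyclic, labeled graph of 2–18 nodes whose
nodes also carry free text. Comparing, clustering, and retrieving such
events requires a similarity that respects *both* graph structure and
node/edge semantics — something neither sequence embeddings nor purely
structural graph kernels provide.

`ddegk` implements an unsupervised, inductive whole-graph embedding for
event graphs based on learned divergences from a set of **anchor graphs**:

1. For each anchor graph `G_A`, a **Node-to-Edges encoder** `H_{G_A}` is
   trained to predict each node's successors from its one-hot identity
   (one-hot → linear embedding of width *d* → *k* fully connected layers →
   per-node sigmoid scores), then frozen.
2. For a (target, anchor) pair, two **cross-graph attention** networks are
   trained around the frozen encoder: a forward network assigning every
   target node a softmax distribution over anchor nodes (a relaxed
   isomorphism), and a reverse network mapping the encoder's predicted
   anchor neighborhood back to target nodes (independent sigmoids).
   Training minimizes the structural negative log-likelihood of the
   target's adjacency plus attribute-consistency losses for node types,
   edge roles, and node text (cosine distance between span embeddings),
   weighted by coefficients `(λ_γv, λ_τv, λ_τe)`.
3. The **divergence** is `D′(G_T‖G_A) = Σ_{(i,j)∈E(G_T)} −log Pr(v_j | v_i,
   H_{G_A})`, rectified by the anchor's self-score so `D(G_A‖G_A) = 0`, and
   optionally symmetrized as `D(G_A,G_T) = D(G_A‖G_T) + D(G_T‖G_A)`.
4. Given `M` anchors, the embedding is the divergence vector
   `Ψ(G_T) = [D(G_T‖G_{A_1}), …, D(G_T‖G_{A_M})]` (a distances-to-kernels
   construction), and the kernel/distance between two graphs is
   `‖Ψ(G_1) − Ψ(G_2)‖₂`.

Node text is embedded with the span pooling `[first sub-word ; mean ; last
sub-word]` over a pluggable backend; the default backend is a deterministic
hashed-character-n-gram embedder, so nothing needs to be downloaded. A
transformer backend (e.g. SciBERT) can be plugged in via
`ddegk.spans.register_backend`.

The package reads BioNLP-ST standoff corpora (`.txt`/`.a1`/`.a2`),
performs the usual preprocessing (top-level event extraction with nested
events inlined, removal of event types with fewer than ten instances,
proportional stratified sampling over event type × node-count bin ×
source), and ships a seeded synthetic event-graph generator so the whole
pipeline is testable offline.

## Worked example

`examples/03_score_pair.py` trains an encoder on a 3-node Binding event and
scores three targets against it:

```
anchor: Binding with 3 nodes
  vs itself               rectified D =   0.0000   symmetric D =   0.0000
  vs isomorphic variant   rectified D =  -0.0001   symmetric D =  -0.0000
  vs other family         rectified D =   2.1936   symmetric D =   4.3878

variant->anchor attention (rows: variant nodes, cols: anchor nodes)
[[0.99 0.01 0.01]
 [0.   1.   0.  ]
 [0.   0.   1.  ]]
```

The anchor itself rectifies to exactly zero by construction; an isomorphic
variant with fresh node ids and synonym-substituted texts lands at ~0 and
its attention matrix recovers the hidden node bijection; a different event
family scores far higher. `examples/04_embed_evaluate.py` embeds 24
synthetic graphs against 6 type-balanced anchors and prints

```
SVM family classification: F1 = 1.000 with {'C': 10.0, 'kernel': 'linear'}
K-means best of 10 runs:   SS = 0.601, ARI = 0.210
silhouette on true family labels: 0.113
```

i.e. the divergence coordinates alone separate the three event families.

## Command line

A thin CLI wraps the library:

```bash
ddegk synth --n 60 --seed 7 --out data/
ddegk --config cfg.json embed --in data/graphs.json --anchors 12 \
      --strategy per-type --seed 0 --out emb.tsv
ddegk evaluate --task cluster --embeddings emb.tsv --labels data/labels.tsv
ddegk retrieve --embeddings emb.tsv --query-id synth:0 --topk 5
ddegk visualize --embeddings emb.tsv --seed 0 --out coords.tsv
```

`parse`, `sample`, and `embed-text` cover standoff ingestion, stratified
sampling, and span-vector caching.

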