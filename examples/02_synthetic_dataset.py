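"""Generate a seeded synthetic event-graph dataset and subsample it.

The default schema has three event families (gene expression, binding,
positive regulation with optional nested phosphorylation) whose graphs look
like the small end of real shared-task corpora: 2-6 typed nodes, role-labeled
edges, and surface strings drawn from per-type synonym clusters.
"""

from collections import Counter

from ddegk import TypeVocabulary, generate, stratified_sample, validate_event_graph
from ddegk.standoff import SamplingSpec, node_count_bin
from ddegk.synth import default_schema

schema = default_schema()
graphs, labels = generate(schema, 200, seed=0)
vocab = TypeVocabulary.from_graphs(graphs)

print("family counts:", dict(Counter(labels)))
print("node-count bins:", dict(Counter(node_count_bin(g.n_nodes)
                                       for g in graphs)))
print("all valid:", all(validate_event_graph(g, vocab).ok for g in graphs))

# Proportional stratified sampling over (family, node-count bin), the same
# preprocessing applied to real corpora before embedding.
sample = stratified_sample(graphs, SamplingSpec(target_n=60, seed=1))
print("sampled:", len(sample), "family shares:",
      dict(Counter(g.principal_type for g in sample)))
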