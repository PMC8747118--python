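"""Parse a BioNLP-ST standoff document into event graphs.

A document is a text file plus .a1 (gold entities) and .a2 (triggers and
event frames). The nested event below — a gene expression whose Cause is a
positive-regulation sub-event — becomes a single 4-node rooted DAG.
"""

from ddegk import adjacency, events_to_graphs, parse_standoff

TEXT = "Bmi-1 is overexpressed and promotes tumorigenesis in mice."
A1 = ("T1\tProtein 0 5\tBmi-1\n"
      "T5\tCancer 36 49\ttumorigenesis\n")
A2 = ("T2\tGene_expression 9 22\toverexpressed\n"
      "T3\tPositive_regulation 27 35\tpromotes\n"
      "E1\tGene_expression:T2 Theme:T1 Cause:E2\n"
      "E2\tPositive_regulation:T3 Theme:T5\n")

doc = parse_standoff(TEXT, A1, A2, doc_id="demo")
graphs = events_to_graphs(doc)

for g in graphs:
    print(f"event graph {g.doc_id}: root type {g.principal_type}, "
          f"{g.n_nodes} nodes, {len(g.edges)} edges")
    for e in g.edges:
        src, dst = g.node(e.source), g.node(e.target)
        print(f"  {src.text!r} ({src.type_label}) --{e.role_label}--> "
              f"{dst.text!r} ({dst.type_label})")
    print("adjacency matrix (node order: root first, breadth-first):")
    print(adjacency(g))

# The Cause argument points at another event: it is realized as a
# trigger-trigger edge, so one top-level frame yields one connected DAG.
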