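"""Detect one metabolon in a six-gene toy genome.

Six consecutive genes gA..gF sit on a linear replicon; five reactions
r1..r5 form a chain through shared main compounds. Four genes are annotated
(gA-r1, gC-r2, gD-r3, gF-r5). The un-annotated genes gB and gE and the
annotation-less reaction r4 are recovered as gaps, and each eligible gap
gene is proposed for the gap reaction with a weight alpha/MPL.
"""

import metabolon as mb

genes = [mb.Gene(f"g{c}", "org1", "chr", i) for i, c in enumerate("ABCDEF")]
links = [mb.ReactionLink(f"r{i}", f"r{i+1}", frozenset({f"c{i}"}))
         for i in range(1, 5)]
known = [("gA", "r1"), ("gC", "r2"), ("gD", "r3"), ("gF", "r5")]
data = mb.assemble_data_graph(
    genes, [f"r{i}" for i in range(1, 6)], links,
    [mb.Association("org1", g, r) for g, r in known],
    mb.Config(circular_replicons=False),
)

result = mb.run_pipeline(data)
m = result.metabolons[0]
print(f"metabolon {m.metabolon_id}: genes {m.genes} (gaps {m.gap_genes}), "
      f"reactions {m.reactions} (gaps {m.gap_reactions})")
for a in result.associations:
    print(f"  {a.gene_id} -> {a.reaction_id}  {a.category:<9} "
          f"MPL={a.mpl}  weight={a.weight:.4f}  Sr>g={a.score_r_to_g:.4f}")
print()
print("The two gap genes are proposed for the gap reaction r4; gE wins the")
print("reaction-to-gene ranking because its shortest context path (3 edges:")
print("gE-gF, gF-r5 Known, r5-r4) is shorter than gB's (4 edges).")
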