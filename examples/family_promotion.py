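"""Cross-organism integration: promoting a Potential association to Inferred.

org3 carries four co-localized genes anchored by Known associations to the
ends of the reaction chain r3..r6, leaving gap genes g3D/g3F and gap
reactions r4/r5 — four Potential pairs. In org2, gene g2F (same family F as
g3F) is already Known for r5. That family evidence promotes (g3F, r5) to an
Inferred association; g3F and r5 then stop being gaps, which removes the now
impossible Potentials (g3F, r4) and (g3D, r5) and leaves (g3D, r4) as the
single surviving hypothesis.
"""

import metabolon as mb

genes = [
    mb.Gene("g2E", "org2", "chr", 0, family_id="E"),
    mb.Gene("g2F", "org2", "chr", 1, family_id="F"),
    mb.Gene("g3C", "org3", "chr", 0, family_id="C"),
    mb.Gene("g3D", "org3", "chr", 1, family_id="D"),
    mb.Gene("g3F", "org3", "chr", 2, family_id="F"),
    mb.Gene("g3G", "org3", "chr", 3, family_id="G"),
]
links = [mb.ReactionLink(f"r{i}", f"r{i+1}", frozenset({f"c{i}"}))
         for i in range(3, 6)]
known = [("org2", "g2E", "r4"), ("org2", "g2F", "r5"),
         ("org3", "g3C", "r3"), ("org3", "g3G", "r6")]
data = mb.assemble_data_graph(
    genes, [f"r{i}" for i in range(3, 7)], links,
    [mb.Association(o, g, r) for o, g, r in known],
    mb.Config(circular_replicons=False),
)

result = mb.run_pipeline(data)
print(f"promoted: {[a.key for a in result.promoted]}")
print(f"removed by promotion: {[a.key for a in result.removed_by_promotion]}")
for a in result.associations:
    print(f"  {a.organism_id} {a.gene_id} -> {a.reaction_id}  {a.category:<9} "
          f"MPL={a.mpl}  weight={a.weight:.4f}")
print()
print("Family-level scores after integration:")
for fs in result.family_scores:
    print(f"  family {fs.family_id} -> {fs.reaction_id}: coverage={fs.coverage:.2f} "
          f"S_F>R={fs.score_f_to_r:.4f}  S_R>F={fs.score_r_to_f:.4f}")
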