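# Methods

This note documents the model, the algorithmic and numerical choices, the
synthetic-data generator, and the known limitations of the package. It
states no empirical claim that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Data model and assumptions

The method assumes (i) that functional neighbours cluster on prokaryote
chromosomes, and (ii) that a curated metabolic network with per-pathway
*main compound* annotations is available. Gene adjacency deliberately
ignores strand and intergenic distance — bidirectionally transcribed
operons exist, and the method should not depend on any operon model.
Positions are 0-based ranks along a replicon, not coordinates. Replicons
are treated as circular by default (a wrap-around edge for replicons of
≥ 3 genes), switchable off in `Config(circular_replicons=False)`; the
choice only matters for clusters spanning the origin. Reaction edges are
undirected regardless of reaction reversibility: connectivity is what the
method consumes, not flux direction. Non-enzymatic genes stay in the gene
graph — they can legitimately be spacers or connectivity gaps — but are
never proposed as candidates.

## Metabolon detection

**Closure.** The g-partial transitive closure joins every vertex pair at
original distance ≤ g + 1. Defaults: `g_gene = 3` (multi-gene
transcription units average ~3 genes, and a gap of 3 covers the large
majority of known units even in the worst case), `g_rxn = 2` (most vertex
pairs of a curated global network are within ~2 intermediates). Closure
edges are labelled and are never exported into metabolons: path lengths and
visualisation always operate on original adjacency.

**Partitioning.** Common connected components are computed by alternating
refinement: start from the connected components of the association-bearing
subgraph, then repeatedly split each block by the connected components of
its gene side and then of its reaction side (in the closed graphs) until a
fixed point. The fixed point is the unique coarsest partition into valid
blocks: a block with both sides connected is never split, so every valid
association set ends up inside one final block — the blocks are exactly the
maximal common connected components, and no tie-breaking is needed. The
test suite checks this against exhaustive subset enumeration on 200 random
instances and verifies independence from input order.

**Gap recovery.** For every closure edge used inside a block (anchor pairs
at original distance between 2 and g + 1), the interior vertices of *all*
shortest original-graph paths realising it become gap members. Taking the
union of all shortest paths is deterministic, order-independent, and errs
toward including plausible candidates; it also guarantees both layers are
connected using original edges only. Retention thresholds
(`min_genes = min_rxns = min_known = 2`) anchor every metabolon with at
least two Known associations, which is what keeps the false-positive rate
of downstream proposals manageable.

**Candidate eligibility.** A gap gene is not proposed when it is flagged
non-metabolic (directly or through its family) or when it already holds a
Known association anywhere in its genome — it is then an annotated member
of some other context, not a candidate. Both rules are applied at
Potential-generation time; the gene remains a connectivity gap either way.

## Weighting and scores

MPL is computed by breadth-first search on the metabolon graph (member
genes and reactions, original adjacency edges, Known cross edges; every
edge counts 1). Paths may pass through gap members — they are genuine
metabolon vertices. A Known association's own edge is excluded from its own
MPL, which gives the floors MPL ≥ 2 (Known) and MPL ≥ 3 (Potential). A
(gene, reaction) pair with no path gets no weight and is dropped with a
warning rather than given weight 0, so the normalising denominators of all
scores stay well-defined. Weights are α/MPL with defaults
`alpha_known = alpha_inferred = 1.0`, `alpha_potential = 0.1` — the 10×
ratio encodes that curated annotation outweighs a context hypothesis.

Gene-level scores are computed per organism on the Known + Potential
snapshot, before cross-organism integration (family-level descriptors, by
contrast, see the post-promotion association set — including Inferred, and
excluding what the non-metabolic filter and promotion pruning removed).
Promotions are decided from the pre-promotion Known set only: no chaining
within a pass, so the operation is deterministic and idempotent. Inferred
associations inherit the MPL of the Potential they were promoted from and
are re-weighted with `alpha_inferred`.

Family-less genes are excluded from family-level numerators but contribute
to the Score_R→F denominator: per reaction the family scores then sum to
≤ 1, reaching 1 exactly when every associated gene is family-assigned.
Ranking uses competition ("1, 1, 3") ranks; under the family score,
family-less genes fall back to their gene-level score and rank after every
family-scored gene. Score sums are asserted to 1 within 1e-12 (plain double
accumulation over small groups); output tables print 4 decimals.

## Benchmark

Orphanization removes *all* Known associations of a reaction in every
organism, and the rerun is a full recomputation — only the transitive
closures are shared across runs, which is sound because they depend on the
graphs alone, never on the associations. A tied rank group straddling the
cutoff k counts iff its competition rank is ≤ k. False positives are
proposals matching no removed (organism, gene, reaction) triple, counted —
like true positives — at rank ≤ k, so at k = ∞ both ranking scores report
identical TP and FP (ranking no longer filters). tp + fn equals the number
of genuine associations of eligible reactions, independent of k and score.

## Synthetic corpus

The generator emulates the corpus shape the method targets: 10 reaction
chains (pathways) linked by main compounds; 8 cluster templates, each a
contiguous 4–6-reaction segment of its own chain, instantiated per organism
with probability 0.9 (conservation) as a contiguous run of genes coding the
segment in order, with per-slot families shared across organisms; spacer
genes inserted between cluster genes at rate 0.2; un-annotated background
genes separating clusters by at least `min_separation = 5` genes (> g_gene
+ 1, so metabolons never merge through background); 10% of background/
spacer genes in shared non-metabolic decoy families (giving the
non-metabolic filter real work); 5% family-assignment noise; circular
genomes of 200 genes, 5 organisms. Defaults live in `SimulationParams`;
generation is deterministic given (params, seed), and infeasible packings
are rejected up front.

What the generator does *not* emulate: mis-annotation (all Known
associations are true), genuinely promiscuous hub metabolites, multi-subunit
and bifunctional enzymes at corpus scale, horizontal transfer, and family
mis-clustering beyond random dropout. Passing tests therefore demonstrate
algorithmic correctness and the qualitative value of family integration on
clean, planted structure — not performance on curated real-genome corpora,
where annotation noise and network density lower both recall and precision.

`withhold_orphans` selects interior segment reactions only (never the first
or last, and never two adjacent within a segment), so every withheld
reaction keeps two Known anchors on both layers and its metabolon survives
the retention thresholds; the withheld gene is guaranteed recoverable as a
gap. This is why near-total recovery of withheld associations is a
*construction check*, not a performance claim; the rank-1 fraction under
Score_R→F is the informative number. The full benchmark, by contrast, also
orphanizes segment-edge reactions, whose genes are not recoverable (gaps
only exist *between* anchors) — recall then saturates well below 1,
mirroring the intrinsic flanking-gene limitation of neighbourhood methods.

## Problem sizes

The shipped configuration runs everything at desk scale: the acceptance
script and the test suite use the 5×200-gene corpus (~40 eligible reactions
per benchmark, each a full pipeline rerun) and 200 random instances of ≤ 12
genes / ≤ 10 reactions for the exhaustive-oracle comparison; the whole
suite completes in a few seconds. All stages are linear-ish in corpus size
except brute-force oracles (tests only) and the benchmark (linear in
eligible reactions × pipeline cost).

## Known limitations

* Genes flanking a metabolon are never proposed (gaps are interior by
  construction); candidates outside the anchored span are invisible.
* Processes whose genes are not chromosomally clustered produce no
  metabolon and hence no candidates.
* Families are taken as given; wrong families propagate through promotion
  and family scores. The bundled similarity clustering is single-linkage
  and intended for convenience, not as an orthology method.
* GraphML export writes all metabolons as one disjoint-union graph (the
  format holds one graph per file); per-metabolon graphs are recoverable
  via the `metabolon_id` attributes.
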