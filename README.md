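# metabolon

Genomic metabolon detection and candidate-gene ranking for orphan enzymatic
activities in prokaryote genomes.

Over a quarter of the enzymatic activities recognized by the IUBMB are
*sequence-orphan*: no nucleic or protein sequence is known to encode them,
so similarity-based annotation transfer can never assign them a gene. This
package implements a purely context-based alternative for prokaryotes. It
exploits two observations: genes of a same biological process tend to be
co-localized on prokaryote chromosomes (operons, regulons), and the
reactions they catalyze tend to be adjacent in the metabolic network
(sharing biologically meaningful "main compounds"). Where both patterns
coincide, an un-annotated gene sitting inside such a cluster is a natural
candidate for the cluster's un-assigned reaction — even when that reaction
is a global sequence-orphan. The intended users are genome annotators and
bioanalysts selecting candidate genes for experimental testing.

## The model

The input is a **data graph** with two vertex kinds and three edge kinds:

* **gene graph** — per replicon, immediately consecutive genes are adjacent
  (strand and intergenic distance ignored; circular replicons close the
  cycle);
* **reaction graph** — global (organism-independent); two reactions are
  adjacent when the product of one is a substrate of the other *and* the
  shared metabolite is flagged a main compound of both in at least one
  pathway (hub metabolites like water never qualify);
* **Known associations** — the current gene ↔ reaction annotations of each
  organism.

**Metabolons.** Both layers are first augmented by their *g-partial
transitive closure* (an edge joins every vertex pair separated by ≤ g
intermediates; g = 3 for genes, 2 for reactions), so small annotation holes
do not break contiguity. The Known associations are then partitioned into
maximal **common connected components**: blocks whose gene side and
reaction side are each connected in the closed graphs, every gene linked to
≥ 1 reaction of the block and vice versa. The vertices the closure edges
jumped over are reinstated as **gap genes** and **gap reactions**, and
blocks below the retention thresholds (≥ 2 genes, ≥ 2 reactions, ≥ 2 Known
associations) are discarded. Each surviving block is a *genomic metabolon*.

**Candidates and weights.** Every (eligible gap gene × gap reaction) pair
of a metabolon becomes a **Potential** association (gap genes flagged
non-metabolic, or annotated elsewhere in their genome, are not eligible).
Each association (G, R) is weighted

    w_G,R = α / MPL,   α_known = 1 = 10·α_potential,  α_inferred = α_known

where MPL is the shortest path between G and R inside the metabolon
(gene-gene, reaction-reaction and Known cross edges only; a Known
association's own edge is excluded, so MPL ≥ 2 for Known and ≥ 3 for
Potential associations). Gene-level scores normalise w per gene
(Score_G→R) and per (organism, reaction) (Score_R→G).

**Cross-organism integration.** Genes carry family ids (any orthology
clustering; a naive single-linkage helper is included). Potential
associations of non-metabolic families are dropped; a Potential (g, r) is
promoted to **Inferred** when another member of g's family is Known for r,
de-gapping g and r and pruning the now-impossible Potentials. Family-level
descriptors summarise the evidence: Coverage_F,R (fraction of members
associated), Score_F→R and Score_R→F (the family's share of the reaction's
total weight, across all organisms). Candidates for each (organism,
reaction) are ranked by Score_R→F (default) or Score_R→G, ties sharing the
minimum rank.

**Benchmark.** Each reaction with a Known association inside a metabolon is
orphanized in turn — all of its annotations removed in every organism — and
the pipeline rerun. Pooled TP/FP/FN over rank cutoffs k yield
precision-recall curves per ranking score.

## Worked example

`examples/toy_metabolon.py` builds six consecutive genes gA..gF over a
five-reaction chain r1..r5 with four Known annotations and runs the
pipeline:

```
metabolon M00001: genes ['gA', 'gB', 'gC', 'gD', 'gE', 'gF'] (gaps ['gB', 'gE']), reactions ['r1', 'r2', 'r3', 'r4', 'r5'] (gaps ['r4'])
  gA -> r1  Known     MPL=4  weight=0.2500  Sr>g=1.0000
  gB -> r4  Potential MPL=4  weight=0.0250  Sr>g=0.4286
  gC -> r2  Known     MPL=3  weight=0.3333  Sr>g=1.0000
  gD -> r3  Known     MPL=3  weight=0.3333  Sr>g=1.0000
  gE -> r4  Potential MPL=3  weight=0.0333  Sr>g=0.5714
  gF -> r5  Known     MPL=5  weight=0.2000  Sr>g=1.0000
```

The un-annotated genes gB/gE and the annotation-less reaction r4 come back
as gaps, and both gap genes are proposed for r4. gE ranks first
(Score_R→G = 0.033/0.058 ≈ 0.571): its context path gE–gF, gF–r5 (Known),
r5–r4 has only 3 edges, so it is the topologically closer candidate.

The other examples show Inferred promotion (`family_promotion.py`),
end-to-end orphan recovery on a synthetic corpus
(`simulate_and_recover.py` — 22/22 withheld associations recovered, 95.5%
at rank 1) and the benchmark (`benchmark_curves.py` — the family score
reaches precision 0.948 at k = 1 against 0.539 for the gene-level score).

A thin CLI mirrors the library (`metabolon simulate | run-all |
find-metabolons | score | integrate | rank | benchmark`); see
`metabolon --help`.

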