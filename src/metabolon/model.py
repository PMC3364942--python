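"""Core domain model: genes, reactions, associations and the two-layer data graph.

Genomic context and metabolic context are coupled through a *data graph*
with two vertex kinds and three edge kinds:

* a per-replicon **gene graph** in which immediately consecutive genes are
  adjacent — transcription direction and intergenic distance are deliberately
  ignored, so the model is independent of operon/regulon definitions;
* a global **reaction graph** in which two reactions are adjacent when the
  product of one is a substrate of the other *and* the shared metabolite is a
  "main compound" of both reactions in at least one pathway (hub metabolites
  such as water never qualify, which keeps the network sparse and
  biologically meaningful);
* **Known** gene-reaction associations, i.e. the current state of functional
  annotation of each organism, which tie the two layers together.

Everything downstream (metabolon detection, candidate generation, scoring,
benchmarking) operates on this structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "KNOWN",
    "POTENTIAL",
    "INFERRED",
    "CATEGORIES",
    "Gene",
    "Reaction",
    "ReactionLink",
    "Association",
    "Config",
    "DataGraph",
    "build_gene_graph",
    "build_reaction_graph",
    "reaction_links_from_compounds",
    "assemble_data_graph",
    "classify_orphan_status",
]

#: Association categories. ``Known`` is curated annotation, ``Potential`` is a
#: metabolon-generated hypothesis, ``Inferred`` is a Potential promoted by
#: family-level evidence.
KNOWN = "Known"
POTENTIAL = "Potential"
INFERRED = "Inferred"
CATEGORIES = (KNOWN, POTENTIAL, INFERRED)


@dataclass
class Gene:
    """A protein-coding feature of one replicon of one organism.

    ``position`` is a 0-based rank along the replicon, not a base-pair
    coordinate; positions within a replicon must be unique and consecutive.
    """

    gene_id: str
    organism_id: str
    replicon_id: str
    position: int
    family_id: str | None = None
    non_metabolic: bool = False

    @property
    def key(self) -> tuple[str, str]:
        """Globally unique handle ``(organism_id, gene_id)``."""
        return (self.organism_id, self.gene_id)


@dataclass
class Reaction:
    """A metabolic reaction, identified globally (organism-independent)."""

    reaction_id: str
    label: str | None = None
    ec_number: str | None = None


@dataclass(frozen=True)
class ReactionLink:
    """An undirected reaction-reaction edge justified by shared main compounds."""

    reaction_a: str
    reaction_b: str
    main_compounds: frozenset[str]

    def __post_init__(self) -> None:
        if self.reaction_a == self.reaction_b:
            raise ValueError(f"self-link on reaction {self.reaction_a!r}")
        if not self.main_compounds:
            raise ValueError(
                f"link {self.reaction_a!r}-{self.reaction_b!r} has no main compound"
            )


@dataclass
class Association:
    """A gene-reaction edge, with its category, MPL and weight.

    The weight is ``alpha(category) / MPL`` once the minimal path length has
    been computed inside a metabolon; associations that never enter a retained
    metabolon keep ``mpl = weight = None`` and do not contribute to scores.
    """

    organism_id: str
    gene_id: str
    reaction_id: str
    category: str = KNOWN
    metabolon_id: str | None = None
    mpl: int | None = None
    weight: float | None = None
    score_g_to_r: float | None = None
    score_r_to_g: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown association category {self.category!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.organism_id, self.gene_id, self.reaction_id)


@dataclass
class Config:
    """Tunable parameters of the whole strategy.

    Defaults are the operational values of the method: gene gap 3 (the mean
    multi-gene transcription unit holds ~3.2 genes, and a gap of 3 covers
    >90% of known transcription units even in the worst case), reaction gap
    2 (most reaction pairs of the global network are within 2 intermediates),
    retention thresholds of 2 genes / 2 reactions / 2 Known associations per
    metabolon, and weighting constants alpha_known = 1 = 10 * alpha_potential
    with alpha_inferred = alpha_known.
    """

    g_gene: int = 3
    g_rxn: int = 2
    min_genes: int = 2
    min_rxns: int = 2
    min_known: int = 2
    alpha_known: float = 1.0
    alpha_potential: float = 0.1
    alpha_inferred: float | None = None  # defaults to alpha_known
    circular_replicons: bool = True
    rank_score: str = "r_to_f"

    def __post_init__(self) -> None:
        if self.alpha_inferred is None:
            self.alpha_inferred = self.alpha_known
        if self.g_gene < 0 or self.g_rxn < 0:
            raise ValueError("gap parameters must be >= 0")
        if min(self.min_genes, self.min_rxns, self.min_known) < 1:
            raise ValueError("retention thresholds must be >= 1")
        if min(self.alpha_known, self.alpha_potential, self.alpha_inferred) <= 0:
            raise ValueError("alpha factors must be > 0")
        if self.rank_score not in ("r_to_f", "r_to_g"):
            raise ValueError(
                f"rank_score must be 'r_to_f' or 'r_to_g', got {self.rank_score!r}"
            )

    def alpha(self, category: str) -> float:
        return {
            KNOWN: self.alpha_known,
            POTENTIAL: self.alpha_potential,
            INFERRED: self.alpha_inferred,
        }[category]


def build_gene_graph(genes: Iterable[Gene], circular: bool = True) -> nx.Graph:
    """Build the adjacency graph of one organism's genes.

    Immediately consecutive genes on a replicon are joined; strand and
    intergenic distance are ignored. With ``circular`` (the default, as
    prokaryote chromosomes are typically circular) the last and first genes
    of each replicon with at least 3 genes are also joined.

    Raises ``ValueError`` naming the offending replicon on duplicate or
    non-consecutive positions, and on genes from several organisms.
    """
    genes = list(genes)
    organisms = {g.organism_id for g in genes}
    if len(organisms) > 1:
        raise ValueError(f"genes from multiple organisms: {sorted(organisms)}")
    graph = nx.Graph(organism_id=next(iter(organisms)) if organisms else None)
    by_replicon: dict[str, list[Gene]] = {}
    for g in genes:
        by_replicon.setdefault(g.replicon_id, []).append(g)
    for replicon_id in sorted(by_replicon):
        members = sorted(by_replicon[replicon_id], key=lambda g: g.position)
        positions = [g.position for g in members]
        for p, q in itertools.pairwise(positions):
            if p == q:
                raise ValueError(
                    f"duplicate position {p} on replicon {replicon_id!r}"
                )
            if q != p + 1:
                raise ValueError(
                    f"positions on replicon {replicon_id!r} are not consecutive "
                    f"({p} followed by {q})"
                )
        for g in members:
            graph.add_node(g.gene_id, replicon_id=replicon_id, position=g.position)
        for a, b in itertools.pairwise(members):
            graph.add_edge(a.gene_id, b.gene_id)
        if circular and len(members) >= 3:
            graph.add_edge(members[-1].gene_id, members[0].gene_id)
    return graph


def build_reaction_graph(
    links: Iterable[ReactionLink],
    reactions: Iterable[Reaction | str] | None = None,
) -> nx.Graph:
    """Build the global reaction graph from main-compound links.

    ``reactions``, when given, fixes the vertex set (isolated reactions are
    retained); a link referencing a reaction outside it is rejected. Parallel
    link rows for the same pair are merged, pooling their main compounds.
    """
    graph = nx.Graph()
    known_ids: set[str] | None = None
    if reactions is not None:
        known_ids = set()
        for r in reactions:
            rid = r.reaction_id if isinstance(r, Reaction) else r
            known_ids.add(rid)
            graph.add_node(rid)
    for link in links:
        for rid in (link.reaction_a, link.reaction_b):
            if known_ids is not None and rid not in known_ids:
                raise ValueError(f"link references unknown reaction {rid!r}")
        if graph.has_edge(link.reaction_a, link.reaction_b):
            pooled = graph.edges[link.reaction_a, link.reaction_b]["main_compounds"]
            pooled = frozenset(pooled) | link.main_compounds
        else:
            pooled = link.main_compounds
        graph.add_edge(link.reaction_a, link.reaction_b, main_compounds=pooled)
    return graph


def reaction_links_from_compounds(
    rows: Iterable[tuple[str, str, str, str, bool]],
) -> list[ReactionLink]:
    """Derive reaction links from a reaction x compound table.

    Each row is ``(reaction_id, compound_id, pathway_id, role, is_main)``
    with role ``substrate`` or ``product``. A compound contributes an edge
    between two reactions only where it is flagged main for *both* of them in
    at least one shared pathway, and the product of one is a substrate of the
    other. Side metabolites (is_main false) never create edges, which is what
    keeps currency compounds like water out of the network.
    """
    substrates: dict[tuple[str, str], set[str]] = {}
    products: dict[tuple[str, str], set[str]] = {}
    for reaction_id, compound_id, pathway_id, role, is_main in rows:
        if role not in ("substrate", "product"):
            raise ValueError(f"unknown role {role!r} for reaction {reaction_id!r}")
        if not is_main:
            continue
        bucket = substrates if role == "substrate" else products
        bucket.setdefault((pathway_id, compound_id), set()).add(reaction_id)
    pairs: dict[tuple[str, str], set[str]] = {}
    for (pathway_id, compound_id), prods in products.items():
        subs = substrates.get((pathway_id, compound_id), set())
        for rp in prods:
            for rs in subs:
                if rp == rs:
                    continue
                a, b = sorted((rp, rs))
                pairs.setdefault((a, b), set()).add(compound_id)
    return [
        ReactionLink(a, b, frozenset(compounds))
        for (a, b), compounds in sorted(pairs.items())
    ]


@dataclass
class DataGraph:
    """The assembled multi-organism data graph.

    ``genes`` maps organism -> gene_id -> :class:`Gene`; ``gene_graphs`` holds
    one adjacency graph per organism; the reaction graph is global and shared.
    ``associations`` are the input Known annotations.
    """

    genes: dict[str, dict[str, Gene]]
    gene_graphs: dict[str, nx.Graph]
    reactions: dict[str, Reaction]
    reaction_graph: nx.Graph
    associations: list[Association]
    config: Config = field(default_factory=Config)

    @property
    def organisms(self) -> list[str]:
        return sorted(self.genes)

    def gene(self, organism_id: str, gene_id: str) -> Gene:
        return self.genes[organism_id][gene_id]

    def known_by_organism(self, organism_id: str) -> list[Association]:
        return sorted(
            (a for a in self.associations if a.organism_id == organism_id),
            key=lambda a: a.key,
        )

    def known_gene_keys(self) -> set[tuple[str, str]]:
        """Keys ``(organism, gene)`` of every gene holding any Known association."""
        return {(a.organism_id, a.gene_id) for a in self.associations}

    def without_reaction(self, reaction_id: str) -> "DataGraph":
        """Copy of this data graph with every Known association to
        ``reaction_id`` removed in every organism (orphanization)."""
        return DataGraph(
            genes=self.genes,
            gene_graphs=self.gene_graphs,
            reactions=self.reactions,
            reaction_graph=self.reaction_graph,
            associations=[
                replace(a) for a in self.associations if a.reaction_id != reaction_id
            ],
            config=self.config,
        )


def assemble_data_graph(
    genes: Iterable[Gene],
    reactions: Iterable[Reaction | str],
    links: Iterable[ReactionLink],
    associations: Iterable[Association],
    config: Config | None = None,
) -> DataGraph:
    """Validate the three inputs and assemble the data graph.

    Rejects duplicate gene ids within an organism, dangling association
    endpoints (naming the offending id) and non-Known input associations.
    Multiple reactions per gene (bi-functional enzymes) and multiple genes
    per reaction (multi-subunit enzymes) are allowed.
    """
    config = config or Config()
    gene_index: dict[str, dict[str, Gene]] = {}
    for g in genes:
        org = gene_index.setdefault(g.organism_id, {})
        if g.gene_id in org:
            raise ValueError(
                f"duplicate gene id {g.gene_id!r} in organism {g.organism_id!r}"
            )
        org[g.gene_id] = g
    reaction_index: dict[str, Reaction] = {}
    for r in reactions:
        r = r if isinstance(r, Reaction) else Reaction(r)
        if r.reaction_id in reaction_index:
            raise ValueError(f"duplicate reaction id {r.reaction_id!r}")
        reaction_index[r.reaction_id] = r
    reaction_graph = build_reaction_graph(links, reaction_index.values())
    gene_graphs = {
        org: build_gene_graph(gene_index[org].values(), config.circular_replicons)
        for org in sorted(gene_index)
    }
    assoc_list: list[Association] = []
    seen: set[tuple[str, str, str]] = set()
    for a in associations:
        if a.category != KNOWN:
            raise ValueError(
                f"input association {a.key} has category {a.category!r}; "
                "only Known associations may be loaded"
            )
        if a.organism_id not in gene_index or a.gene_id not in gene_index[a.organism_id]:
            raise ValueError(
                f"association references unknown gene {a.gene_id!r} "
                f"in organism {a.organism_id!r}"
            )
        if a.reaction_id not in reaction_index:
            raise ValueError(
                f"association references unknown reaction {a.reaction_id!r}"
            )
        if a.key in seen:
            raise ValueError(f"duplicate association {a.key}")
        seen.add(a.key)
        assoc_list.append(a)
    assoc_list.sort(key=lambda a: a.key)
    return DataGraph(
        genes=gene_index,
        gene_graphs=gene_graphs,
        reactions=reaction_index,
        reaction_graph=reaction_graph,
        associations=assoc_list,
        config=config,
    )


def classify_orphan_status(
    data: DataGraph, reaction_id: str, organism_id: str
) -> str:
    """Classify a reaction as ``assigned``, ``local_orphan`` or ``global_orphan``.

    A reaction is a global orphan when no loaded organism holds a Known
    association for it, a local orphan when the queried organism holds none
    but some other organism does, and assigned otherwise. Note "global" is
    relative to the loaded corpus, exactly as the status is relative to the
    platform's genomes in production use.
    """
    if reaction_id not in data.reactions:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    holders = {a.organism_id for a in data.associations if a.reaction_id == reaction_id}
    if not holders:
        return "global_orphan"
    if organism_id not in holders:
        return "local_orphan"
    return "assigned"
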