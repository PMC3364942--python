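"""Genomic metabolon detection.

A *genomic metabolon* is a maximal group of co-localized genes whose
products catalyze reactions connected in the global metabolic network.
Detection runs in four steps, per organism:

1. **g-partial transitive closure** of the gene graph (gap parameter
   ``g_gene``) and of the reaction graph (``g_rxn``): an extra edge joins
   every vertex pair separated by at most g intermediate vertices, so that
   un-annotated genes and missing reactions do not break contiguity.
2. **Common connected component (CCC) partitioning** of the Known
   gene-reaction associations: the associations are split into the unique
   coarsest partition such that each block's gene side is connected in the
   closed gene graph and its reaction side is connected in the closed
   reaction graph. Blocks are maximal, and every Known association lies in
   exactly one block.
3. **Gap recovery**: the intermediate genes/reactions that the closure
   edges jumped over are reinstated as *gap* members, so the final metabolon
   is connected using only original adjacency edges.
4. **Filtering**: metabolons below the retention thresholds (minimum genes,
   reactions, Known associations) are discarded.

Gap genes and gap reactions are then paired into Potential gene-reaction
associations — the candidate annotations the whole strategy exists to
produce.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .model import (
    KNOWN,
    POTENTIAL,
    Association,
    Config,
    DataGraph,
    Gene,
)

__all__ = [
    "Metabolon",
    "partial_transitive_closure",
    "partition_cccs",
    "recover_gaps",
    "filter_metabolons",
    "generate_potential",
    "find_metabolons",
]

logger = logging.getLogger(__name__)


@dataclass
class Metabolon:
    """One recovered common connected component with its gap members.

    ``gene_is_gap`` / ``reaction_is_gap`` map member ids to their gap status:
    a gap member has no Known association inside the metabolon and was
    recovered purely to restore contiguity. ``gene_edges`` and
    ``reaction_edges`` are *original* adjacency edges only — closure edges
    are never exported, so path lengths and visualisation operate on real
    adjacency.
    """

    metabolon_id: str
    organism_id: str
    gene_is_gap: dict[str, bool]
    reaction_is_gap: dict[str, bool]
    gene_edges: list[tuple[str, str]]
    reaction_edges: list[tuple[str, str]]
    associations: list[Association] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_is_gap)

    @property
    def reactions(self) -> list[str]:
        return sorted(self.reaction_is_gap)

    @property
    def gap_genes(self) -> list[str]:
        return sorted(g for g, gap in self.gene_is_gap.items() if gap)

    @property
    def gap_reactions(self) -> list[str]:
        return sorted(r for r, gap in self.reaction_is_gap.items() if gap)

    @property
    def known_associations(self) -> list[Association]:
        return [a for a in self.associations if a.category == KNOWN]

    def n_known(self) -> int:
        return len(self.known_associations)


def partial_transitive_closure(graph: nx.Graph, g: int) -> nx.Graph:
    """Return the g-partial transitive closure of ``graph``.

    An edge joins every vertex pair whose original shortest-path distance is
    at most ``g + 1`` (i.e. separated by at most ``g`` intermediate
    vertices). Original edges carry ``closure=False``; added edges carry
    ``closure=True``. ``g = 0`` returns an (attribute-annotated) copy.
    """
    if g < 0:
        raise ValueError("gap parameter must be >= 0")
    closed = nx.Graph()
    closed.add_nodes_from(graph.nodes(data=True))
    for u, v in graph.edges:
        closed.add_edge(u, v, closure=False)
    if g == 0:
        return closed
    for u in graph:
        dists = nx.single_source_shortest_path_length(graph, u, cutoff=g + 1)
        for v, d in dists.items():
            if d >= 2 and not closed.has_edge(u, v):
                closed.add_edge(u, v, closure=True)
    return closed


def partition_cccs(
    associations: Sequence[Association],
    closed_gene_graph: nx.Graph,
    closed_reaction_graph: nx.Graph,
) -> list[list[Association]]:
    """Partition associations into maximal common connected components.

    Alternating refinement: start from the connected components of the
    association-bearing subgraph (gene layer + reaction layer + association
    edges, all on closed graphs), then repeatedly split each block by the
    connected components of its gene side and then of its reaction side,
    until a fixed point. The fixed point is the unique coarsest partition in
    which each block is a valid CCC; any valid set of associations is wholly
    contained in one final block, so blocks are maximal.

    Every input association ends up in exactly one block, and (genes only
    entering through associations) every gene of a block is linked to at
    least one reaction of the block and vice-versa.
    """
    associations = sorted(associations, key=lambda a: a.key)
    if not associations:
        return []
    seed = nx.Graph()
    genes = {a.gene_id for a in associations}
    rxns = {a.reaction_id for a in associations}
    for a in associations:
        seed.add_edge(("g", a.gene_id), ("r", a.reaction_id))
    for u, v in closed_gene_graph.subgraph(genes).edges:
        seed.add_edge(("g", u), ("g", v))
    for u, v in closed_reaction_graph.subgraph(rxns).edges:
        seed.add_edge(("r", u), ("r", v))
    component_of: dict[tuple[str, str], int] = {}
    for i, comp in enumerate(nx.connected_components(seed)):
        for node in comp:
            component_of[node] = i
    blocks: dict[tuple, list[Association]] = {}
    for a in associations:
        blocks.setdefault((component_of[("g", a.gene_id)],), []).append(a)
    work = list(blocks.values())

    def split(block: list[Association], side: str, graph: nx.Graph):
        ids = {a.gene_id if side == "g" else a.reaction_id for a in block}
        comps = list(nx.connected_components(graph.subgraph(ids)))
        if len(comps) <= 1:
            return None
        index = {v: i for i, comp in enumerate(comps) for v in comp}
        parts: dict[int, list[Association]] = {}
        for a in block:
            parts.setdefault(
                index[a.gene_id if side == "g" else a.reaction_id], []
            ).append(a)
        return list(parts.values())

    changed = True
    while changed:
        changed = False
        for side, graph in (("g", closed_gene_graph), ("r", closed_reaction_graph)):
            next_work = []
            for block in work:
                parts = split(block, side, graph)
                if parts is None:
                    next_work.append(block)
                else:
                    next_work.extend(parts)
                    changed = True
            work = next_work
    for block in work:
        block.sort(key=lambda a: a.key)
    work.sort(key=lambda block: block[0].key)
    return work


def _recover_side(
    anchors: Iterable[str], graph: nx.Graph, g: int
) -> tuple[set[str], set[tuple[str, str]]]:
    """Gap members for one layer: interior vertices of every shortest
    original-graph path realising a closure edge between two anchors."""
    anchors = sorted(set(anchors))
    members = set(anchors)
    for i, u in enumerate(anchors):
        dists = nx.single_source_shortest_path_length(graph, u, cutoff=g + 1)
        for v in anchors[i + 1 :]:
            if 2 <= dists.get(v, g + 2) <= g + 1:
                for path in nx.all_shortest_paths(graph, u, v):
                    members.update(path[1:-1])
    edges = {
        tuple(sorted((u, v)))
        for u, v in graph.subgraph(members).edges
    }
    return members, edges


def recover_gaps(
    ccc: Sequence[Association],
    gene_graph: nx.Graph,
    reaction_graph: nx.Graph,
    config: Config,
    metabolon_id: str = "M",
) -> Metabolon:
    """Turn one CCC into a metabolon by reinstating gap members.

    For every closure edge used inside the CCC (anchor pairs at original
    distance between 2 and g+1), the interior vertices of *all* shortest
    original-graph paths realising it are added as gap members; using the
    union of all shortest paths keeps the result deterministic and
    order-independent. Afterwards both layers are connected through original
    edges only.
    """
    ccc = sorted(ccc, key=lambda a: a.key)
    if not ccc:
        raise ValueError("cannot recover gaps of an empty CCC")
    organisms = {a.organism_id for a in ccc}
    if len(organisms) != 1:
        raise ValueError(f"CCC spans multiple organisms: {sorted(organisms)}")
    anchor_genes = {a.gene_id for a in ccc}
    anchor_rxns = {a.reaction_id for a in ccc}
    gene_members, gene_edges = _recover_side(anchor_genes, gene_graph, config.g_gene)
    rxn_members, rxn_edges = _recover_side(anchor_rxns, reaction_graph, config.g_rxn)
    return Metabolon(
        metabolon_id=metabolon_id,
        organism_id=next(iter(organisms)),
        gene_is_gap={g: g not in anchor_genes for g in sorted(gene_members)},
        reaction_is_gap={r: r not in anchor_rxns for r in sorted(rxn_members)},
        gene_edges=sorted(gene_edges),
        reaction_edges=sorted(rxn_edges),
        associations=[replace(a, metabolon_id=metabolon_id) for a in ccc],
    )


def filter_metabolons(
    metabolons: Iterable[Metabolon], config: Config
) -> list[Metabolon]:
    """Keep metabolons meeting the retention thresholds.

    Gene and reaction counts include gap members; the Known-association
    count does not (gaps by definition carry none).
    """
    kept = [
        m
        for m in metabolons
        if len(m.gene_is_gap) >= config.min_genes
        and len(m.reaction_is_gap) >= config.min_rxns
        and m.n_known() >= config.min_known
    ]
    return kept


def generate_potential(
    metabolon: Metabolon,
    known_gene_keys: set[tuple[str, str]],
    genes: Mapping[str, Gene],
    nonmetabolic_families: set[str] | frozenset[str] = frozenset(),
) -> list[Association]:
    """Propose Potential associations between gap genes and gap reactions.

    One Potential association per (eligible gap gene x gap reaction) pair.
    A gap gene is ineligible when it is flagged non-metabolic (directly or
    through its family) — such genes are kept as connectivity gaps but never
    proposed — or when it already holds a Known association anywhere in its
    genome (it is then annotated elsewhere, not a candidate).
    """
    org = metabolon.organism_id
    eligible = []
    for gid in metabolon.gap_genes:
        gene = genes[gid]
        if gene.non_metabolic:
            continue
        if gene.family_id is not None and gene.family_id in nonmetabolic_families:
            continue
        if (org, gid) in known_gene_keys:
            continue
        eligible.append(gid)
    return [
        Association(
            organism_id=org,
            gene_id=gid,
            reaction_id=rid,
            category=POTENTIAL,
            metabolon_id=metabolon.metabolon_id,
        )
        for gid in eligible
        for rid in metabolon.gap_reactions
    ]


def find_metabolons(
    data: DataGraph,
    config: Config | None = None,
    closed_gene_graphs: Mapping[str, nx.Graph] | None = None,
    closed_reaction_graph: nx.Graph | None = None,
) -> list[Metabolon]:
    """Detect and filter metabolons for every organism of the data graph.

    Metabolon ids are assigned deterministically by sorted
    ``(organism, smallest gene id)`` so reruns and input permutations yield
    identical labels. Precomputed closures may be supplied (they depend only
    on the graphs, not on the associations, so callers that rerun the
    pipeline on modified annotation sets can reuse them).
    """
    config = config or data.config
    if closed_reaction_graph is None:
        closed_reaction_graph = partial_transitive_closure(
            data.reaction_graph, config.g_rxn
        )
    found: list[Metabolon] = []
    for org in data.organisms:
        if closed_gene_graphs is not None and org in closed_gene_graphs:
            closed_gene = closed_gene_graphs[org]
        else:
            closed_gene = partial_transitive_closure(
                data.gene_graphs[org], config.g_gene
            )
        cccs = partition_cccs(
            data.known_by_organism(org), closed_gene, closed_reaction_graph
        )
        recovered = [
            recover_gaps(ccc, data.gene_graphs[org], data.reaction_graph, config)
            for ccc in cccs
        ]
        kept = filter_metabolons(recovered, config)
        logger.info(
            "%s: %d CCC(s), %d metabolon(s) retained", org, len(cccs), len(kept)
        )
        found.extend(kept)
    found.sort(key=lambda m: (m.organism_id, m.genes[0]))
    for i, m in enumerate(found, start=1):
        mid = f"M{i:05d}"
        m.metabolon_id = mid
        for a in m.associations:
            a.metabolon_id = mid
    return found
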