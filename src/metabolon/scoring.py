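"""Association weighting: minimal path lengths and gene-level scores.

Each gene-reaction association inside a metabolon is weighted by
``alpha / MPL`` where the **Minimal Path Length** is the length of the
shortest path through the metabolon graph between the gene and the reaction.
The metabolon graph contains the metabolon's original gene-gene edges,
original reaction-reaction edges and its Known gene-reaction edges; only
Known edges may be crossed between the two layers, and a Known association's
own edge is excluded from its own MPL so that the measure always captures
surrounding context rather than the annotation itself. Consequently the MPL
of a Known association is at least 2 (exactly 2 only for multi-functional
genes or multi-subunit enzymes) and the MPL of a Potential association is at
least 3 (a gene edge, a Known crossing and a reaction edge at minimum).

Gene-level association scores normalise these weights per gene (over its
candidate reactions) and per (organism, reaction) (over its candidate
genes); they are the single-genome counterparts of the family-level scores.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx

from .find import Metabolon
from .model import KNOWN, POTENTIAL, Association, Config

__all__ = [
    "metabolon_graph",
    "compute_mpl",
    "association_weight",
    "weigh_metabolon",
    "weigh_metabolons",
    "annotate_gene_scores",
    "gene_to_reaction_score",
    "reaction_to_gene_score",
]

logger = logging.getLogger(__name__)


def metabolon_graph(metabolon: Metabolon) -> nx.Graph:
    """The path-search graph of a metabolon.

    Nodes are ``("g", gene_id)`` and ``("r", reaction_id)`` (gap members
    included — paths may pass through them); edges are the metabolon's
    original gene/reaction adjacency edges plus its Known association edges.
    Every edge counts 1.
    """
    graph = nx.Graph()
    graph.add_nodes_from(("g", g) for g in metabolon.genes)
    graph.add_nodes_from(("r", r) for r in metabolon.reactions)
    graph.add_edges_from((("g", u), ("g", v)) for u, v in metabolon.gene_edges)
    graph.add_edges_from((("r", u), ("r", v)) for u, v in metabolon.reaction_edges)
    graph.add_edges_from(
        (("g", a.gene_id), ("r", a.reaction_id))
        for a in metabolon.associations
        if a.category == KNOWN
    )
    return graph


def compute_mpl(
    metabolon: Metabolon,
    gene_id: str,
    reaction_id: str,
    category: str = POTENTIAL,
    graph: nx.Graph | None = None,
) -> int | None:
    """Minimal path length between a gene and a reaction of a metabolon.

    For a Known association the association's own edge is not traversed.
    Returns ``None`` when no path exists (the association is then dropped
    rather than given a weight of zero, keeping score denominators
    well-defined).
    """
    if gene_id not in metabolon.gene_is_gap:
        raise KeyError(f"gene {gene_id!r} not in metabolon {metabolon.metabolon_id}")
    if reaction_id not in metabolon.reaction_is_gap:
        raise KeyError(
            f"reaction {reaction_id!r} not in metabolon {metabolon.metabolon_id}"
        )
    graph = graph.copy() if graph is not None else metabolon_graph(metabolon)
    source, target = ("g", gene_id), ("r", reaction_id)
    if category == KNOWN and graph.has_edge(source, target):
        graph.remove_edge(source, target)
    try:
        return nx.shortest_path_length(graph, source, target)
    except nx.NetworkXNoPath:
        return None


def association_weight(category: str, mpl: int, config: Config) -> float:
    """``alpha(category) / MPL`` — strictly decreasing in MPL, favouring
    candidates topologically close to the reaction gap."""
    if mpl < 1:
        raise ValueError("MPL must be >= 1")
    return config.alpha(category) / mpl


def weigh_metabolon(metabolon: Metabolon, config: Config) -> list[Association]:
    """Compute MPL and weight for every association of one metabolon.

    Associations with undefined MPL (no path) are removed from the metabolon
    and returned; a warning is logged for each.
    """
    graph = metabolon_graph(metabolon)
    dropped: list[Association] = []
    kept: list[Association] = []
    for a in metabolon.associations:
        mpl = compute_mpl(metabolon, a.gene_id, a.reaction_id, a.category, graph)
        if mpl is None:
            logger.warning(
                "association %s in %s has undefined MPL; dropped",
                a.key,
                metabolon.metabolon_id,
            )
            dropped.append(a)
            continue
        a.mpl = mpl
        a.weight = association_weight(a.category, mpl, config)
        kept.append(a)
    metabolon.associations = kept
    return dropped


def weigh_metabolons(
    metabolons: Iterable[Metabolon], config: Config
) -> list[Association]:
    """Weigh every metabolon; returns all dropped associations."""
    dropped: list[Association] = []
    for m in metabolons:
        dropped.extend(weigh_metabolon(m, config))
    return dropped


def annotate_gene_scores(associations: Sequence[Association]) -> None:
    """Set gene-level scores on weighted associations, in place.

    ``score_g_to_r`` is the association's share of the gene's total weight
    over all its reactions; ``score_r_to_g`` is its share of the reaction's
    total weight over all candidate genes of the same organism. Each sums to
    1 over its normalisation group.
    """
    weighted = [a for a in associations if a.weight is not None]
    by_gene: dict[tuple[str, str], float] = {}
    by_rxn: dict[tuple[str, str], float] = {}
    for a in weighted:
        by_gene[(a.organism_id, a.gene_id)] = (
            by_gene.get((a.organism_id, a.gene_id), 0.0) + a.weight
        )
        by_rxn[(a.organism_id, a.reaction_id)] = (
            by_rxn.get((a.organism_id, a.reaction_id), 0.0) + a.weight
        )
    for a in weighted:
        a.score_g_to_r = a.weight / by_gene[(a.organism_id, a.gene_id)]
        a.score_r_to_g = a.weight / by_rxn[(a.organism_id, a.reaction_id)]


def _lookup(
    associations: Sequence[Association],
    organism_id: str,
    gene_id: str,
    reaction_id: str,
) -> Association:
    for a in associations:
        if a.key == (organism_id, gene_id, reaction_id):
            return a
    raise KeyError((organism_id, gene_id, reaction_id))


def gene_to_reaction_score(
    associations: Sequence[Association],
    organism_id: str,
    gene_id: str,
    reaction_id: str,
) -> float:
    """Weight share of (G, R) among all weighted associations (G, *)."""
    target = _lookup(associations, organism_id, gene_id, reaction_id)
    if target.weight is None:
        raise ValueError(f"association {target.key} has no weight")
    denom = sum(
        a.weight
        for a in associations
        if a.weight is not None
        and (a.organism_id, a.gene_id) == (organism_id, gene_id)
    )
    return target.weight / denom


def reaction_to_gene_score(
    associations: Sequence[Association],
    organism_id: str,
    gene_id: str,
    reaction_id: str,
) -> float:
    """Weight share of (G, R) among all weighted associations (*, R) in O."""
    target = _lookup(associations, organism_id, gene_id, reaction_id)
    if target.weight is None:
        raise ValueError(f"association {target.key} has no weight")
    denom = sum(
        a.weight
        for a in associations
        if a.weight is not None
        and (a.organism_id, a.reaction_id) == (organism_id, reaction_id)
    )
    return target.weight / denom
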