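"""End-to-end orchestration: data graph in, ranked candidates out.

The stages run in their canonical order:

1. metabolon detection (closure, CCC partitioning, gap recovery, filtering);
2. Potential association generation between gap genes and gap reactions;
3. MPL computation and alpha/MPL weighting, then gene-level scores on the
   per-organism Known + Potential snapshot;
4. cross-organism integration: non-metabolic filtering, Inferred promotion,
   family-level scores (computed after both, on the reduced association set);
5. candidate ranking per (organism, reaction).

Closures depend only on the gene and reaction graphs, never on the
annotation set, so they can be computed once and reused across runs that
differ only in associations (the orphanization benchmark does exactly that).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .families import (
    Family,
    FamilyReactionScore,
    RankedCandidate,
    build_families,
    compute_family_scores,
    drop_nonmetabolic,
    promote_inferred,
    rank_candidates,
)
from .find import (
    Metabolon,
    find_metabolons,
    generate_potential,
    partial_transitive_closure,
)
from .model import Association, Config, DataGraph
from .scoring import annotate_gene_scores, weigh_metabolons

__all__ = ["Closures", "prepare_closures", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class Closures:
    """Precomputed g-partial transitive closures of both layers."""

    gene: dict[str, nx.Graph]
    reaction: nx.Graph


def prepare_closures(data: DataGraph, config: Config | None = None) -> Closures:
    config = config or data.config
    return Closures(
        gene={
            org: partial_transitive_closure(data.gene_graphs[org], config.g_gene)
            for org in data.organisms
        },
        reaction=partial_transitive_closure(data.reaction_graph, config.g_rxn),
    )


@dataclass
class PipelineResult:
    """Everything one run produces."""

    data: DataGraph
    config: Config
    metabolons: list[Metabolon]
    families: dict[str, Family]
    family_scores: list[FamilyReactionScore]
    rankings: list[RankedCandidate]
    dropped_unreachable: list[Association] = field(default_factory=list)
    dropped_nonmetabolic: list[Association] = field(default_factory=list)
    promoted: list[Association] = field(default_factory=list)
    removed_by_promotion: list[Association] = field(default_factory=list)

    @property
    def associations(self) -> list[Association]:
        """All metabolon associations (Known, Potential, Inferred), sorted."""
        out = [a for m in self.metabolons for a in m.associations]
        out.sort(key=lambda a: a.key)
        return out

    def candidate_pairs(self) -> list[tuple[str, str]]:
        """Sorted (organism, reaction) pairs holding at least one candidate."""
        return sorted(
            {
                (a.organism_id, a.reaction_id)
                for a in self.associations
                if a.category in ("Potential", "Inferred")
            }
        )


def run_pipeline(
    data: DataGraph,
    config: Config | None = None,
    closures: Closures | None = None,
    families: Mapping[str, Family] | None = None,
) -> PipelineResult:
    """Run the full strategy on a data graph.

    ``families`` defaults to the families declared by the genes'
    ``family_id`` attributes; pass an explicit mapping to override (e.g. one
    produced by :func:`metabolon.families.naive_families_from_similarity`).
    """
    config = config or data.config
    if closures is None:
        closures = prepare_closures(data, config)
    metabolons = find_metabolons(
        data,
        config,
        closed_gene_graphs=closures.gene,
        closed_reaction_graph=closures.reaction,
    )
    known_gene_keys = data.known_gene_keys()
    if families is None:
        families = build_families(
            g for org in data.organisms for g in data.genes[org].values()
        )
    nonmetabolic = {f.family_id for f in families.values() if f.non_metabolic}
    for m in metabolons:
        m.associations.extend(
            generate_potential(
                m, known_gene_keys, data.genes[m.organism_id], nonmetabolic
            )
        )
    dropped_unreachable = weigh_metabolons(metabolons, config)
    all_assocs = [a for m in metabolons for a in m.associations]
    annotate_gene_scores(all_assocs)
    dropped_nm = drop_nonmetabolic(metabolons, families)
    promoted, removed = promote_inferred(
        metabolons, data.associations, families, config
    )
    final_assocs = [a for m in metabolons for a in m.associations]
    family_scores = compute_family_scores(final_assocs, families)
    result = PipelineResult(
        data=data,
        config=config,
        metabolons=metabolons,
        families=dict(families),
        family_scores=family_scores,
        rankings=[],
        dropped_unreachable=dropped_unreachable,
        dropped_nonmetabolic=dropped_nm,
        promoted=promoted,
        removed_by_promotion=removed,
    )
    for org, rxn in result.candidate_pairs():
        result.rankings.extend(
            rank_candidates(
                final_assocs, families, family_scores, org, rxn, config.rank_score
            )
        )
    logger.info(
        "pipeline: %d metabolon(s), %d association(s) (%d Potential, %d Inferred), "
        "%d family score row(s), %d ranking row(s)",
        len(result.metabolons),
        len(final_assocs),
        sum(a.category == "Potential" for a in final_assocs),
        len(promoted),
        len(family_scores),
        len(result.rankings),
    )
    return result
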