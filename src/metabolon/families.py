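"""Cross-organism integration through gene families.

A single-genome Potential association is only a hypothesis; its credibility
grows when the same gene-context / reaction-context pattern recurs in other
organisms. Genes are grouped into families (an input here — any orthology
clustering will do; a naive single-linkage similarity clustering is provided
as a convenience), and three things happen at family level:

1. Potential associations held by *non-metabolic* families (transporters,
   regulators and other non-enzymes commonly embedded in metabolic operons)
   are dropped.
2. A Potential association (g, r) is **promoted to Inferred** when another
   member of g's family already holds a Known association to r. The gene and
   reaction then cease to be gaps in that metabolon, and the remaining
   Potential associations involving either of them in that metabolon are
   removed — the annotation transfer renders them impossible. Promotions are
   computed from the pre-promotion Known set only, which makes the operation
   deterministic and idempotent.
3. Family-reaction pairs are scored: Coverage (fraction of members
   associated), Score_F->R (share of the family's total association weight
   on the reaction) and Score_R->F (share of the reaction's total
   association weight on the family, across all organisms; family-less genes
   contribute to the denominator only).

Candidates for a reaction in an organism are finally ranked by the chosen
score, with competition ranking ("1, 1, 3") for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .find import Metabolon
from .model import INFERRED, KNOWN, POTENTIAL, Association, Config, Gene

__all__ = [
    "Family",
    "FamilyReactionScore",
    "RankedCandidate",
    "build_families",
    "naive_families_from_similarity",
    "drop_nonmetabolic",
    "promote_inferred",
    "family_coverage",
    "family_to_reaction_score",
    "reaction_to_family_score",
    "compute_family_scores",
    "rank_candidates",
]

logger = logging.getLogger(__name__)

GeneKey = tuple[str, str]  # (organism_id, gene_id)


@dataclass
class Family:
    """A cross-organism gene family. Members are ``(organism, gene)`` keys."""

    family_id: str
    members: set[GeneKey] = field(default_factory=set)
    non_metabolic: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class FamilyReactionScore:
    """Family-level descriptors for one (family, reaction) pair.

    Only pairs with at least one association are emitted, so coverage is
    always in (0, 1].
    """

    family_id: str
    reaction_id: str
    family_size: int
    coverage: float
    score_f_to_r: float
    score_r_to_f: float


@dataclass
class RankedCandidate:
    """One candidate gene for one reaction in one organism."""

    organism_id: str
    reaction_id: str
    gene_id: str
    rank: int
    score: float
    score_name: str
    category: str


def build_families(genes: Iterable[Gene]) -> dict[str, Family]:
    """Collect families from per-gene ``family_id`` attributes.

    A family is flagged non-metabolic when any member gene carries the flag
    (callers are expected to flag families consistently; the disjunction is
    the conservative reading).
    """
    families: dict[str, Family] = {}
    for g in genes:
        if g.family_id is None:
            continue
        fam = families.setdefault(g.family_id, Family(g.family_id))
        fam.members.add(g.key)
        if g.non_metabolic:
            fam.non_metabolic = True
    return families


def naive_families_from_similarity(
    similarity_edges: Iterable[tuple[GeneKey, GeneKey, float]],
    threshold: float,
) -> dict[str, Family]:
    """Single-linkage clustering of a gene similarity graph.

    Convenience stand-in for a proper orthology clustering: families are the
    connected components of the graph keeping only edges with similarity >=
    threshold; singletons are kept. Duplicate pairs with conflicting scores
    are rejected. Family ids are assigned from the sorted smallest member,
    so the result is independent of edge order.
    """
    scores: dict[tuple[GeneKey, GeneKey], float] = {}
    graph = nx.Graph()
    for a, b, s in similarity_edges:
        pair = tuple(sorted((a, b)))
        if pair in scores and scores[pair] != s:
            raise ValueError(
                f"conflicting similarity scores for pair {pair}: "
                f"{scores[pair]} vs {s}"
            )
        scores[pair] = s
        graph.add_node(a)
        graph.add_node(b)
        if s >= threshold:
            graph.add_edge(a, b)
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda comp: comp[0],
    )
    return {
        f"FAM{i:05d}": Family(f"FAM{i:05d}", set(comp))
        for i, comp in enumerate(components, start=1)
    }


def family_of_map(families: Mapping[str, Family]) -> dict[GeneKey, str]:
    """Invert families into a (organism, gene) -> family_id map.

    Raises on a gene claimed by two families (a gene belongs to at most one).
    """
    out: dict[GeneKey, str] = {}
    for fam in families.values():
        for key in fam.members:
            if key in out and out[key] != fam.family_id:
                raise ValueError(
                    f"gene {key} belongs to families {out[key]!r} and "
                    f"{fam.family_id!r}"
                )
            out[key] = fam.family_id
    return out


def drop_nonmetabolic(
    metabolons: Iterable[Metabolon], families: Mapping[str, Family]
) -> list[Association]:
    """Remove Potential associations of genes in non-metabolic families.

    Known (and Inferred) associations are untouched — the rule exists to
    stop proposing enzymatic roles for non-enzymes, not to contest curated
    annotation. Returns the removed associations.
    """
    flagged_members = {
        key
        for fam in families.values()
        if fam.non_metabolic
        for key in fam.members
    }
    removed: list[Association] = []
    for m in metabolons:
        kept = []
        for a in m.associations:
            if a.category == POTENTIAL and (a.organism_id, a.gene_id) in flagged_members:
                removed.append(a)
            else:
                kept.append(a)
        m.associations = kept
    if removed:
        logger.info("dropped %d Potential association(s) from non-metabolic families",
                    len(removed))
    return removed


def promote_inferred(
    metabolons: Iterable[Metabolon],
    known_associations: Sequence[Association],
    families: Mapping[str, Family],
    config: Config,
) -> tuple[list[Association], list[Association]]:
    """Promote family-supported Potential associations to Inferred.

    A Potential (g, r) becomes Inferred when another member of g's family
    holds a Known association to r anywhere in the corpus. Promoted
    associations are re-weighted with ``alpha_inferred`` (they inherit the
    MPL of the Potential they came from); the gene and reaction cease to be
    gaps in their metabolon and every association *still* Potential that
    involves either of them in that metabolon is removed.

    Promotions are decided from the pre-promotion Known set only: no
    chaining within a pass, and a second application is a no-op.

    Returns ``(promoted, removed)``.
    """
    fam_of = family_of_map(families)
    known_rxns_by_family: dict[str, set[str]] = {}
    for a in known_associations:
        fam = fam_of.get((a.organism_id, a.gene_id))
        if fam is not None:
            known_rxns_by_family.setdefault(fam, set()).add(a.reaction_id)
    promoted: list[Association] = []
    removed: list[Association] = []
    for m in metabolons:
        to_promote = [
            a
            for a in m.associations
            if a.category == POTENTIAL
            and a.reaction_id
            in known_rxns_by_family.get(fam_of.get((a.organism_id, a.gene_id), ""), ())
        ]
        if not to_promote:
            continue
        degapped_genes = set()
        degapped_rxns = set()
        for a in to_promote:
            a.category = INFERRED
            if a.mpl is not None:
                a.weight = config.alpha_inferred / a.mpl
            m.gene_is_gap[a.gene_id] = False
            m.reaction_is_gap[a.reaction_id] = False
            degapped_genes.add(a.gene_id)
            degapped_rxns.add(a.reaction_id)
            promoted.append(a)
        kept = []
        for a in m.associations:
            if a.category == POTENTIAL and (
                a.gene_id in degapped_genes or a.reaction_id in degapped_rxns
            ):
                removed.append(a)
            else:
                kept.append(a)
        m.associations = kept
    if promoted:
        logger.info(
            "promoted %d association(s) to Inferred, removing %d Potential(s)",
            len(promoted),
            len(removed),
        )
    return promoted, removed


def _weighted(associations: Iterable[Association]) -> list[Association]:
    return [a for a in associations if a.weight is not None]


def family_coverage(
    family: Family, reaction_id: str, associations: Sequence[Association]
) -> float:
    """Fraction of the family's genes associated with the reaction, whatever
    the category."""
    associated = {
        (a.organism_id, a.gene_id)
        for a in associations
        if a.reaction_id == reaction_id
        and (a.organism_id, a.gene_id) in family.members
    }
    return len(associated) / family.size


def family_to_reaction_score(
    family: Family, reaction_id: str, associations: Sequence[Association]
) -> float:
    """Share of the family's total association weight landing on the reaction."""
    weighted = _weighted(associations)
    member_assocs = [
        a for a in weighted if (a.organism_id, a.gene_id) in family.members
    ]
    denom = sum(a.weight for a in member_assocs)
    if denom == 0:
        raise ValueError(f"family {family.family_id!r} has no weighted association")
    num = sum(a.weight for a in member_assocs if a.reaction_id == reaction_id)
    return num / denom


def reaction_to_family_score(
    family: Family, reaction_id: str, associations: Sequence[Association]
) -> float:
    """Share of the reaction's total association weight (all organisms, all
    genes — family-less genes included in the denominator) held by the family."""
    weighted = [a for a in _weighted(associations) if a.reaction_id == reaction_id]
    denom = sum(a.weight for a in weighted)
    if denom == 0:
        raise ValueError(f"reaction {reaction_id!r} has no weighted association")
    num = sum(
        a.weight for a in weighted if (a.organism_id, a.gene_id) in family.members
    )
    return num / denom


def compute_family_scores(
    associations: Sequence[Association], families: Mapping[str, Family]
) -> list[FamilyReactionScore]:
    """All family-level descriptors, for every (family, reaction) pair with at
    least one association.

    Uses Known, Potential and Inferred associations across all organisms.
    Per family the Score_F->R values sum to 1; per reaction the Score_R->F
    values sum to at most 1, with equality exactly when every associated
    gene belongs to a family.
    """
    weighted = _weighted(associations)
    fam_of = family_of_map(families)
    rxn_total: dict[str, float] = {}
    fam_total: dict[str, float] = {}
    pair_weight: dict[tuple[str, str], float] = {}
    pair_members: dict[tuple[str, str], set[GeneKey]] = {}
    for a in weighted:
        rxn_total[a.reaction_id] = rxn_total.get(a.reaction_id, 0.0) + a.weight
        fam = fam_of.get((a.organism_id, a.gene_id))
        if fam is None:
            continue
        fam_total[fam] = fam_total.get(fam, 0.0) + a.weight
        pair = (fam, a.reaction_id)
        pair_weight[pair] = pair_weight.get(pair, 0.0) + a.weight
        pair_members.setdefault(pair, set()).add((a.organism_id, a.gene_id))
    out = []
    for (fam, rxn) in sorted(pair_weight):
        family = families[fam]
        out.append(
            FamilyReactionScore(
                family_id=fam,
                reaction_id=rxn,
                family_size=family.size,
                coverage=len(pair_members[(fam, rxn)]) / family.size,
                score_f_to_r=pair_weight[(fam, rxn)] / fam_total[fam],
                score_r_to_f=pair_weight[(fam, rxn)] / rxn_total[rxn],
            )
        )
    return out


def rank_candidates(
    associations: Sequence[Association],
    families: Mapping[str, Family],
    family_scores: Sequence[FamilyReactionScore],
    organism_id: str,
    reaction_id: str,
    score_name: str = "r_to_f",
) -> list[RankedCandidate]:
    """Rank candidate genes (Potential or Inferred) for one reaction in one
    organism, descending by the chosen score.

    ``score_name`` is ``r_to_f`` (reaction-to-family, the default and the
    better-performing choice) or ``r_to_g`` (reaction-to-gene). Under the
    family score, genes without a family (or whose family has no score for
    the reaction) fall back to their gene-level score and are ranked after
    every family-scored gene. Ties share the minimum (competition) rank.
    """
    if score_name not in ("r_to_f", "r_to_g"):
        raise ValueError(f"unknown score {score_name!r}")
    candidates = [
        a
        for a in associations
        if a.organism_id == organism_id
        and a.reaction_id == reaction_id
        and a.category in (POTENTIAL, INFERRED)
        and a.weight is not None
    ]
    if not candidates:
        return []
    fam_of = family_of_map(families)
    fs_index = {(fs.family_id, fs.reaction_id): fs for fs in family_scores}
    keyed = []
    for a in candidates:
        if score_name == "r_to_g":
            group, score = 0, a.score_r_to_g
        else:
            fam = fam_of.get((a.organism_id, a.gene_id))
            fs = fs_index.get((fam, reaction_id)) if fam is not None else None
            if fs is not None:
                group, score = 0, fs.score_r_to_f
            else:
                group, score = 1, a.score_r_to_g
        keyed.append(((group, -score), a, score))
    keyed.sort(key=lambda item: (item[0], item[1].gene_id))
    ranked = []
    for i, (sort_key, a, score) in enumerate(keyed):
        rank = 1 + sum(1 for other, _, _ in keyed if other < sort_key)
        ranked.append(
            RankedCandidate(
                organism_id=organism_id,
                reaction_id=reaction_id,
                gene_id=a.gene_id,
                rank=rank,
                score=score,
                score_name=score_name,
                category=a.category,
            )
        )
    return ranked
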