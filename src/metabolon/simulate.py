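"""Synthetic corpora with planted metabolon structure.

The generator emulates the shape of a curated multi-genome corpus: a global
reaction network made of pathway chains linked by main compounds, circular
genomes in which groups of enzyme-coding genes sit contiguously (operon-like
clusters) with occasional un-annotated spacer genes, families conserved
across organisms, and a sprinkling of non-enzymatic decoy genes (the
transporters/regulators that real operons drag along). Every planted cluster
instantiates a *template*: a contiguous segment of one reaction chain whose
reactions are coded, in order, by co-localized genes sharing per-slot
families across organisms.

``withhold_orphans`` then removes all Known associations of selected
reactions in every organism, turning them into recoverable global orphans:
withheld reactions are interior to their segment (so the metabolon keeps at
least two Known anchors on each layer), and no two withheld reactions are
adjacent within a segment. Ground truth records what was withheld so
end-to-end recovery can be measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import (
    Association,
    Config,
    DataGraph,
    Gene,
    Reaction,
    ReactionLink,
    assemble_data_graph,
)

__all__ = [
    "SimulationParams",
    "ClusterTemplate",
    "ClusterInstance",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "withhold_orphans",
]

logger = logging.getLogger(__name__)


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults define the standard study corpus.

    5 organisms of 200 genes, 60 reactions in 10 pathway chains, 8 planted
    cluster templates of 4-6 reactions each (one chain per template), 90%
    cross-organism conservation, a 20% spacer rate inside clusters, 10%
    decoy (non-metabolic) genes among the un-annotated ones and 5% family
    assignment noise.
    """

    n_organisms: int = 5
    genes_per_organism: int = 200
    n_reactions: int = 60
    n_chains: int = 10
    n_clusters: int = 8
    min_cluster_rxns: int = 4
    max_cluster_rxns: int = 6
    conservation: float = 0.9
    spacer_rate: float = 0.2
    decoy_fraction: float = 0.1
    family_noise: float = 0.05
    background_family_rate: float = 0.5
    min_separation: int = 5
    circular: bool = True

    def __post_init__(self) -> None:
        for name in ("n_organisms", "genes_per_organism", "n_reactions",
                     "n_chains", "n_clusters", "min_cluster_rxns",
                     "max_cluster_rxns", "min_separation"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("conservation", "spacer_rate", "decoy_fraction",
                     "family_noise", "background_family_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_cluster_rxns > self.max_cluster_rxns:
            raise ValueError("min_cluster_rxns > max_cluster_rxns")
        if self.n_clusters > self.n_chains:
            raise ValueError("need at least one chain per cluster template")
        if self.n_reactions // self.n_chains < self.min_cluster_rxns:
            raise ValueError("chains too short for the requested cluster size")
        # worst case every within-cluster slot receives a spacer
        worst = self.n_clusters * self.max_cluster_rxns * 2 + self.min_separation * (
            self.n_clusters + 1
        )
        if worst > self.genes_per_organism:
            raise ValueError(
                f"infeasible packing: up to {worst} genes needed per genome "
                f"but only {self.genes_per_organism} available"
            )


@dataclass(frozen=True)
class ClusterTemplate:
    """A reusable cluster blueprint: one reaction-chain segment plus the
    per-slot family ids shared by all its instances."""

    template_id: int
    chain_id: int
    reaction_ids: tuple[str, ...]
    family_ids: tuple[str, ...]


@dataclass(frozen=True)
class ClusterInstance:
    """One planted occurrence of a template in one organism. ``gene_ids``
    lists the core (annotated) genes in segment order, spacers excluded."""

    organism_id: str
    template_id: int
    gene_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    assignments: list[tuple[str, str, str]]  # (organism, gene, reaction)
    templates: list[ClusterTemplate]
    clusters: list[ClusterInstance]
    withheld: list[tuple[str, str, str]] = field(default_factory=list)
    withheld_reactions: list[str] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    """Generated inputs plus their ground truth."""

    genes: list[Gene]
    reactions: list[Reaction]
    links: list[ReactionLink]
    associations: list[Association]
    truth: GroundTruth
    params: SimulationParams
    seed: int

    def data_graph(self, config: Config | None = None) -> DataGraph:
        config = config or Config(circular_replicons=self.params.circular)
        return assemble_data_graph(
            self.genes, self.reactions, self.links,
            [replace(a) for a in self.associations], config,
        )


def _chains(params: SimulationParams) -> list[list[str]]:
    """Split the reaction ids into contiguous pathway chains."""
    base, extra = divmod(params.n_reactions, params.n_chains)
    chains, start = [], 0
    for c in range(params.n_chains):
        size = base + (1 if c < extra else 0)
        chains.append([f"R{start + i:03d}" for i in range(size)])
        start += size
    return chains


def simulate_dataset(params: SimulationParams | None = None, seed: int = 0) -> SimulatedDataset:
    """Generate a corpus; deterministic for fixed ``(params, seed)``."""
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    chains = _chains(params)
    reactions = [Reaction(rid) for chain in chains for rid in chain]
    links: list[ReactionLink] = []
    compound = 0
    for chain in chains:
        for a, b in zip(chain, chain[1:]):
            links.append(ReactionLink(a, b, frozenset({f"C{compound:03d}"})))
            compound += 1

    template_chains = rng.choice(params.n_chains, size=params.n_clusters, replace=False)
    templates: list[ClusterTemplate] = []
    for t, chain_id in enumerate(template_chains):
        chain = chains[chain_id]
        seg_len = int(
            rng.integers(params.min_cluster_rxns,
                         min(params.max_cluster_rxns, len(chain)) + 1)
        )
        start = int(rng.integers(0, len(chain) - seg_len + 1))
        segment = tuple(chain[start : start + seg_len])
        families = tuple(f"FAM_t{t}_s{j}" for j in range(seg_len))
        templates.append(ClusterTemplate(t, int(chain_id), segment, families))

    genes: list[Gene] = []
    associations: list[Association] = []
    assignments: list[tuple[str, str, str]] = []
    instances: list[ClusterInstance] = []
    n_decoy_families = 3

    for o in range(params.n_organisms):
        org = f"org{o + 1}"
        present = [t for t in range(params.n_clusters)
                   if rng.random() < params.conservation]
        order = [int(i) for i in rng.permutation(len(present))]
        ordered = [templates[present[i]] for i in order]

        def background_entry() -> dict:
            u = rng.random()
            if u < params.decoy_fraction:
                fam = f"NMF{int(rng.integers(n_decoy_families))}"
                return {"family": fam, "non_metabolic": True, "rxn": None}
            if u < params.decoy_fraction + params.background_family_rate:
                return {"family": "BG", "non_metabolic": False, "rxn": None}
            return {"family": None, "non_metabolic": False, "rxn": None}

        blocks: list[list[dict]] = []
        for tpl in ordered:
            block: list[dict] = []
            for j, rxn in enumerate(tpl.reaction_ids):
                fam = tpl.family_ids[j]
                if rng.random() < params.family_noise:
                    fam = None
                block.append({"family": fam, "non_metabolic": False,
                              "rxn": rxn, "template": tpl.template_id, "slot": j})
                if j < len(tpl.reaction_ids) - 1 and rng.random() < params.spacer_rate:
                    block.append(background_entry())
            blocks.append(block)

        n_cluster_genes = sum(len(b) for b in blocks)
        n_background = params.genes_per_organism - n_cluster_genes
        n_slots = len(blocks) + 1
        extra = n_background - params.min_separation * n_slots
        if extra < 0:  # unreachable given the packing check, kept defensive
            raise ValueError("infeasible packing after spacer placement")
        spread = rng.multinomial(extra, np.full(n_slots, 1.0 / n_slots))
        slot_sizes = [params.min_separation + int(x) for x in spread]

        entries: list[dict] = []
        for i, block in enumerate(blocks):
            entries.extend(background_entry() for _ in range(slot_sizes[i]))
            entries.extend(block)
        entries.extend(background_entry() for _ in range(slot_sizes[-1]))

        singleton = 0
        core_genes: dict[tuple[int, int], str] = {}
        for pos, entry in enumerate(entries):
            gid = f"{org}_g{pos:04d}"
            fam = entry["family"]
            if fam == "BG":
                fam = f"BG_{org}_{singleton:04d}"
                singleton += 1
            genes.append(
                Gene(gid, org, "chr", pos, family_id=fam,
                     non_metabolic=entry["non_metabolic"])
            )
            if entry["rxn"] is not None:
                associations.append(Association(org, gid, entry["rxn"]))
                assignments.append((org, gid, entry["rxn"]))
                core_genes[(entry["template"], entry["slot"])] = gid
        for tpl in ordered:
            instances.append(
                ClusterInstance(
                    organism_id=org,
                    template_id=tpl.template_id,
                    gene_ids=tuple(
                        core_genes[(tpl.template_id, j)]
                        for j in range(len(tpl.reaction_ids))
                    ),
                    reaction_ids=tpl.reaction_ids,
                )
            )

    truth = GroundTruth(
        assignments=sorted(assignments),
        templates=templates,
        clusters=sorted(instances, key=lambda c: (c.organism_id, c.template_id)),
    )
    return SimulatedDataset(
        genes=genes,
        reactions=reactions,
        links=links,
        associations=sorted(associations, key=lambda a: a.key),
        truth=truth,
        params=params,
        seed=seed,
    )


def withhold_orphans(
    dataset: SimulatedDataset, fraction: float = 0.2, seed: int = 0
) -> SimulatedDataset:
    """Withhold a fraction of the plantable reactions as global orphans.

    Eligible reactions are interior to their template segment, so every
    cluster instance keeps at least two Known anchors on both layers and the
    metabolon survives the removal; additionally no two withheld reactions
    may be adjacent within a segment. All Known associations of a withheld
    reaction are removed in every organism. When the requested fraction is
    not attainable under these constraints the selection is capped with a
    warning. Returns a new dataset whose ground truth records the withheld
    associations.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    interior: dict[str, tuple[int, int]] = {}  # rxn -> (template, slot)
    for tpl in dataset.truth.templates:
        for j, rxn in enumerate(tpl.reaction_ids):
            if 0 < j < len(tpl.reaction_ids) - 1:
                interior[rxn] = (tpl.template_id, j)
    with_known = {a.reaction_id for a in dataset.associations}
    eligible = sorted(r for r in interior if r in with_known)
    if not eligible:
        raise ValueError("no reaction eligible for withholding")
    target = max(1, int(round(fraction * len(eligible))))
    chosen: list[str] = []
    taken_slots: set[tuple[int, int]] = set()
    for idx in rng.permutation(len(eligible)):
        rxn = eligible[int(idx)]
        tpl, slot = interior[rxn]
        if (tpl, slot - 1) in taken_slots or (tpl, slot + 1) in taken_slots:
            continue
        chosen.append(rxn)
        taken_slots.add((tpl, slot))
        if len(chosen) >= target:
            break
    if len(chosen) < target:
        logger.warning(
            "withholding capped at %d of %d requested reactions "
            "(anchor constraints)", len(chosen), target,
        )
    chosen_set = set(chosen)
    kept = [a for a in dataset.associations if a.reaction_id not in chosen_set]
    withheld = [
        (a.organism_id, a.gene_id, a.reaction_id)
        for a in dataset.associations
        if a.reaction_id in chosen_set
    ]
    truth = GroundTruth(
        assignments=dataset.truth.assignments,
        templates=dataset.truth.templates,
        clusters=dataset.truth.clusters,
        withheld=sorted(withheld),
        withheld_reactions=sorted(chosen_set),
    )
    return SimulatedDataset(
        genes=dataset.genes,
        reactions=dataset.reactions,
        links=dataset.links,
        associations=kept,
        truth=truth,
        params=dataset.params,
        seed=dataset.seed,
    )
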