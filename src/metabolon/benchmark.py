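"""Systematic orphanization benchmark.

Every reaction that holds at least one Known association inside a metabolon
of the reference run is, in turn, rendered a global sequence-orphan: all of
its Known associations are removed in every organism and the whole pipeline
is rerun from scratch (metabolons, Potential generation, weighting,
integration, ranking). A genuine association counts as a true positive at
rank cutoff ``k`` when it reappears as a Potential association with
competition rank at most ``k`` under the chosen score, as a false negative
otherwise; a proposed association that matches no genuine one counts as a
false positive when its rank is at most ``k``. ``k = inf`` declares every
proposal positive, at which point the two ranking scores coincide (ranking
no longer filters anything). Results are pooled over all eligible reactions
into precision/recall rows per (score, k), plus a "self-rank" view — the
cumulative fraction of recovered genuine associations found within the first
n ranks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .families import rank_candidates
from .model import Config, DataGraph
from .pipeline import Closures, PipelineResult, prepare_closures, run_pipeline

__all__ = [
    "BenchmarkResult",
    "BenchmarkOutcome",
    "eligible_reactions",
    "orphanize_reaction",
    "score_recovery",
    "run_benchmark",
    "evaluate_recovery",
]

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkResult:
    """One pooled precision/recall row for a (score, k) pair."""

    score_name: str
    k: float  # positive integer or math.inf
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0


@dataclass
class BenchmarkOutcome:
    results: list[BenchmarkResult]
    #: score_name -> list of (rank, cumulative fraction of recovered TPs)
    self_rank: dict[str, list[tuple[int, float]]]
    eligible: list[str]
    #: per-score list of (organism, gene, reaction, rank, genuine?)
    proposals: dict[str, list[tuple[str, str, str, int, bool]]] = field(
        default_factory=dict
    )


def eligible_reactions(reference: PipelineResult) -> list[str]:
    """Reactions with at least one Known association inside a metabolon."""
    return sorted(
        {
            a.reaction_id
            for m in reference.metabolons
            for a in m.known_associations
        }
    )


def orphanize_reaction(data: DataGraph, reaction_id: str) -> DataGraph:
    """Remove every Known association involving the reaction, in every
    organism, turning it into a global sequence-orphan."""
    if reaction_id not in data.reactions:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    return data.without_reaction(reaction_id)


def score_recovery(
    proposals: Sequence[tuple[str, str, int]],
    genuine: set[tuple[str, str]],
    k: float,
) -> tuple[int, int, int]:
    """(tp, fp, fn) increments for one orphanized reaction at cutoff ``k``.

    ``proposals`` holds ``(organism, gene, rank)`` for every candidate
    proposed for the reaction; ``genuine`` holds the (organism, gene) pairs
    of the removed Known associations.
    """
    tp = sum(1 for org, gene, rank in proposals
             if rank <= k and (org, gene) in genuine)
    fp = sum(1 for org, gene, rank in proposals
             if rank <= k and (org, gene) not in genuine)
    fn = len(genuine) - tp
    return tp, fp, fn


def run_benchmark(
    data: DataGraph,
    config: Config | None = None,
    score_names: Sequence[str] = ("r_to_f", "r_to_g"),
    k_grid: Sequence[float] = (1, 2, 3, math.inf),
    closures: Closures | None = None,
    reference: PipelineResult | None = None,
) -> BenchmarkOutcome:
    """Pooled orphanization benchmark over every eligible reaction.

    Each orphanized run is a full recomputation (only the transitive
    closures, which do not depend on associations, are shared). Reactions
    with no metabolon presence in the reference run are skipped with a log
    entry. Deterministic for fixed inputs and config.
    """
    config = config or data.config
    closures = closures or prepare_closures(data, config)
    reference = reference or run_pipeline(data, config, closures)
    eligible = eligible_reactions(reference)
    if not eligible:
        logger.warning("no eligible reaction: empty benchmark")
        return BenchmarkOutcome(results=[], self_rank={}, eligible=[])
    skipped = sorted(set(data.reactions) - set(eligible))
    if skipped:
        logger.info("%d reaction(s) without metabolon presence skipped", len(skipped))

    per_score: dict[str, list[tuple[str, str, str, int, bool]]] = {
        s: [] for s in score_names
    }
    total_genuine = 0
    for rxn in eligible:
        genuine = {
            (a.organism_id, a.gene_id)
            for a in data.associations
            if a.reaction_id == rxn
        }
        total_genuine += len(genuine)
        run = run_pipeline(orphanize_reaction(data, rxn), config, closures)
        orgs = sorted(
            {
                a.organism_id
                for a in run.associations
                if a.reaction_id == rxn and a.category == "Potential"
            }
        )
        assocs = run.associations
        for score_name in score_names:
            for org in orgs:
                for cand in rank_candidates(
                    assocs, run.families, run.family_scores, org, rxn, score_name
                ):
                    per_score[score_name].append(
                        (org, cand.gene_id, rxn, cand.rank,
                         (org, cand.gene_id) in genuine)
                    )

    results: list[BenchmarkResult] = []
    for score_name in score_names:
        rows = per_score[score_name]
        for k in k_grid:
            tp = sum(1 for *_, rank, good in rows if rank <= k and good)
            fp = sum(1 for *_, rank, good in rows if rank <= k and not good)
            results.append(
                BenchmarkResult(score_name, k, tp, fp, total_genuine - tp)
            )

    self_rank: dict[str, list[tuple[int, float]]] = {}
    for score_name in score_names:
        ranks = sorted(rank for *_, rank, good in per_score[score_name] if good)
        n = len(ranks)
        curve: list[tuple[int, float]] = []
        if n:
            for r in range(1, max(ranks) + 1):
                curve.append((r, sum(1 for x in ranks if x <= r) / n))
        self_rank[score_name] = curve

    return BenchmarkOutcome(
        results=results,
        self_rank=self_rank,
        eligible=eligible,
        proposals=per_score,
    )


def evaluate_recovery(
    result: PipelineResult,
    withheld: Iterable[tuple[str, str, str]],
    score_name: str = "r_to_f",
) -> dict[str, float]:
    """Recovery statistics for a set of withheld genuine associations.

    An association is *recovered* when it reappears as a Potential (or
    Inferred) association in the run; it is *recovered at rank 1* when the
    gene additionally tops the candidate ranking of its (organism, reaction)
    pair under ``score_name``. Returns counts and fractions.
    """
    withheld = sorted(set(withheld))
    if not withheld:
        raise ValueError("no withheld association to evaluate")
    proposed = {
        a.key for a in result.associations if a.category in ("Potential", "Inferred")
    }
    recovered = [w for w in withheld if w in proposed]
    rank_cache: dict[tuple[str, str], dict[str, int]] = {}
    at_rank1 = 0
    for org, gene, rxn in recovered:
        pair = (org, rxn)
        if pair not in rank_cache:
            rank_cache[pair] = {
                c.gene_id: c.rank
                for c in rank_candidates(
                    result.associations,
                    result.families,
                    result.family_scores,
                    org,
                    rxn,
                    score_name,
                )
            }
        if rank_cache[pair].get(gene) == 1:
            at_rank1 += 1
    n = len(withheld)
    return {
        "n_withheld": n,
        "n_recovered": len(recovered),
        "n_rank1": at_rank1,
        "recovered_fraction": len(recovered) / n,
        "rank1_fraction": at_rank1 / n,
    }
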