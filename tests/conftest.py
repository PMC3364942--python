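"""Shared fixtures: the worked toy metabolon, a three-organism promotion
scenario, and the default synthetic corpus (session-scoped — several test
modules reuse the same runs)."""

from __future__ import annotations

import math

import pytest

import metabolon as mb

TOY_KNOWN = [("gA", "r1"), ("gC", "r2"), ("gD", "r3"), ("gF", "r5")]


def make_toy_data(known=TOY_KNOWN, config: mb.Config | None = None,
                  replicon_of=None) -> mb.DataGraph:
    """Six consecutive genes gA..gF on one linear replicon and five chained
    reactions r1..r5; Known associations as given."""
    config = config or mb.Config(circular_replicons=False)
    replicon_of = replicon_of or {}
    genes = [
        mb.Gene(f"g{c}", "org1", replicon_of.get(f"g{c}", "chr"), i)
        for i, c in enumerate("ABCDEF")
    ]
    # positions must restart per replicon
    by_rep: dict[str, int] = {}
    for g in genes:
        g.position = by_rep.get(g.replicon_id, 0)
        by_rep[g.replicon_id] = g.position + 1
    links = [
        mb.ReactionLink(f"r{i}", f"r{i + 1}", frozenset({f"c{i}"}))
        for i in range(1, 5)
    ]
    assocs = [mb.Association("org1", g, r) for g, r in known]
    return mb.assemble_data_graph(
        genes, [f"r{i}" for i in range(1, 6)], links, assocs, config
    )


@pytest.fixture
def toy_data() -> mb.DataGraph:
    return make_toy_data()


@pytest.fixture
def toy_result(toy_data) -> mb.PipelineResult:
    return mb.run_pipeline(toy_data)


def make_promotion_data() -> mb.DataGraph:
    """Two organisms sharing family F.

    org3 carries genes g3C, g3D, g3F, g3G in a row annotated (g3C,r3) and
    (g3G,r6) on the chain r3-r4-r5-r6, so g3D/g3F are gap genes and r4/r5
    gap reactions: four Potential pairs arise. org2 carries the adjacent
    pair (g2E,r4), (g2F,r5). Family F = {g2F, g3F}; g2F's Known association
    to r5 licenses promotion of (g3F, r5).
    """
    genes = [
        mb.Gene("g2E", "org2", "chr", 0, family_id="E"),
        mb.Gene("g2F", "org2", "chr", 1, family_id="F"),
        mb.Gene("g3C", "org3", "chr", 0, family_id="C"),
        mb.Gene("g3D", "org3", "chr", 1, family_id="D"),
        mb.Gene("g3F", "org3", "chr", 2, family_id="F"),
        mb.Gene("g3G", "org3", "chr", 3, family_id="G"),
    ]
    links = [
        mb.ReactionLink(f"r{i}", f"r{i + 1}", frozenset({f"c{i}"}))
        for i in range(3, 6)
    ]
    assocs = [
        mb.Association("org2", "g2E", "r4"),
        mb.Association("org2", "g2F", "r5"),
        mb.Association("org3", "g3C", "r3"),
        mb.Association("org3", "g3G", "r6"),
    ]
    return mb.assemble_data_graph(
        genes, [f"r{i}" for i in range(3, 7)], links, assocs,
        mb.Config(circular_replicons=False),
    )


@pytest.fixture
def promotion_data() -> mb.DataGraph:
    return make_promotion_data()


CORPUS_SEED = 1
WITHHOLD_SEED = 2
BENCH_K_GRID = (1, 2, 3, 4, math.inf)


@pytest.fixture(scope="session")
def default_corpus() -> mb.SimulatedDataset:
    return mb.simulate_dataset(mb.SimulationParams(), seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def withheld_corpus(default_corpus) -> mb.SimulatedDataset:
    return mb.withhold_orphans(default_corpus, 0.2, seed=WITHHOLD_SEED)


@pytest.fixture(scope="session")
def corpus_result(default_corpus) -> mb.PipelineResult:
    return mb.run_pipeline(default_corpus.data_graph())


@pytest.fixture(scope="session")
def withheld_result(withheld_corpus) -> mb.PipelineResult:
    return mb.run_pipeline(withheld_corpus.data_graph())


@pytest.fixture(scope="session")
def bench_outcome(default_corpus) -> mb.BenchmarkOutcome:
    return mb.run_benchmark(default_corpus.data_graph(), k_grid=BENCH_K_GRID)
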