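"""Tabular readers/writers, GraphML export and the run manifest.

All tables are tab-separated UTF-8 with a header row and "." decimals;
scores are printed to 4 decimals. These choices keep diffs stable, which the
test-suite exploits: every output is byte-identical across reruns with the
same inputs, configuration and seed (the manifest's timestamp being the one
documented exception).

Input dialects
--------------
``genes.tsv``
    organism_id, replicon_id, gene_id, position, family_id ("" if none),
    non_metabolic (0/1).
``reaction_links.tsv``
    reaction_a, reaction_b, main_compound_ids (comma-joined).
``reaction_compounds.tsv`` (alternative to links)
    reaction_id, compound_id, pathway_id, role (substrate/product),
    is_main (0/1).
``associations.tsv``
    organism_id, gene_id, reaction_id, category (input rows must be Known).

Validation failures name the file, the line number and the offending value.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from . import __version__
from .benchmark import BenchmarkOutcome
from .find import Metabolon
from .model import (
    KNOWN,
    Association,
    Config,
    DataGraph,
    Gene,
    Reaction,
    ReactionLink,
    assemble_data_graph,
    classify_orphan_status,
    reaction_links_from_compounds,
)
from .pipeline import PipelineResult

__all__ = [
    "read_genes",
    "read_reaction_links",
    "read_reaction_compounds",
    "read_associations",
    "read_inputs",
    "write_genes",
    "write_reaction_links",
    "write_associations",
    "write_outputs",
    "metabolons_to_graphml",
    "write_benchmark",
]

logger = logging.getLogger(__name__)


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:.4f}"


class TableError(ValueError):
    """A validation failure located in an input table."""

    def __init__(self, path: Path | str, line: int, message: str):
        super().__init__(f"{path}, line {line}: {message}")


def _rows(path: Path, required: Sequence[str]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise TableError(path, 1, f"missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            yield lineno, row


def read_genes(path: str | Path) -> list[Gene]:
    path = Path(path)
    genes: list[Gene] = []
    seen: set[tuple[str, str]] = set()
    cols = ("organism_id", "replicon_id", "gene_id", "position", "family_id",
            "non_metabolic")
    for lineno, row in _rows(path, cols):
        key = (row["organism_id"], row["gene_id"])
        if key in seen:
            raise TableError(path, lineno, f"duplicate gene id {row['gene_id']!r}")
        seen.add(key)
        try:
            position = int(row["position"])
        except ValueError:
            raise TableError(path, lineno, f"bad position {row['position']!r}")
        if row["non_metabolic"] not in ("0", "1"):
            raise TableError(
                path, lineno, f"non_metabolic must be 0/1, got {row['non_metabolic']!r}"
            )
        genes.append(
            Gene(
                gene_id=row["gene_id"],
                organism_id=row["organism_id"],
                replicon_id=row["replicon_id"],
                position=position,
                family_id=row["family_id"] or None,
                non_metabolic=row["non_metabolic"] == "1",
            )
        )
    return genes


def read_reaction_links(path: str | Path) -> list[ReactionLink]:
    path = Path(path)
    links: list[ReactionLink] = []
    for lineno, row in _rows(path, ("reaction_a", "reaction_b", "main_compound_ids")):
        compounds = frozenset(c for c in row["main_compound_ids"].split(",") if c)
        try:
            links.append(ReactionLink(row["reaction_a"], row["reaction_b"], compounds))
        except ValueError as exc:
            raise TableError(path, lineno, str(exc))
    return links


def read_reaction_compounds(path: str | Path) -> list[ReactionLink]:
    path = Path(path)
    rows = []
    cols = ("reaction_id", "compound_id", "pathway_id", "role", "is_main")
    for lineno, row in _rows(path, cols):
        if row["role"] not in ("substrate", "product"):
            raise TableError(path, lineno, f"bad role {row['role']!r}")
        if row["is_main"] not in ("0", "1"):
            raise TableError(path, lineno, f"is_main must be 0/1, got {row['is_main']!r}")
        rows.append(
            (row["reaction_id"], row["compound_id"], row["pathway_id"],
             row["role"], row["is_main"] == "1")
        )
    return reaction_links_from_compounds(rows)


def read_associations(path: str | Path) -> list[Association]:
    path = Path(path)
    out: list[Association] = []
    for lineno, row in _rows(path, ("organism_id", "gene_id", "reaction_id", "category")):
        if row["category"] != KNOWN:
            raise TableError(
                path, lineno,
                f"input associations must be Known, got {row['category']!r}",
            )
        out.append(Association(row["organism_id"], row["gene_id"], row["reaction_id"]))
    return out


def read_inputs(
    genes_path: str | Path,
    associations_path: str | Path,
    links_path: str | Path | None = None,
    compounds_path: str | Path | None = None,
    config: Config | None = None,
) -> DataGraph:
    """Load and validate the three input tables into a data graph.

    Provide either ``links_path`` or ``compounds_path`` for the reaction
    layer. The reaction vertex set is the union of link endpoints and
    association targets (isolated reactions thus survive).
    """
    if (links_path is None) == (compounds_path is None):
        raise ValueError("provide exactly one of links_path / compounds_path")
    genes = read_genes(genes_path)
    links = (
        read_reaction_links(links_path)
        if links_path is not None
        else read_reaction_compounds(compounds_path)
    )
    associations = read_associations(associations_path)
    reaction_ids = sorted(
        {l.reaction_a for l in links}
        | {l.reaction_b for l in links}
        | {a.reaction_id for a in associations}
    )
    return assemble_data_graph(genes, reaction_ids, links, associations, config)


def write_genes(genes: Iterable[Gene], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["organism_id", "replicon_id", "gene_id", "position",
                    "family_id", "non_metabolic"])
        for g in sorted(genes, key=lambda g: (g.organism_id, g.replicon_id, g.position)):
            w.writerow([g.organism_id, g.replicon_id, g.gene_id, g.position,
                        g.family_id or "", int(g.non_metabolic)])


def write_reaction_links(links: Iterable[ReactionLink], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["reaction_a", "reaction_b", "main_compound_ids"])
        for l in sorted(links, key=lambda l: (l.reaction_a, l.reaction_b)):
            w.writerow([l.reaction_a, l.reaction_b, ",".join(sorted(l.main_compounds))])


def write_associations(associations: Iterable[Association], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["organism_id", "gene_id", "reaction_id", "category"])
        for a in sorted(associations, key=lambda a: a.key):
            w.writerow([a.organism_id, a.gene_id, a.reaction_id, a.category])


def metabolons_to_graphml(metabolons: Iterable[Metabolon], path: str | Path) -> None:
    """Export metabolons to a single GraphML file.

    GraphML holds one graph per file, so the metabolons are written as the
    disjoint union of their graphs: node ids are ``metabolon|kind|id`` and
    every node and edge carries a ``metabolon_id`` attribute, which makes
    the individual graphs recoverable on re-import. Node attributes: kind
    ("gene"/"reaction"), is_gap; edge attributes: kind ("gene", "reaction"
    or "association"), plus category/mpl/weight on association edges.
    """
    union = nx.Graph()
    for m in metabolons:
        def node(kind: str, ident: str) -> str:
            return f"{m.metabolon_id}|{kind}|{ident}"

        for gid, gap in sorted(m.gene_is_gap.items()):
            union.add_node(node("gene", gid), kind="gene", name=gid, is_gap=gap,
                           metabolon_id=m.metabolon_id, organism_id=m.organism_id)
        for rid, gap in sorted(m.reaction_is_gap.items()):
            union.add_node(node("reaction", rid), kind="reaction", name=rid,
                           is_gap=gap, metabolon_id=m.metabolon_id,
                           organism_id=m.organism_id)
        for u, v in m.gene_edges:
            union.add_edge(node("gene", u), node("gene", v), kind="gene",
                           metabolon_id=m.metabolon_id)
        for u, v in m.reaction_edges:
            union.add_edge(node("reaction", u), node("reaction", v), kind="reaction",
                           metabolon_id=m.metabolon_id)
        for a in m.associations:
            attrs = {"kind": "association", "category": a.category,
                     "metabolon_id": m.metabolon_id}
            if a.mpl is not None:
                attrs["mpl"] = a.mpl
            if a.weight is not None:
                attrs["weight"] = a.weight
            union.add_edge(node("gene", a.gene_id), node("reaction", a.reaction_id),
                           **attrs)
    nx.write_graphml(union, path)


def write_benchmark(outcome: BenchmarkOutcome, outdir: str | Path) -> None:
    outdir = Path(outdir)
    with open(outdir / "benchmark.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["score", "k", "tp", "fp", "fn", "recall", "precision"])
        for r in outcome.results:
            k = "inf" if r.k == float("inf") else int(r.k)
            w.writerow([r.score_name, k, r.tp, r.fp, r.fn,
                        _fmt(r.recall), _fmt(r.precision)])
    with open(outdir / "benchmark_selfrank.tsv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["score", "rank", "cumulative_tp_fraction"])
        for score_name in sorted(outcome.self_rank):
            for rank, frac in outcome.self_rank[score_name]:
                w.writerow([score_name, rank, _fmt(frac)])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    result: PipelineResult,
    outdir: str | Path,
    benchmark: BenchmarkOutcome | None = None,
    input_paths: Iterable[str | Path] = (),
) -> None:
    """Write every result table, the GraphML export and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metabolons_to_graphml(result.metabolons, outdir / "metabolons.graphml")

    assocs = result.associations
    with open(outdir / "associations_out.tsv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["organism_id", "gene_id", "reaction_id", "category",
                    "metabolon_id", "mpl", "weight", "score_g_to_r",
                    "score_r_to_g"])
        for a in assocs:
            w.writerow([a.organism_id, a.gene_id, a.reaction_id, a.category,
                        a.metabolon_id or "", a.mpl if a.mpl is not None else "",
                        _fmt(a.weight), _fmt(a.score_g_to_r), _fmt(a.score_r_to_g)])

    with open(outdir / "family_scores.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["family_id", "reaction_id", "family_size", "coverage",
                    "score_f_to_r", "score_r_to_f"])
        for fs in result.family_scores:
            w.writerow([fs.family_id, fs.reaction_id, fs.family_size,
                        _fmt(fs.coverage), _fmt(fs.score_f_to_r),
                        _fmt(fs.score_r_to_f)])

    with open(outdir / "rankings.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["organism_id", "reaction_id", "gene_id", "rank", "score",
                    "category", "orphan_status"])
        status_cache: dict[tuple[str, str], str] = {}
        for c in result.rankings:
            pair = (c.organism_id, c.reaction_id)
            if pair not in status_cache:
                status_cache[pair] = classify_orphan_status(
                    result.data, c.reaction_id, c.organism_id
                )
            w.writerow([c.organism_id, c.reaction_id, c.gene_id, c.rank,
                        _fmt(c.score), c.category, status_cache[pair]])

    if benchmark is not None:
        write_benchmark(benchmark, outdir)

    by_cat: dict[str, int] = {}
    for a in assocs:
        by_cat[a.category] = by_cat.get(a.category, 0) + 1
    manifest = {
        "tool": "metabolon",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": asdict(result.config),
        "inputs": {str(p): _sha256(Path(p)) for p in input_paths},
        "counts": {
            "organisms": len(result.data.organisms),
            "genes": sum(len(v) for v in result.data.genes.values()),
            "reactions": len(result.data.reactions),
            "metabolons": len(result.metabolons),
            "associations": dict(sorted(by_cat.items())),
            "family_score_rows": len(result.family_scores),
            "ranking_rows": len(result.rankings),
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("outputs written to %s", outdir)
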