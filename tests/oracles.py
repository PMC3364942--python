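"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive subset enumeration,
hand-rolled BFS — and shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np

from metabolon import Association, Config, Gene, ReactionLink, assemble_data_graph


def bfs_distances(adj: dict, source) -> dict:
    """Plain BFS over an adjacency mapping (no networkx)."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def graph_adj(graph: nx.Graph) -> dict:
    return {u: sorted(graph.neighbors(u)) for u in graph}


def closure_oracle(graph: nx.Graph, g: int) -> set[frozenset]:
    """Edge set of the g-partial transitive closure, by all-pairs BFS."""
    adj = graph_adj(graph)
    edges = set()
    for u in graph:
        for v, d in bfs_distances(adj, u).items():
            if 1 <= d <= g + 1:
                edges.add(frozenset((u, v)))
    return edges


def _connected(ids: set, graph: nx.Graph) -> bool:
    if not ids:
        return False
    adj = {u: [v for v in graph.neighbors(u) if v in ids]
           for u in ids if u in graph}
    if len(adj) != len(ids):
        return False
    start = next(iter(ids))
    return set(bfs_distances(adj, start)) == ids


def brute_force_cccs(
    associations, closed_gene: nx.Graph, closed_rxn: nx.Graph
) -> set[frozenset]:
    """All maximal association subsets whose gene side and reaction side are
    each connected in the respective closed graph, by subset enumeration."""
    assocs = list(associations)
    valid = []
    for r in range(1, len(assocs) + 1):
        for combo in itertools.combinations(range(len(assocs)), r):
            chosen = [assocs[i] for i in combo]
            genes = {a.gene_id for a in chosen}
            rxns = {a.reaction_id for a in chosen}
            if _connected(genes, closed_gene) and _connected(rxns, closed_rxn):
                valid.append(frozenset(a.key for a in chosen))
    return {s for s in valid if not any(s < t for t in valid)}


def gap_members_oracle(anchors, graph: nx.Graph, g: int) -> set:
    """Gap members for one layer, by the distance-sum characterisation:
    w lies on a shortest u-v path iff d(u,w) + d(w,v) = d(u,v)."""
    adj = graph_adj(graph)
    anchors = sorted(set(anchors))
    dists = {a: bfs_distances(adj, a) for a in anchors}
    members = set(anchors)
    for u, v in itertools.combinations(anchors, 2):
        d = dists[u].get(v)
        if d is None or not 2 <= d <= g + 1:
            continue
        for w in graph:
            du, dv = dists[u].get(w), dists[v].get(w)
            if du is not None and dv is not None and du + dv == d and 0 < du < d:
                members.add(w)
    return members


def mpl_oracle(metabolon, gene_id: str, reaction_id: str, category: str) -> int | None:
    """Shortest gene->reaction path by hand-rolled BFS over the metabolon's
    original edges plus Known association edges (own edge excluded for a
    Known association)."""
    adj: dict = {}

    def add(u, v):
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    for u, v in metabolon.gene_edges:
        add(("g", u), ("g", v))
    for u, v in metabolon.reaction_edges:
        add(("r", u), ("r", v))
    for a in metabolon.associations:
        if a.category != "Known":
            continue
        if category == "Known" and (a.gene_id, a.reaction_id) == (gene_id, reaction_id):
            continue
        add(("g", a.gene_id), ("r", a.reaction_id))
    dist = bfs_distances(adj, ("g", gene_id))
    return dist.get(("r", reaction_id))


def random_instance(rng: np.random.Generator):
    """A random small data graph: <=12 genes on 1-2 linear replicons, <=10
    reactions with random links, <=10 random Known associations."""
    n_genes = int(rng.integers(4, 13))
    n_rxns = int(rng.integers(3, 11))
    n_replicons = int(rng.integers(1, 3))
    split = int(rng.integers(2, n_genes - 1)) if n_replicons == 2 else n_genes
    genes = []
    for i in range(n_genes):
        rep = "repA" if i < split else "repB"
        pos = i if i < split else i - split
        genes.append(Gene(f"g{i:02d}", "org1", rep, pos))
    rxn_ids = [f"r{i:02d}" for i in range(n_rxns)]
    links = []
    p = rng.uniform(0.15, 0.4)
    for i, j in itertools.combinations(range(n_rxns), 2):
        if rng.random() < p:
            links.append(ReactionLink(rxn_ids[i], rxn_ids[j], frozenset({f"c{i}_{j}"})))
    n_assoc = int(rng.integers(2, 11))
    pairs = [(g.gene_id, r) for g in genes for r in rxn_ids]
    idx = rng.choice(len(pairs), size=min(n_assoc, len(pairs)), replace=False)
    assocs = [Association("org1", *pairs[int(i)]) for i in sorted(idx)]
    config = Config(min_genes=1, min_rxns=1, min_known=1,
                    circular_replicons=bool(rng.random() < 0.5))
    data = assemble_data_graph(genes, rxn_ids, links, assocs, config)
    return data, config
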