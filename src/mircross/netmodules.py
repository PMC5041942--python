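"""Module detection: maximal bicliques and k-clique percolation.

The miRNA-pathway network is mined for biclique modules — maximal complete
bipartite subgraphs pairing a miRNA set with a pathway set it jointly
regulates.  The pathway crosstalk network is mined for clique-percolation
communities: unions of k-cliques chained by (k-1)-node overlaps, the
CFinder notion of a module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Optional

import networkx as nx
from networkx.algorithms.community import k_clique_communities

from mircross.errors import InputError


@dataclass(frozen=True)
class BicliqueModule:
    id: int
    mirna_set: FrozenSet[str]
    pathway_set: FrozenSet[str]


@dataclass(frozen=True)
class CliqueCommunity:
    id: int
    pathway_set: FrozenSet[str]
    k: int


def _bipartite_sides(graph: nx.Graph):
    mirnas = {n for n, a in graph.nodes(data=True) if a.get("kind") == "miRNA"}
    pathways = {n for n, a in graph.nodes(data=True) if a.get("kind") == "pathway"}
    untagged = set(graph.nodes) - mirnas - pathways
    if untagged or any(graph.has_edge(a, b) for side in (mirnas, pathways)
                       for a in side for b in side if a < b):
        raise InputError("network is not a node-tagged bipartite miRNA-pathway graph")
    return mirnas, pathways


def maximal_bicliques(
    graph: nx.Graph,
    min_mirnas: int = 1,
    min_pathways: int = 1,
) -> List[BicliqueModule]:
    """Enumerate maximal bicliques of the bipartite miRNA-pathway network.

    Uses the standard reduction to maximal-clique enumeration: augment the
    graph with all within-side edges; the maximal cliques of the augmented
    graph that contain at least one node of each side are exactly the
    maximal bicliques with both sides nonempty.  Modules are returned in
    deterministic lexicographic order of their sorted member IDs and get
    sequential IDs from 1.
    """
    mirnas, pathways = _bipartite_sides(graph)
    if not graph.number_of_edges():
        return []
    aug = nx.Graph(graph.edges)
    for side in (mirnas & set(aug), pathways & set(aug)):
        members = sorted(side)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                aug.add_edge(a, b)
    modules = []
    for clique in nx.find_cliques(aug):
        ms = frozenset(n for n in clique if n in mirnas)
        ps = frozenset(n for n in clique if n in pathways)
        if len(ms) >= max(min_mirnas, 1) and len(ps) >= max(min_pathways, 1):
            modules.append((tuple(sorted(ms)), tuple(sorted(ps))))
    modules.sort()
    return [
        BicliqueModule(id=i, mirna_set=frozenset(ms), pathway_set=frozenset(ps))
        for i, (ms, ps) in enumerate(modules, start=1)
    ]


def clique_percolation(graph: nx.Graph, k: int = 3) -> List[CliqueCommunity]:
    """k-clique percolation communities of a simple graph.

    Two k-cliques are adjacent when they share k-1 nodes; a community is a
    connected component of that overlap relation, reported as the union of
    its cliques' nodes.  Deterministically ordered and numbered from 1.
    """
    if k < 3:
        raise InputError("clique percolation needs k >= 3")
    if any(a == b for a, b in graph.edges):
        raise InputError("graph must be simple (no self-loops)")
    communities = sorted(tuple(sorted(c)) for c in k_clique_communities(graph, k))
    return [
        CliqueCommunity(id=i, pathway_set=frozenset(c), k=k)
        for i, c in enumerate(communities, start=1)
    ]


def extract_core_module(
    crosstalk: nx.Graph,
    anchor_pathway_id: str,
    k: int = 3,
) -> nx.Graph:
    """Neighborhood of the community containing an anchor pathway.

    Returns the k-clique community holding the anchor plus the "indirect
    route" pathways: nodes outside the community adjacent to at least two
    community members (they bridge community pathways through paths that
    leave the module).  If the anchor joins no community the subgraph is
    the anchor alone.  Nodes carry an ``in_community`` attribute.
    """
    if anchor_pathway_id not in crosstalk:
        raise InputError(f"anchor pathway {anchor_pathway_id!r} not in network")
    community = {anchor_pathway_id}
    for comm in clique_percolation(crosstalk, k=k):
        if anchor_pathway_id in comm.pathway_set:
            community = set(comm.pathway_set)
            break
    bridges = set()
    for node in crosstalk.nodes:
        if node in community:
            continue
        if sum(1 for nb in crosstalk.neighbors(node) if nb in community) >= 2:
            bridges.add(node)
    sub = crosstalk.subgraph(community | bridges).copy()
    for node in sub.nodes:
        sub.nodes[node]["in_community"] = node in community
    return sub
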