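"""Network integration and TF-centric core-network reconstruction.

Per-condition networks are merged by node/edge union with per-element
source tracking (which input networks contributed each node or edge), an
optional ``shared_only`` filter retains only elements present in at least
m inputs. Core networks are reconstructed around transcription factors:
GO-filtered TF seeds, their direct neighbors, an optional GO filter on the
neighbors, the induced subgraph, and a degree ranking of the resulting
hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .gcn import CoexpressionNetwork

__all__ = [
    "CoreNetwork",
    "merge_networks",
    "reconstruct_core",
    "first_neighbors",
    "shared_edge_decomposition",
]


@dataclass
class CoreNetwork:
    """TF-centered, GO-filtered subgraph of an integrated network.

    ``hub_ranking`` lists (gene, degree-in-core, is_tf) sorted by degree
    descending with lexicographic tie-break on the gene id.
    """

    parent: CoexpressionNetwork
    graph: nx.Graph
    seed_tfs: set[str]
    hub_ranking: list[tuple[str, int, bool]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def as_network(self) -> CoexpressionNetwork:
        return CoexpressionNetwork(
            graph=self.graph, r_threshold=self.parent.r_threshold, mode=self.parent.mode
        )


def merge_networks(
    nets: Sequence[CoexpressionNetwork], shared_only: int = 1
) -> CoexpressionNetwork:
    """Union of networks with per-node/per-edge source tracking.

    All inputs must share build parameters (threshold and mode). Each
    output node and edge carries ``source_conditions`` = the union of the
    sources of the inputs containing it; an edge present in several inputs
    keeps every r keyed by source in ``r_by_source`` and stores the
    largest-magnitude one as its representative ``r``. ``shared_only`` = m
    keeps only nodes present in >= m inputs (edges survive if both
    endpoints do), m = 1 being the pure union.
    """
    if len(nets) < 2:
        raise ValueError("merging needs >= 2 networks")
    first = nets[0]
    for other in nets[1:]:
        if not first.same_parameters(other):
            raise ValueError(
                "networks built with different parameters cannot be merged "
                f"({first.r_threshold}/{first.mode} vs {other.r_threshold}/{other.mode})"
            )
    if shared_only < 1:
        raise ValueError("shared_only must be >= 1")

    merged = nx.Graph()
    node_presence: dict[str, int] = {}
    for net in nets:
        for node, data in net.graph.nodes(data=True):
            node_presence[node] = node_presence.get(node, 0) + 1
            if node not in merged:
                merged.add_node(
                    node,
                    is_tf=data.get("is_tf", False),
                    go_terms=data.get("go_terms", frozenset()),
                    source_conditions=frozenset(data.get("source_conditions", frozenset())),
                )
            else:
                nd = merged.nodes[node]
                nd["is_tf"] = nd["is_tf"] or data.get("is_tf", False)
                nd["go_terms"] = nd["go_terms"] | data.get("go_terms", frozenset())
                nd["source_conditions"] = nd["source_conditions"] | frozenset(
                    data.get("source_conditions", frozenset())
                )
        for u, v, data in net.graph.edges(data=True):
            r_by_source = dict(data.get("r_by_source", {}))
            sources = frozenset(data.get("source_conditions", frozenset()))
            if merged.has_edge(u, v):
                ed = merged.edges[u, v]
                ed["r_by_source"].update(r_by_source)
                ed["source_conditions"] = ed["source_conditions"] | sources
                rs = list(ed["r_by_source"].values()) or [ed["r"], data.get("r", 0.0)]
                ed["r"] = max(rs, key=abs)
            else:
                merged.add_edge(
                    u,
                    v,
                    r=data.get("r", 0.0),
                    r_by_source=r_by_source,
                    source_conditions=sources,
                )
    if shared_only > 1:
        keep = {n for n, c in node_presence.items() if c >= shared_only}
        merged = merged.subgraph(keep).copy()
    return CoexpressionNetwork(
        graph=merged, r_threshold=first.r_threshold, mode=first.mode
    )


def first_neighbors(net: CoexpressionNetwork, seeds: Iterable[str]) -> set[str]:
    """Seeds together with every node sharing an edge with a seed."""
    seeds = set(seeds)
    unknown = seeds - set(net.graph.nodes)
    if unknown:
        raise ValueError(f"seed gene {sorted(unknown)[0]!r} not in network")
    out = set(seeds)
    for s in seeds:
        out.update(net.graph.neighbors(s))
    return out


def _rank_hubs(graph: nx.Graph, metric: str = "degree") -> list[tuple[str, int, bool]]:
    if metric == "degree":
        score = dict(graph.degree())
    elif metric == "betweenness":
        score = nx.betweenness_centrality(graph)
    else:
        raise ValueError(f"unknown hub metric {metric!r}")
    entries = [
        (node, graph.degree(node), bool(graph.nodes[node].get("is_tf", False)))
        for node in graph.nodes
    ]
    return sorted(entries, key=lambda e: (-score[e[0]], e[0]))


def reconstruct_core(
    net: CoexpressionNetwork,
    tf_genes: Iterable[str],
    go_filter: Iterable[str] | None = None,
    hub_metric: str = "degree",
) -> CoreNetwork:
    """Reconstruct the TF-centered, GO-filtered core of a network.

    Step 1: seeds = TFs present in the network, restricted (when
    ``go_filter`` is given) to TFs carrying at least one filter term.
    Step 2: candidates = seeds plus their direct neighbors. Step 3: with a
    GO filter, non-seed candidates must carry a filter term. Step 4: the
    induced subgraph on the retained nodes (edges among non-seed survivors
    are kept). Step 5: hubs ranked within the core by ``hub_metric``
    (degree by default; betweenness as a secondary option).
    """
    tf_in_net = set(tf_genes) & set(net.graph.nodes)
    if not tf_in_net:
        raise ValueError("no annotated TFs in network")
    filter_terms = None if go_filter is None else set(go_filter)
    if filter_terms is not None:
        seeds = {
            t
            for t in tf_in_net
            if net.graph.nodes[t].get("go_terms", frozenset()) & filter_terms
        }
        if not seeds:
            raise ValueError("no annotated TFs in network carry a filter GO term")
    else:
        seeds = tf_in_net
    candidates = first_neighbors(net, seeds)
    if filter_terms is not None:
        retained = {
            n
            for n in candidates
            if n in seeds or net.graph.nodes[n].get("go_terms", frozenset()) & filter_terms
        }
    else:
        retained = candidates
    core_graph = net.graph.subgraph(retained).copy()
    return CoreNetwork(
        parent=net,
        graph=core_graph,
        seed_tfs=set(seeds),
        hub_ranking=_rank_hubs(core_graph, hub_metric),
    )


def shared_edge_decomposition(
    merged: CoexpressionNetwork,
) -> dict[frozenset[str], int]:
    """Partition a merged network's edges by their exact source set.

    Cells sum to the total edge count; quantifies condition-specific
    versus shared co-expression structure.
    """
    cells: dict[frozenset[str], int] = {}
    for _u, _v, data in merged.graph.edges(data=True):
        key = frozenset(data.get("source_conditions", frozenset()))
        cells[key] = cells.get(key, 0) + 1
    assert sum(cells.values()) == merged.n_edges
    return cells
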