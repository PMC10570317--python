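"""Per-condition gene co-expression networks by thresholded Pearson r.

A network is built over one condition's DEGs from the log-expression of
all that condition's samples (mock and treated, every time point): edges
are gene pairs whose Pearson correlation passes the threshold, r >= 0.9
by default. Signed mode (default) keeps only positive correlations at or
above the threshold; absolute mode keeps |r| >= threshold. Genes left
without any retained edge are dropped, so node counts can fall below DEG
counts.

The pairwise computation is blocked so networks over ~10^4 genes
(~10^8 candidate pairs) stay within a bounded memory footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = ["CoexpressionNetwork", "build_gcn", "network_stats", "NetworkStats"]

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionNetwork:
    """Undirected gene graph with per-edge correlations.

    ``graph`` node attributes: is_tf (bool), go_terms (frozenset),
    source_conditions (frozenset of condition labels). Edge attributes:
    r (representative correlation: largest magnitude across sources),
    r_by_source (dict condition -> r), source_conditions (frozenset).
    """

    graph: nx.Graph
    r_threshold: float
    mode: str = "signed"

    def __post_init__(self) -> None:
        if self.mode not in ("signed", "absolute"):
            raise ValueError(f"unknown correlation mode {self.mode!r}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def annotate_nodes(self, annotation: pd.DataFrame) -> None:
        """Attach is_tf / go_terms node attributes from an annotation table."""
        for node in self.graph.nodes:
            if node in annotation.index:
                self.graph.nodes[node]["is_tf"] = bool(annotation.loc[node, "is_tf"])
                self.graph.nodes[node]["go_terms"] = frozenset(
                    annotation.loc[node, "go_terms"]
                )

    def same_parameters(self, other: "CoexpressionNetwork") -> bool:
        return self.r_threshold == other.r_threshold and self.mode == other.mode


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    degree: dict[str, int] = field(default_factory=dict)
    degree_distribution: dict[int, int] = field(default_factory=dict)


def _edge_passes(r: float, threshold: float, mode: str) -> bool:
    if mode == "signed":
        return r >= threshold
    return abs(r) >= threshold


def build_gcn(
    expr: ExpressionMatrix,
    deg_genes: Iterable[str],
    r_threshold: float = 0.9,
    mode: str = "signed",
    source: str | None = None,
    block_size: int = 2000,
) -> CoexpressionNetwork:
    """Build a co-expression network over ``deg_genes``.

    Parameters
    ----------
    expr : expression matrix restricted to one condition's samples
        (log-transformed expression is expected).
    deg_genes : genes to correlate; must be a subset of the matrix genes.
    r_threshold : edge retention threshold in (0, 1), inclusive comparison.
    mode : ``signed`` keeps r >= threshold; ``absolute`` keeps |r| >= it.
    source : condition label recorded on nodes and edges.
    block_size : genes per block in the pairwise correlation loop.

    Zero-variance genes are excluded before correlation; nodes are the
    genes incident to at least one retained edge.
    """
    if expr.values.shape[1] < 3:
        raise ValueError("co-expression needs >= 3 samples")
    if not 0.0 < r_threshold < 1.0:
        raise ValueError(f"r_threshold must be in (0, 1), got {r_threshold}")
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown correlation mode {mode!r}")
    genes = [g for g in dict.fromkeys(deg_genes)]
    unknown = set(genes) - set(expr.values.index)
    if unknown:
        raise ValueError(f"genes absent from expression matrix: {sorted(unknown)[:3]}")
    graph = nx.Graph()
    net = CoexpressionNetwork(graph=graph, r_threshold=r_threshold, mode=mode)
    if not genes:
        logger.warning("empty DEG set: returning empty network")
        return net

    X = expr.values.loc[genes].to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.info("excluding %d zero-variance genes", int((~keep).sum()))
    genes = [g for g, k in zip(genes, keep) if k]
    X = X[keep]
    n = len(genes)
    if n < 2:
        return net

    # standardize rows so blockwise dot products are Pearson correlations
    Z = (X - X.mean(axis=1, keepdims=True)) / (X.std(axis=1, keepdims=True) * np.sqrt(X.shape[1]))
    src = frozenset() if source is None else frozenset({source})
    for i0 in range(0, n, block_size):
        i1 = min(i0 + block_size, n)
        for j0 in range(i0, n, block_size):
            j1 = min(j0 + block_size, n)
            R = Z[i0:i1] @ Z[j0:j1].T
            np.clip(R, -1.0, 1.0, out=R)
            if mode == "signed":
                ii, jj = np.nonzero(R >= r_threshold)
            else:
                ii, jj = np.nonzero(np.abs(R) >= r_threshold)
            for a, b in zip(ii, jj):
                gi, gj = i0 + a, j0 + b
                if gi >= gj:  # upper triangle only; skips self-pairs
                    continue
                r = float(R[a, b])
                u, v = genes[gi], genes[gj]
                graph.add_edge(
                    u,
                    v,
                    r=r,
                    r_by_source={source: r} if source is not None else {},
                    source_conditions=src,
                )
    for node in graph.nodes:
        graph.nodes[node].setdefault("is_tf", False)
        graph.nodes[node].setdefault("go_terms", frozenset())
        graph.nodes[node]["source_conditions"] = src
    return net


def network_stats(net: CoexpressionNetwork) -> NetworkStats:
    """Node/edge counts, per-node degree, and the degree histogram."""
    degree = {n: d for n, d in net.graph.degree()}
    dist: dict[int, int] = {}
    for d in degree.values():
        dist[d] = dist.get(d, 0) + 1
    return NetworkStats(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        degree=degree,
        degree_distribution=dict(sorted(dist.items())),
    )
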