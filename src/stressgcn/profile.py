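"""Z-score expression profiling of core-network genes and clustering.

Group-mean expression (one column per condition/time-point group) is
standardized per gene — population standard deviation, constant rows set
to zero — and the standardized profiles are grouped into k clusters
(hierarchical Ward by default, seeded k-means as an alternative). The
heatmap orders rows by cluster, then by dendrogram leaf order within the
cluster, with a TF indicator track mirroring the red TF column of
published stress-network heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

__all__ = ["ZScoreMatrix", "ClusterAssignment", "zscore", "cluster_profiles", "render_heatmap"]

logger = logging.getLogger(__name__)


@dataclass
class ZScoreMatrix:
    """Per-gene standardized group-mean expression (gene x group)."""

    values: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def groups(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]  # gene -> cluster id in 1..k
    k: int
    method: str
    linkage: np.ndarray | None = None  # scipy linkage record for hierarchical
    genes: list[str] = field(default_factory=list)

    def members(self, cluster_id: int) -> list[str]:
        return [g for g in self.genes if self.assignment[g] == cluster_id]


def zscore(group_mean_matrix: pd.DataFrame) -> ZScoreMatrix:
    """Row-standardize group means: (x - row mean) / row sd (population).

    Constant rows become all zeros (logged); needs >= 2 groups.
    """
    if group_mean_matrix.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 groups")
    X = group_mean_matrix.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    # exact-range check: a row of identical values can still have sd ~ 1e-16
    constant = X.max(axis=1) == X.min(axis=1)
    if constant.any():
        logger.info("%d constant rows set to zero in z-score matrix", int(constant.sum()))
    sd[constant, :] = 1.0
    Z = (X - mean) / sd
    Z[constant] = 0.0
    return ZScoreMatrix(
        pd.DataFrame(Z, index=group_mean_matrix.index, columns=group_mean_matrix.columns)
    )


def cluster_profiles(
    z: ZScoreMatrix, k: int, method: str = "hierarchical_ward", seed: int = 0
) -> ClusterAssignment:
    """Group standardized profiles into k clusters.

    hierarchical_ward: Euclidean distance, Ward linkage, tree cut at k.
    kmeans: seeded with 10 restarts, best inertia. Cluster ids are
    relabelled 1..k in order of first appearance along the gene list so the
    labelling is deterministic.
    """
    n = len(z.genes)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    X = z.values.to_numpy(dtype=float)
    linkage = None
    if method == "hierarchical_ward":
        linkage = hierarchy.linkage(X, method="ward", metric="euclidean")
        raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    elif method == "kmeans":
        model = KMeans(n_clusters=k, n_init=10, random_state=seed)
        raw = model.fit_predict(X) + 1
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for gene, label in zip(z.genes, raw):
        if label not in relabel:
            relabel[label] = len(relabel) + 1
        assignment[gene] = relabel[label]
    if len(relabel) != k:
        raise RuntimeError(f"clustering produced {len(relabel)} nonempty clusters, expected {k}")
    return ClusterAssignment(
        assignment=assignment, k=k, method=method, linkage=linkage, genes=list(z.genes)
    )


def ordered_genes(z: ZScoreMatrix, clusters: ClusterAssignment) -> list[str]:
    """Row order for display: by cluster, then dendrogram leaf order within.

    For k-means (no tree) rows within a cluster keep a per-cluster Ward
    leaf order computed on the fly, so the ordering is always deterministic.
    """
    order: list[str] = []
    gene_pos = {g: i for i, g in enumerate(z.genes)}
    X = z.values.to_numpy(dtype=float)
    for cid in range(1, clusters.k + 1):
        members = clusters.members(cid)
        if len(members) <= 2:
            order.extend(sorted(members, key=gene_pos.get))
            continue
        sub = X[[gene_pos[g] for g in members]]
        link = hierarchy.linkage(sub, method="ward", metric="euclidean")
        leaves = hierarchy.leaves_list(link)
        order.extend(members[i] for i in leaves)
    return order


def render_heatmap(
    z: ZScoreMatrix,
    clusters: ClusterAssignment,
    tf_genes: Iterable[str],
    out_path: str | Path,
) -> list[str]:
    """Write a clustered Z-score heatmap with a TF indicator track.

    Returns the row (gene) order used, top to bottom, so callers can
    record it for reproducibility checks.
    """
    if not z.genes:
        raise ValueError("nothing to render: empty gene list")
    missing = set(z.genes) - set(clusters.assignment)
    if missing:
        raise ValueError(f"clusters do not cover genes: {sorted(missing)[:3]}")
    tf_genes = set(tf_genes)
    order = ordered_genes(z, clusters)
    data = z.values.loc[order]

    fig_h = max(3.0, 0.12 * len(order) + 1.5)
    fig, (ax_hm, ax_tf) = plt.subplots(
        1, 2, figsize=(0.6 * len(z.groups) + 4, fig_h),
        gridspec_kw={"width_ratios": [20, 1]}, constrained_layout=True,
    )
    vmax = max(1.0, float(np.abs(data.to_numpy()).max()))
    im = ax_hm.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax_hm.set_xticks(range(len(z.groups)))
    ax_hm.set_xticklabels(z.groups, rotation=90, fontsize=6)
    ax_hm.set_yticks([])
    ax_hm.set_ylabel("genes (by cluster)")
    fig.colorbar(im, ax=ax_hm, shrink=0.6, label="Z-score")

    tf_track = np.array([[1.0 if g in tf_genes else 0.0] for g in order])
    ax_tf.imshow(tf_track, aspect="auto", cmap=matplotlib.colors.ListedColormap(["#f0f0f0", "#d62728"]), vmin=0, vmax=1)
    ax_tf.set_xticks([0])
    ax_tf.set_xticklabels(["TF"], fontsize=6)
    ax_tf.set_yticks([])

    # cluster boundaries
    boundary = 0
    for cid in range(1, clusters.k):
        boundary += len(clusters.members(cid))
        ax_hm.axhline(boundary - 0.5, color="black", linewidth=0.6)

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return order
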