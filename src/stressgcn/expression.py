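"""FPKM normalization, group-mean profiles and sample-level PCA.

Correlation and PCA downstream operate on log2(FPKM + 1) by default:
variance stabilization is standard practice for expression correlation.
Per-sample totals for FPKM are computed over the analyzed gene set,
not over aligner-reported mapped reads, which are unavailable once the
pipeline starts from a count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .synthetic_data import CountExperiment

__all__ = ["ExpressionMatrix", "PcaResult", "fpkm", "log_transform", "pca", "group_means"]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a log-transform flag."""

    values: pd.DataFrame
    log_transformed: bool = False
    samples: pd.DataFrame | None = None  # sample metadata carried from the source

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if not self.log_transformed and (arr < 0).any():
            raise ValueError("non-log expression values must be nonnegative")

    def restrict_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        sub = self.values.loc[:, sample_ids]
        meta = self.samples.loc[sample_ids] if self.samples is not None else None
        return ExpressionMatrix(sub, self.log_transformed, meta)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # sample x component, columns PC1..PCk
    explained_variance_ratio: np.ndarray
    n_components: int


def fpkm(exp: CountExperiment) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[g, s] = counts[g, s] / ((length_bp[g] / 1e3) * (total[s] / 1e6))
    with total[s] the column sum over the analyzed genes.
    """
    totals = exp.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    lengths = exp.gene_lengths.loc[exp.counts.index]
    kb = lengths.to_numpy(dtype=float)[:, None] / 1e3
    millions = totals.to_numpy(dtype=float)[None, :] / 1e6
    vals = exp.counts.to_numpy(dtype=float) / (kb * millions)
    out = pd.DataFrame(vals, index=exp.counts.index, columns=exp.counts.columns)
    return ExpressionMatrix(out, log_transformed=False, samples=exp.samples)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount); refuses to double-transform."""
    if m.log_transformed:
        raise ValueError("matrix is already log-transformed")
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    vals = np.log2(m.values + pseudocount)
    return ExpressionMatrix(vals, log_transformed=True, samples=m.samples)


def pca(m: ExpressionMatrix, n_components: int = 2, scale: bool = False) -> PcaResult:
    """PCA with samples as observations and genes as (centered) features.

    Genes are mean-centered before decomposition; with ``scale`` they are
    additionally divided by their standard deviation (constant genes are
    left centered only). Scores are ordered by decreasing explained
    variance.
    """
    n_samples = m.values.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_comp = min(m.values.shape[0], n_samples - 1)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    X = m.values.to_numpy(dtype=float).T  # samples x genes
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.values.columns, columns=cols),
        explained_variance_ratio=model.explained_variance_ratio_,
        n_components=n_components,
    )


def group_means(
    m: ExpressionMatrix,
    samples: pd.DataFrame | None = None,
    by: tuple[str, ...] = ("condition", "time_point", "arm"),
) -> pd.DataFrame:
    """Arithmetic mean over the replicate columns of each sample group.

    Groups are ordered lexicographically by the ``by`` keys. Column labels
    join the key values with ``:``. Every sample must belong to exactly one
    group and every group must be nonempty.
    """
    meta = samples if samples is not None else m.samples
    if meta is None:
        raise ValueError("no sample metadata available for grouping")
    missing = m.values.columns.difference(meta.index)
    if len(missing):
        raise ValueError(f"samples without metadata: {list(missing[:3])}")
    meta = meta.loc[m.values.columns]
    keys = [tuple(rec) for rec in meta[list(by)].itertuples(index=False)]
    groups: dict[tuple, list[str]] = {}
    for sid, key in zip(m.values.columns, keys):
        groups.setdefault(key, []).append(sid)
    out = {}
    for key in sorted(groups):
        cols = groups[key]
        if not cols:
            raise ValueError(f"empty group {key}")
        out[":".join(map(str, key))] = m.values[cols].mean(axis=1)
    return pd.DataFrame(out, index=m.values.index)
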