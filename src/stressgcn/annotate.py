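"""TF/GO annotation handling and GO over-representation analysis.

GO terms are treated as flat labels as supplied in the annotation table;
no ontology-DAG ancestor propagation is performed (pre-expand the filter
set with descendants externally if needed). Enrichment is one-sided
over-representation: a hypergeometric tail by default, or a
length-weighted Monte-Carlo null that emulates the read-count length bias
correction of RNA-seq enrichment tools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_adjust

__all__ = ["read_annotation", "enrich", "stress_go_filter", "EnrichmentRow"]

GO_PATTERN = re.compile(r"^GO:\d{7}$")


@dataclass
class EnrichmentRow:
    go_id: str
    k: int  # hits in set
    K: int  # hits in background
    n: int  # set size
    N: int  # background size
    p_value: float
    fdr: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise ValueError(
                f"inconsistent contingency for {self.go_id}: "
                f"k={self.k} K={self.K} n={self.n} N={self.N}"
            )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read an annotation TSV into a gene-indexed DataFrame.

    Expected columns: gene_id, length_bp, is_tf (0/1), tf_family,
    go_terms (semicolon-separated GO ids). go_terms becomes a frozenset;
    malformed GO ids raise with the 1-based data line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tf_family": str})
    required = ["gene_id", "length_bp", "is_tf", "tf_family", "go_terms"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"annotation file {path} is missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    terms = []
    for lineno, raw in enumerate(df["go_terms"].fillna(""), start=2):
        ids = [t for t in str(raw).split(";") if t]
        for t in ids:
            if not GO_PATTERN.match(t):
                raise ValueError(f"{path}:{lineno}: malformed GO id {t!r}")
        terms.append(frozenset(ids))
    out = pd.DataFrame(
        {
            "length_bp": df["length_bp"].astype(int).to_numpy(),
            "is_tf": df["is_tf"].astype(bool).to_numpy(),
            "tf_family": df["tf_family"].fillna("").to_numpy(),
            "go_terms": terms,
        },
        index=pd.Index(df["gene_id"], name="gene_id"),
    )
    if (out["length_bp"] < 1).any():
        bad = out.index[out["length_bp"] < 1][0]
        raise ValueError(f"gene length < 1 bp for {bad!r}")
    return out


def stress_go_filter(ann: pd.DataFrame, filter_terms: Iterable[str]) -> set[str]:
    """Genes whose GO annotation intersects ``filter_terms``."""
    filter_terms = set(filter_terms)
    if not filter_terms:
        raise ValueError("filter_terms must be nonempty")
    return {g for g, terms in ann["go_terms"].items() if terms & filter_terms}


def _length_weights(ann: pd.DataFrame, background: list[str], in_set: np.ndarray) -> np.ndarray:
    """Logistic fit of set membership on gene length -> sampling weights.

    Mirrors the spirit of length-bias correction: longer genes are more
    likely to be detected, so the null resamples genes with probability
    proportional to the fitted membership probability at their length.
    """
    lengths = ann.loc[background, "length_bp"].to_numpy(dtype=float)
    x = np.log(lengths)
    x = (x - x.mean()) / (x.std() or 1.0)
    # simple Newton-IRLS logistic regression on one covariate
    beta = np.zeros(2)
    X = np.column_stack([np.ones_like(x), x])
    y = in_set.astype(float)
    for _ in range(25):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(hess + 1e-8 * np.eye(2), grad)
        except np.linalg.LinAlgError:
            break
        beta += step
        if np.abs(step).max() < 1e-10:
            break
    weights = 1.0 / (1.0 + np.exp(-(X @ beta)))
    weights = np.clip(weights, 1e-6, None)
    return weights / weights.sum()


def enrich(
    gene_set: Iterable[str],
    background: Iterable[str],
    ann: pd.DataFrame,
    method: str = "hypergeometric",
    n_draws: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentRow]:
    """One-sided GO over-representation of ``gene_set`` versus ``background``.

    hypergeometric: p = P(X >= k) for X ~ Hypergeom(N, K, n).
    length_weighted: the null draws gene sets of size n with probability
    proportional to a logistic fit of set membership on log length, and
    p = (1 + #{draws with k* >= k}) / (n_draws + 1).

    Rows are BH-adjusted across terms and sorted by (p, GO id).
    """
    gene_set = set(gene_set)
    background_list = sorted(set(background))
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    if not gene_set <= set(background_list):
        raise ValueError("gene_set must be a subset of background")
    missing = set(background_list) - set(ann.index)
    if missing:
        raise ValueError(f"background genes without annotation: {sorted(missing)[:3]}")
    if method not in ("hypergeometric", "length_weighted"):
        raise ValueError(f"unknown enrichment method {method!r}")

    N = len(background_list)
    n = len(gene_set)
    term_members: dict[str, set[str]] = {}
    for g in background_list:
        for t in ann.loc[g, "go_terms"]:
            term_members.setdefault(t, set()).add(g)

    in_set = np.array([g in gene_set for g in background_list])
    if method == "length_weighted":
        weights = _length_weights(ann, background_list, in_set)
        rng = np.random.default_rng(seed)
        idx = np.arange(N)
        draws = np.stack(
            [rng.choice(idx, size=n, replace=False, p=weights) for _ in range(n_draws)]
        )
        member_mask = {
            t: np.isin(np.arange(N), [background_list.index(g) for g in members])
            for t, members in term_members.items()
        }

    rows = []
    for t in sorted(term_members):
        members = term_members[t]
        K = len(members)
        k = len(members & gene_set)
        if method == "hypergeometric":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            null_k = member_mask[t][draws].sum(axis=1)
            p = float((1 + (null_k >= k).sum()) / (n_draws + 1))
        rows.append(EnrichmentRow(go_id=t, k=k, K=K, n=n, N=N, p_value=min(p, 1.0)))
    if rows:
        fdrs = bh_adjust([r.p_value for r in rows])
        for r, f in zip(rows, fdrs):
            r.fdr = float(f)
    rows.sort(key=lambda r: (r.p_value, r.go_id))
    return rows
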