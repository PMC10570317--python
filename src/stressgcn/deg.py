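"""Differential expression calling against matched mocks.

Each (condition, time point) comparison is tested independently: DESeq-style
median-of-ratios size factors, per-gene method-of-moments negative-binomial
dispersion, a Wald test on the difference of log group means with NB
variance propagated by the delta method, and Benjamini-Hochberg adjustment
within the comparison. A gene is a DEG of a condition if it passes the
fold-change and FDR cutoffs at any time point of that condition.

Defaults: |log2FC| > 1 and FDR < 0.05.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import CountExperiment

__all__ = [
    "DegTable",
    "VennPartition",
    "estimate_size_factors",
    "estimate_dispersion",
    "test_gene",
    "call_degs",
    "bh_adjust",
    "venn_partition",
]

logger = logging.getLogger(__name__)

#: floor for method-of-moments dispersion estimates
ALPHA_MIN = 1e-8
#: pseudocount, in normalized-count units, in the log2 fold change
LFC_PSEUDOCOUNT = 0.5


@dataclass
class DegTable:
    """Per-(condition, time point) differential-expression results.

    ``table`` has one row per (gene, condition, time_point) with columns
    gene_id, condition, time_point, log2fc, p_value, fdr, is_deg.
    """

    table: pd.DataFrame
    log2fc_cutoff: float = 1.0
    fdr_cutoff: float = 0.05

    def deg_genes(self, condition: str | None = None) -> set[str]:
        """Genes flagged is_deg at any time point (of one condition if given)."""
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        return set(t.loc[t["is_deg"], "gene_id"])

    def deg_sets_by_condition(self) -> dict[str, set[str]]:
        return {c: self.deg_genes(c) for c in self.table["condition"].unique()}


@dataclass
class VennPartition:
    """Exclusive-subset DEG counts over condition combinations."""

    cells: dict[frozenset[str], int]
    universe_size: int
    conditions: tuple[str, ...] = ()

    def total(self) -> int:
        return sum(self.cells.values())


def estimate_size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with a positive geometric mean across samples (i.e. nonzero
    in every sample) enter the median. If no such gene exists the estimate
    falls back to total-count ratios with a logged warning.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 1:
        raise ValueError("counts must be a gene x sample matrix")
    if (arr.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one nonzero count")
    with np.errstate(divide="ignore"):
        log_counts = np.log(arr)
    all_positive = np.isfinite(log_counts).all(axis=1)
    if all_positive.any():
        log_geomean = log_counts[all_positive].mean(axis=1)
        ratios = log_counts[all_positive] - log_geomean[:, None]
        log_factors = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no gene with all-positive counts; falling back to total-count ratios"
        )
        log_factors = np.log(arr.sum(axis=0))
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return np.exp(log_factors)


def estimate_dispersion(
    counts: pd.DataFrame | np.ndarray,
    size_factors: np.ndarray,
    arms: np.ndarray | list[str] | None = None,
) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion on normalized counts.

    The arm-mean difference is removed before pooling the residual variance
    (so a true treatment effect does not inflate the dispersion):
    alpha = max((var - mu) / mu^2, ALPHA_MIN) with mu the grand mean of the
    normalized counts and var the pooled within-arm variance.
    """
    arr = np.asarray(counts, dtype=float)
    n = arr.shape[1]
    if n < 3:
        raise ValueError("dispersion estimation needs >= 3 samples")
    y = arr / np.asarray(size_factors, dtype=float)[None, :]
    if arms is None:
        arm_labels = np.zeros(n, dtype=int)
    else:
        _, arm_labels = np.unique(np.asarray(arms), return_inverse=True)
    n_arms = len(np.unique(arm_labels))
    resid = np.empty_like(y)
    for a in np.unique(arm_labels):
        cols = arm_labels == a
        resid[:, cols] = y[:, cols] - y[:, cols].mean(axis=1, keepdims=True)
    dof = max(n - n_arms, 1)
    var = (resid**2).sum(axis=1) / dof
    mu = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, ALPHA_MIN)
    return np.maximum(alpha, ALPHA_MIN)


def test_gene(
    treated: np.ndarray,
    mock: np.ndarray,
    size_factors_treated: np.ndarray,
    size_factors_mock: np.ndarray,
    dispersion: float,
) -> tuple[float, float]:
    """Wald test of treated vs mock for one gene.

    log2fc = log2((mean normalized treated + c) / (mean normalized mock + c))
    with c = 0.5 normalized counts. The variance of each arm mean uses the
    NB relation Var = mu + alpha mu^2 on the normalized scale, propagated
    to the log2 scale by the delta method; the Wald statistic is referred
    to a t distribution with n_t + n_m - 2 degrees of freedom (small-sample
    reference; see docs). All-zero genes return (0.0, 1.0).
    """
    t = np.asarray(treated, dtype=float) / np.asarray(size_factors_treated, dtype=float)
    m = np.asarray(mock, dtype=float) / np.asarray(size_factors_mock, dtype=float)
    if len(t) < 1 or len(m) < 1:
        raise ValueError("each arm needs at least one sample")
    if t.sum() == 0 and m.sum() == 0:
        return 0.0, 1.0
    c = LFC_PSEUDOCOUNT
    mt, mm = t.mean(), m.mean()
    log2fc = math.log2((mt + c) / (mm + c))
    alpha = max(float(dispersion), ALPHA_MIN)
    # delta method: Var(log2(mean + c)) = Var(mean) / ((mean + c) ln 2)^2
    var_t = (mt + alpha * mt**2) / len(t) / ((mt + c) * math.log(2)) ** 2
    var_m = (mm + alpha * mm**2) / len(m) / ((mm + c) * math.log(2)) ** 2
    se = math.sqrt(var_t + var_m)
    if se == 0.0:
        return log2fc, 1.0 if log2fc == 0.0 else 0.0
    wald = log2fc / se
    df = max(len(t) + len(m) - 2, 1)
    p = 2.0 * stats.t.sf(abs(wald), df=df)
    return log2fc, min(p, 1.0)


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return fdr


def call_degs(
    exp: CountExperiment,
    condition: str,
    log2fc_cutoff: float = 1.0,
    fdr_cutoff: float = 0.05,
) -> DegTable:
    """Call DEGs for one condition: each time point versus its mock.

    For every time point with both arms present, size factors and
    dispersions are estimated on that comparison's samples only, each gene
    is Wald-tested, and p-values are BH-adjusted within the comparison.
    """
    tps = [
        tp
        for tp in dict.fromkeys(exp.samples.loc[exp.samples["condition"] == condition, "time_point"])
    ]
    if not tps:
        raise ValueError(f"condition {condition!r} has no samples")
    rows = []
    for tp in tps:
        mock_ids = exp.samples_of(condition, tp, "mock")
        treat_ids = exp.samples_of(condition, tp, "treated")
        if not mock_ids:
            raise ValueError(f"no mock samples for {condition!r} at {tp!r}")
        if not treat_ids:
            raise ValueError(f"no treated samples for {condition!r} at {tp!r}")
        sub = exp.counts[mock_ids + treat_ids]
        sf = estimate_size_factors(sub)
        arms = np.array(["mock"] * len(mock_ids) + ["treated"] * len(treat_ids))
        disp = estimate_dispersion(sub, sf, arms)
        sf_mock, sf_treat = sf[: len(mock_ids)], sf[len(mock_ids):]
        cnt = sub.to_numpy(dtype=float)
        lfcs = np.empty(len(sub))
        pvals = np.empty(len(sub))
        for gi in range(len(sub)):
            lfcs[gi], pvals[gi] = test_gene(
                cnt[gi, len(mock_ids):], cnt[gi, : len(mock_ids)], sf_treat, sf_mock, disp[gi]
            )
        fdr = bh_adjust(pvals)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": sub.index,
                    "condition": condition,
                    "time_point": tp,
                    "log2fc": lfcs,
                    "p_value": pvals,
                    "fdr": fdr,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["is_deg"] = (table["log2fc"].abs() > log2fc_cutoff) & (table["fdr"] < fdr_cutoff)
    return DegTable(table=table, log2fc_cutoff=log2fc_cutoff, fdr_cutoff=fdr_cutoff)


def call_degs_all(
    exp: CountExperiment, log2fc_cutoff: float = 1.0, fdr_cutoff: float = 0.05
) -> DegTable:
    """Concatenate :func:`call_degs` over every condition in the experiment."""
    tables = [
        call_degs(exp, cond, log2fc_cutoff, fdr_cutoff).table for cond in exp.conditions
    ]
    return DegTable(
        table=pd.concat(tables, ignore_index=True),
        log2fc_cutoff=log2fc_cutoff,
        fdr_cutoff=fdr_cutoff,
    )


def venn_partition(deg_sets: dict[str, set[str]]) -> VennPartition:
    """Exact exclusive-subset counts over all nonempty condition subsets.

    Cell S counts genes that are DEGs in exactly the conditions of S; the
    cells partition the union of the per-condition DEG sets.
    """
    conditions = sorted(deg_sets)
    if len(conditions) < 2:
        raise ValueError("venn partition needs >= 2 condition sets")
    if len(conditions) > 8:
        raise ValueError(f"{len(conditions)} sets exceed the 8-set guard")
    universe: set[str] = set().union(*deg_sets.values())
    cells: dict[frozenset[str], int] = {}
    for r in range(1, len(conditions) + 1):
        for combo in itertools.combinations(conditions, r):
            cells[frozenset(combo)] = 0
    for gene in universe:
        member = frozenset(c for c in conditions if gene in deg_sets[c])
        cells[member] += 1
    assert sum(cells.values()) == len(universe)
    return VennPartition(
        cells=cells, universe_size=len(universe), conditions=tuple(conditions)
    )
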