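"""Synthetic multi-stress RNA-seq experiments with planted ground truth.

The generator emulates the statistical structure a stress co-expression
study assumes: several stress conditions, each with mock and treated arms
sampled over time points; negative-binomial counts; a subset of genes
differentially expressed per condition; co-expression modules driven by a
shared latent factor, each organized around a designated transcription
factor (TF) hub; and a set of genes carrying a stress-response GO label.

Every downstream stage (FPKM, DEG calling, network construction, core
reconstruction, profiling) can therefore be scored against a known truth
ledger without touching any external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "CountExperiment",
    "generate_experiment",
    "write_experiment",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic multi-condition count experiment.

    Attributes
    ----------
    n_genes : total number of genes simulated.
    n_conditions : number of stress conditions; each gets mock and treated
        arms at every time point.
    time_points : ordered time-point labels shared by all conditions.
    n_replicates : replicates per (condition, time point, arm).
    baseline_mean_log2_range : (low, high) of the per-gene baseline
        expression drawn uniformly on the log2 scale.
    nb_dispersion : negative-binomial dispersion alpha, so that
        Var = mu + alpha * mu**2.
    n_modules : number of planted co-expression modules.
    module_size_range : (low, high) genes per module, inclusive.
    module_latent_sd : standard deviation of the per-sample module latent
        factor (log2 units); larger values tighten within-module correlation.
    module_latent_within_group_sd : fraction of the latent factor's unit
        variance realized as per-sample jitter; the rest is shared by all
        replicates of a (condition, time point) group, mock and treated
        alike, emulating a coordinated time-course response.
    module_noise_sd : standard deviation of gene-specific log2 noise added
        on top of the latent signal.
    hub_noise_frac : the hub TF's gene-specific noise as a fraction of
        module_noise_sd; the hub drives the module, so it tracks the
        latent factor with the largest loading and the highest
        communality, and its hubness must still emerge from the built
        network.
    de_fraction : fraction of genes planted as differentially expressed in
        each condition (module members of a condition's modules count
        toward this fraction).
    de_log2fc_range : (low, high) magnitude of the planted log2 fold change;
        the sign is chosen at random per gene (per module for module
        members, whose realized magnitude is loading x module shift).
    tf_fraction : fraction of genes flagged as transcription factors
        (module hubs are always TFs, on top of this fraction).
    stress_go_fraction : fraction of non-module genes carrying the stress
        GO label; module members carry it with probability
        ``module_go_prob``.
    module_go_prob : probability that a module member is GO-labelled
        (default 1.0, so core reconstruction can find whole modules).
    gene_length_range : (low, high) transcript length in bp.
    library_size_range : (low, high) per-sample library size in fragments;
        drawn log-uniformly to exercise depth normalization.
    stress_go_term : the GO identifier used as the stress label.
    seed : master seed; identical parameters and seed give byte-identical
        experiments.
    """

    n_genes: int = 1000
    n_conditions: int = 3
    time_points: tuple[str, ...] = ("6h", "12h", "24h")
    n_replicates: int = 3
    baseline_mean_log2_range: tuple[float, float] = (5.0, 10.0)
    nb_dispersion: float = 0.02
    n_modules: int = 3
    module_size_range: tuple[int, int] = (15, 25)
    module_latent_sd: float = 1.0
    module_latent_within_group_sd: float = 0.3
    module_noise_sd: float = 0.3
    hub_noise_frac: float = 1 / 3
    de_fraction: float = 0.1
    de_log2fc_range: tuple[float, float] = (1.5, 3.0)
    tf_fraction: float = 0.1
    stress_go_fraction: float = 0.2
    module_go_prob: float = 1.0
    gene_length_range: tuple[int, int] = (500, 5000)
    library_size_range: tuple[int, int] = (1_000_000, 5_000_000)
    stress_go_term: str = "GO:0050896"
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated field."""
        for name in ("n_genes", "n_conditions", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_modules < 0:
            raise ValueError(f"n_modules must be >= 0, got {self.n_modules}")
        if not self.time_points:
            raise ValueError("time_points must be nonempty")
        for name in ("nb_dispersion", "module_latent_sd", "module_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.module_latent_within_group_sd <= 1.0:
            raise ValueError("module_latent_within_group_sd must be in [0, 1]")
        if not 0.0 <= self.hub_noise_frac <= 1.0:
            raise ValueError("hub_noise_frac must be in [0, 1]")
        for name in (
            "de_fraction",
            "tf_fraction",
            "stress_go_fraction",
            "module_go_prob",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for name in (
            "baseline_mean_log2_range",
            "module_size_range",
            "de_log2fc_range",
            "gene_length_range",
            "library_size_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} low {lo} exceeds high {hi}")
        if self.module_size_range[0] < 3 and self.n_modules > 0:
            raise ValueError("module_size_range low must be >= 3 (modules need >= 3 members)")
        if self.n_modules * self.module_size_range[1] > self.n_genes:
            raise ValueError(
                "module_size_range upper bound x n_modules exceeds n_genes "
                f"({self.module_size_range[1]} x {self.n_modules} > {self.n_genes})"
            )
        if self.gene_length_range[0] < 1:
            raise ValueError("gene_length_range low must be >= 1 bp")
        if self.library_size_range[0] < 1:
            raise ValueError("library_size_range low must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one generated experiment.

    ``module_membership`` maps gene id -> module id (genes outside every
    module are absent); ``hub_tf_of_module`` maps module id -> the TF
    carrying the largest latent loading; ``de_genes`` maps
    (condition, time_point) -> {gene id: signed log2FC}; ``go_annotated``
    and ``tf_genes`` are plain gene-id sets.
    """

    module_membership: dict[str, int] = field(default_factory=dict)
    hub_tf_of_module: dict[int, str] = field(default_factory=dict)
    de_genes: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    go_annotated: set[str] = field(default_factory=set)
    tf_genes: set[str] = field(default_factory=set)

    def validate(self) -> None:
        for mod, hub in self.hub_tf_of_module.items():
            if self.module_membership.get(hub) != mod:
                raise ValueError(f"hub {hub} is not a member of module {mod}")
            if hub not in self.tf_genes:
                raise ValueError(f"hub {hub} is not flagged as a TF")
        sizes: dict[int, int] = {}
        for mod in self.module_membership.values():
            sizes[mod] = sizes.get(mod, 0) + 1
        for mod, size in sizes.items():
            if size < 3:
                raise ValueError(f"module {mod} has only {size} members (>= 3 required)")

    def module_genes(self, module_id: int) -> set[str]:
        return {g for g, m in self.module_membership.items() if m == module_id}

    def de_genes_of_condition(self, condition: str) -> set[str]:
        """Union of planted DE genes over the condition's time points."""
        out: set[str] = set()
        for (cond, _tp), genes in self.de_genes.items():
            if cond == condition:
                out.update(genes)
        return out


@dataclass
class CountExperiment:
    """Raw counts plus sample metadata: the pipeline's entry point.

    ``counts`` is a gene x sample integer DataFrame; ``samples`` is indexed
    by sample id with columns condition, time_point, replicate, arm
    (arm in {mock, treated}); ``gene_lengths`` is a per-gene bp Series
    aligned with ``counts.index``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series
    #: synthetic provenance only: the latent log2 mean expression before
    #: count sampling (not written to disk, absent for real experiments)
    log2_mean: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in counts")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in counts")
        if list(self.samples.index) != list(self.counts.columns):
            raise ValueError("sample metadata does not match counts columns")
        missing = self.counts.index.difference(self.gene_lengths.index)
        if len(missing):
            raise ValueError(f"missing gene lengths for {list(missing[:3])}...")
        if (self.gene_lengths.loc[self.counts.index] < 1).any():
            bad = self.gene_lengths[self.gene_lengths < 1].index[0]
            raise ValueError(f"gene length < 1 bp for {bad}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(
        self,
        condition: str,
        time_point: str | None = None,
        arm: str | None = None,
    ) -> list[str]:
        mask = self.samples["condition"] == condition
        if time_point is not None:
            mask &= self.samples["time_point"] == time_point
        if arm is not None:
            mask &= self.samples["arm"] == arm
        return list(self.samples.index[mask])


def _sample_table(params: SimulationParams) -> pd.DataFrame:
    rows = []
    for ci in range(params.n_conditions):
        cond = f"stress{ci + 1}"
        for tp in params.time_points:
            for arm in ("mock", "treated"):
                for rep in range(1, params.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{cond}_{tp}_{arm}_r{rep}",
                            "condition": cond,
                            "time_point": tp,
                            "replicate": rep,
                            "arm": arm,
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def _plant_modules(
    params: SimulationParams, rng: np.random.Generator, gene_ids: list[str]
) -> tuple[dict[str, int], dict[int, str], dict[str, float]]:
    """Assign modules, pick hubs, and draw latent loadings.

    Loadings are positive (modules emulate co-regulated gene sets) and the
    hub receives the largest loading, so its hubness must emerge from the
    correlation structure rather than being wired into the graph.
    """
    membership: dict[str, int] = {}
    hubs: dict[int, str] = {}
    loadings: dict[str, float] = {}
    if params.n_modules == 0:
        return membership, hubs, loadings
    lo, hi = params.module_size_range
    sizes = rng.integers(lo, hi + 1, size=params.n_modules)
    pool = list(rng.permutation(gene_ids))
    for mod in range(1, params.n_modules + 1):
        members = [pool.pop() for _ in range(sizes[mod - 1])]
        lds = rng.uniform(0.6, 0.85, size=len(members))
        hub_idx = int(rng.integers(len(members)))
        lds[hub_idx] = 1.0  # hub carries the largest loading magnitude
        for g, l in zip(members, lds):
            membership[g] = mod
            loadings[g] = float(l)
        hubs[mod] = members[hub_idx]
    return membership, hubs, loadings


def generate_experiment(
    params: SimulationParams,
) -> tuple[CountExperiment, pd.DataFrame, SyntheticTruth]:
    """Generate counts, an annotation table, and the truth ledger.

    The expression model, on the log2 scale, for gene g in sample s is

        log2 mu[g, s] = baseline[g] + loading[g] * f[m(g), s] * latent_sd
                        + noise_sd * eps[g, s] + de_lfc[g, s]

    where f is the module latent factor drawn independently per sample
    (so co-expression spans mock/treated arms and time points) and
    de_lfc applies only in treated arms of the gene's assigned condition.
    Counts are drawn NB(mean = library-scaled expected fragments,
    dispersion = nb_dispersion) via a Gamma-Poisson mixture; each gene
    owns a pseudo-random stream keyed by (seed, gene index) so per-gene
    draws are reproducible under gene subsetting.

    Returns
    -------
    (CountExperiment, annotation DataFrame, SyntheticTruth)
        The annotation table is indexed by gene id with columns
        length_bp, is_tf, tf_family, go_terms (frozenset of GO ids).
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))

    gene_ids = [f"G{i:05d}" for i in range(params.n_genes)]
    samples = _sample_table(params)
    n_samples = len(samples)

    baseline = rng.uniform(*params.baseline_mean_log2_range, size=params.n_genes)
    membership, hubs, loadings = _plant_modules(params, rng, gene_ids)

    # TF flags: hubs are always TFs; additional TFs drawn at tf_fraction.
    tf_flags = rng.random(params.n_genes) < params.tf_fraction
    tf_genes = {g for g, f in zip(gene_ids, tf_flags) if f}
    tf_genes.update(hubs.values())

    # Stress-GO labels: module members with module_go_prob, background
    # genes with stress_go_fraction.
    go_annotated: set[str] = set()
    for g in gene_ids:
        p = params.module_go_prob if g in membership else params.stress_go_fraction
        if rng.random() < p:
            go_annotated.add(g)

    # Planted DE. Each module is a stress-responsive regulon: it is
    # assigned to one condition (round-robin) and its latent factor is
    # shifted in that condition's treated arm, so a member's realized
    # log2FC is loading x module shift and module members are DEGs of
    # their own condition. Additional DE genes are drawn at random, with
    # an independent signed log2FC each, to fill de_fraction per condition.
    conditions = [f"stress{ci + 1}" for ci in range(params.n_conditions)]
    n_de = int(round(params.de_fraction * params.n_genes))
    de_genes: dict[tuple[str, str], dict[str, float]] = {}
    de_lookup: dict[tuple[str, str], float] = {}  # (gene, condition) -> lfc
    module_condition = {
        mod: conditions[(mod - 1) % params.n_conditions] for mod in hubs
    }
    module_shift = {
        mod: float(rng.choice([-1.0, 1.0]) * rng.uniform(*params.de_log2fc_range))
        for mod in hubs
    }
    for cond in conditions:
        ledger: dict[str, float] = {}
        for mod, mcond in module_condition.items():
            if mcond != cond:
                continue
            for g in (g for g, m in membership.items() if m == mod):
                ledger[g] = loadings[g] * module_shift[mod]
        candidates = [i for i, g in enumerate(gene_ids) if g not in ledger]
        n_extra = max(0, n_de - len(ledger))
        if n_extra > len(candidates):
            raise ValueError("de_fraction too large for the non-module gene pool")
        chosen = rng.choice(len(candidates), size=n_extra, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_extra)
        mags = rng.uniform(*params.de_log2fc_range, size=n_extra)
        for i, s, m in zip(chosen, signs, mags):
            ledger[gene_ids[candidates[i]]] = float(s * m)
        for tp in params.time_points:
            de_genes[(cond, tp)] = dict(ledger)
        for g, lfc in ledger.items():
            de_lookup[(g, cond)] = lfc

    # Module latent factors: unit-variance per sample, decomposed into a
    # component shared by all replicates of a (condition, time point)
    # group — mock and treated alike, so the treatment contrast stays
    # clean — plus per-sample jitter.
    w = params.module_latent_within_group_sd
    group_keys = list(zip(samples["condition"], samples["time_point"]))
    uniq_groups = list(dict.fromkeys(group_keys))
    group_idx = np.array([uniq_groups.index(k) for k in group_keys])
    group_draw = rng.normal(0.0, 1.0, size=(params.n_modules + 1, len(uniq_groups)))
    jitter = rng.normal(0.0, 1.0, size=(params.n_modules + 1, n_samples))
    latent = np.sqrt(max(0.0, 1.0 - w**2)) * group_draw[:, group_idx] + w * jitter

    # Per-gene log2 mean expression across samples.
    log2_mu = np.tile(baseline[:, None], (1, n_samples))
    sample_cond = samples["condition"].to_numpy()
    sample_arm = samples["arm"].to_numpy()
    noise = rng.normal(0.0, 1.0, size=(params.n_genes, n_samples))
    hub_set = set(hubs.values())
    for gi, g in enumerate(gene_ids):
        mod = membership.get(g)
        if mod is not None:
            noise_sd = params.module_noise_sd * (
                params.hub_noise_frac if g in hub_set else 1.0
            )
            log2_mu[gi] += (
                loadings[g] * params.module_latent_sd * latent[mod]
                + noise_sd * noise[gi]
            )
    treated_mask = sample_arm == "treated"
    for gi, g in enumerate(gene_ids):
        for cond in conditions:
            lfc = de_lookup.get((g, cond))
            if lfc is not None:
                log2_mu[gi, treated_mask & (sample_cond == cond)] += lfc

    lengths = rng.integers(
        params.gene_length_range[0], params.gene_length_range[1] + 1, size=params.n_genes
    )
    lib_lo, lib_hi = params.library_size_range
    lib_sizes = np.exp(rng.uniform(np.log(lib_lo), np.log(lib_hi), size=n_samples))

    # Expected fragment counts: relative abundance weighted by transcript
    # length (fragment yield scales with length), scaled to library size.
    expr = np.exp2(log2_mu)
    weights = expr * (lengths[:, None] / 1000.0)
    mu = weights / weights.sum(axis=0, keepdims=True) * lib_sizes[None, :]

    counts = np.empty((params.n_genes, n_samples), dtype=np.int64)
    alpha = params.nb_dispersion
    for gi in range(params.n_genes):
        gene_rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(gi,)))
        row_mu = mu[gi]
        if alpha > 0:
            lam = gene_rng.gamma(shape=1.0 / alpha, scale=alpha * row_mu)
            counts[gi] = gene_rng.poisson(lam)
        else:
            counts[gi] = gene_rng.poisson(row_mu)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples.index)
    lengths_s = pd.Series(lengths, index=gene_ids, name="length_bp")
    exp = CountExperiment(
        counts=counts_df,
        samples=samples,
        gene_lengths=lengths_s,
        log2_mean=pd.DataFrame(log2_mu, index=gene_ids, columns=samples.index),
    )

    ann = pd.DataFrame(
        {
            "length_bp": lengths_s,
            "is_tf": [g in tf_genes for g in gene_ids],
            "tf_family": [
                f"TF_FAM{(i % 5) + 1}" if g in tf_genes else ""
                for i, g in enumerate(gene_ids)
            ],
            "go_terms": [
                frozenset({params.stress_go_term}) if g in go_annotated else frozenset()
                for g in gene_ids
            ],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    truth = SyntheticTruth(
        module_membership=membership,
        hub_tf_of_module=hubs,
        de_genes=de_genes,
        go_annotated=go_annotated,
        tf_genes=tf_genes,
    )
    truth.validate()
    return exp, ann, truth


def _truth_to_json(truth: SyntheticTruth) -> dict:
    return {
        "module_membership": dict(sorted(truth.module_membership.items())),
        "hub_tf_of_module": {str(k): v for k, v in sorted(truth.hub_tf_of_module.items())},
        "de_genes": [
            {
                "condition": cond,
                "time_point": tp,
                "genes": dict(sorted(genes.items())),
            }
            for (cond, tp), genes in sorted(truth.de_genes.items())
        ],
        "go_annotated": sorted(truth.go_annotated),
        "tf_genes": sorted(truth.tf_genes),
    }


def truth_from_json(obj: Mapping) -> SyntheticTruth:
    truth = SyntheticTruth(
        module_membership={g: int(m) for g, m in obj["module_membership"].items()},
        hub_tf_of_module={int(k): v for k, v in obj["hub_tf_of_module"].items()},
        de_genes={
            (entry["condition"], entry["time_point"]): {
                g: float(v) for g, v in entry["genes"].items()
            }
            for entry in obj["de_genes"]
        },
        go_annotated=set(obj["go_annotated"]),
        tf_genes=set(obj["tf_genes"]),
    )
    return truth


def write_experiment(
    exp: CountExperiment,
    ann: pd.DataFrame,
    truth: SyntheticTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write counts.tsv, samples.tsv, annotation.tsv and truth.json.

    The files round-trip losslessly through ``stressgcn.io_formats``
    readers. Returns a name -> path map of everything written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.tsv",
        "annotation": directory / "annotation.tsv",
        "truth": directory / "truth.json",
    }
    counts_out = exp.counts.copy()
    counts_out.index.name = "gene_id"
    counts_out.to_csv(paths["counts"], sep="\t", lineterminator="\n")
    exp.samples.to_csv(paths["samples"], sep="\t", lineterminator="\n")

    ann_out = ann.copy()
    ann_out["is_tf"] = ann_out["is_tf"].astype(int)
    ann_out["go_terms"] = [";".join(sorted(t)) for t in ann_out["go_terms"]]
    ann_out.index.name = "gene_id"
    ann_out.to_csv(paths["annotation"], sep="\t", lineterminator="\n")

    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(_truth_to_json(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path, encoding="utf-8") as fh:
        return truth_from_json(json.load(fh))
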