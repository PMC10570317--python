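"""On-disk formats, Cytoscape-compatible exports, and the pipeline driver.

Canonical table dialect: TSV, UTF-8, Unix newlines, lexicographic row
order. Node tables carry gene_id, is_tf, go_terms, degree,
source_conditions; edge tables carry source, target, r,
source_conditions. Networks additionally export as SIF and GraphML so
they load directly in Cytoscape and other graph tools.

``run_pipeline`` executes the full strategy: FPKM -> per-condition DEG
calling -> Venn partition -> per-condition co-expression networks ->
integrated networks per user-defined group -> TF-centric GO-filtered core
reconstruction -> GO enrichment -> Z-score profiling and clustering, with
every artifact written to the output directory plus a run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import enrich, read_annotation
from .deg import DegTable, call_degs, venn_partition
from .expression import ExpressionMatrix, fpkm, group_means, log_transform, pca
from .gcn import CoexpressionNetwork, build_gcn, network_stats
from .integrate import merge_networks, reconstruct_core, shared_edge_decomposition
from .profile import cluster_profiles, render_heatmap, zscore
from .synthetic_data import CountExperiment

__all__ = [
    "PipelineConfig",
    "read_counts",
    "read_samples",
    "load_experiment",
    "write_network_tables",
    "read_network_tables",
    "write_deg_table",
    "read_deg_table",
    "export_sif",
    "export_graphml",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["condition", "time_point", "replicate", "arm"]


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV (first column gene_id, integer cells)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    arr = df.to_numpy()
    if arr.size and (not np.issubdtype(arr.dtype, np.number) or (arr < 0).any()):
        raise ValueError(f"{path}: counts must be nonnegative numbers")
    return df.astype(np.int64) if arr.size else df


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "time_point": str})
    for col in ["sample_id"] + SAMPLE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad_arm = set(df["arm"]) - {"mock", "treated"}
    if bad_arm:
        raise ValueError(f"{path}: arm must be mock/treated, got {sorted(bad_arm)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df.set_index("sample_id")


def load_experiment(
    counts_path: str | Path, samples_path: str | Path, annotation_path: str | Path
) -> tuple[CountExperiment, pd.DataFrame]:
    """Assemble a CountExperiment plus annotation table from TSV inputs."""
    counts = read_counts(counts_path)
    samples = read_samples(samples_path)
    ann = read_annotation(annotation_path)
    missing = counts.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"genes missing from annotation: {list(missing[:3])}")
    exp = CountExperiment(
        counts=counts,
        samples=samples.loc[counts.columns],
        gene_lengths=ann["length_bp"].astype(int),
    )
    return exp, ann


def _fmt_sources(sources) -> str:
    return ";".join(sorted(sources))


def write_network_tables(
    net: CoexpressionNetwork, directory: str | Path, prefix: str = "network"
) -> dict[str, Path]:
    """Write <prefix>_nodes.tsv / <prefix>_edges.tsv in lexicographic order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    node_rows = []
    for node in sorted(net.graph.nodes):
        data = net.graph.nodes[node]
        node_rows.append(
            {
                "gene_id": node,
                "is_tf": int(bool(data.get("is_tf", False))),
                "go_terms": ";".join(sorted(data.get("go_terms", frozenset()))),
                "degree": net.graph.degree(node),
                "source_conditions": _fmt_sources(data.get("source_conditions", frozenset())),
            }
        )
    edge_rows = []
    for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
        data = net.graph.edges[u, v]
        edge_rows.append(
            {
                "source": u,
                "target": v,
                "r": f"{data.get('r', 0.0):.6f}",
                "source_conditions": _fmt_sources(data.get("source_conditions", frozenset())),
            }
        )
    paths = {
        "nodes": directory / f"{prefix}_nodes.tsv",
        "edges": directory / f"{prefix}_edges.tsv",
    }
    pd.DataFrame(
        node_rows, columns=["gene_id", "is_tf", "go_terms", "degree", "source_conditions"]
    ).to_csv(paths["nodes"], sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(
        edge_rows, columns=["source", "target", "r", "source_conditions"]
    ).to_csv(paths["edges"], sep="\t", index=False, lineterminator="\n")
    return paths


def read_network_tables(
    directory: str | Path,
    prefix: str = "network",
    r_threshold: float = 0.9,
    mode: str = "signed",
) -> CoexpressionNetwork:
    directory = Path(directory)
    nodes = pd.read_csv(directory / f"{prefix}_nodes.tsv", sep="\t", dtype={"gene_id": str})
    edges = pd.read_csv(
        directory / f"{prefix}_edges.tsv", sep="\t", dtype={"source": str, "target": str}
    )
    for col in ["gene_id", "is_tf", "go_terms", "degree", "source_conditions"]:
        if col not in nodes.columns:
            raise ValueError(f"node table missing column {col!r}")
    for col in ["source", "target", "r", "source_conditions"]:
        if col not in edges.columns:
            raise ValueError(f"edge table missing column {col!r}")
    graph = nx.Graph()
    for row in nodes.itertuples(index=False):
        graph.add_node(
            row.gene_id,
            is_tf=bool(row.is_tf),
            go_terms=frozenset(str(row.go_terms).split(";")) - {"", "nan"},
            source_conditions=frozenset(str(row.source_conditions).split(";")) - {"", "nan"},
        )
    for row in edges.itertuples(index=False):
        sources = frozenset(str(row.source_conditions).split(";")) - {"", "nan"}
        graph.add_edge(
            row.source,
            row.target,
            r=float(row.r),
            r_by_source={s: float(row.r) for s in sources},
            source_conditions=sources,
        )
    return CoexpressionNetwork(graph=graph, r_threshold=r_threshold, mode=mode)


def write_deg_table(t: DegTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = t.table.sort_values(["condition", "time_point", "gene_id"], kind="stable")
    out = out.assign(
        log2fc=out["log2fc"].map("{:.6f}".format),
        p_value=out["p_value"].map("{:.6e}".format),
        fdr=out["fdr"].map("{:.6e}".format),
        is_deg=out["is_deg"].astype(int),
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def read_deg_table(
    path: str | Path, log2fc_cutoff: float = 1.0, fdr_cutoff: float = 0.05
) -> DegTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "time_point": str})
    df["is_deg"] = df["is_deg"].astype(bool)
    return DegTable(table=df, log2fc_cutoff=log2fc_cutoff, fdr_cutoff=fdr_cutoff)


def export_sif(net: CoexpressionNetwork, path: str | Path) -> Path:
    """One edge per line: source <TAB> co <TAB> target."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\tco\t{v}\n")
    return path


def export_graphml(net: CoexpressionNetwork, path: str | Path) -> Path:
    """GraphML with is_tf/go/source node attributes and r edge attributes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = nx.Graph()
    for node in sorted(net.graph.nodes):
        data = net.graph.nodes[node]
        g.add_node(
            node,
            is_tf=bool(data.get("is_tf", False)),
            go_terms=";".join(sorted(data.get("go_terms", frozenset()))),
            source_conditions=_fmt_sources(data.get("source_conditions", frozenset())),
        )
    for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
        data = net.graph.edges[u, v]
        g.add_edge(
            u,
            v,
            r=float(data.get("r", 0.0)),
            source_conditions=_fmt_sources(data.get("source_conditions", frozenset())),
        )
    nx.write_graphml(g, path)
    return path


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Everything needed for a full run, loadable from a YAML file.

    ``network_groups`` maps an integrated-network label (e.g. "abiotic")
    to the conditions merged into it; by default all conditions form one
    group called "integrated". ``n_clusters`` may be an int or a per-group
    mapping.
    """

    counts: str = "counts.tsv"
    samples: str = "samples.tsv"
    annotation: str = "annotation.tsv"
    out_dir: str = "stressgcn_out"
    log2fc_cutoff: float = 1.0
    fdr_cutoff: float = 0.05
    r_threshold: float = 0.9
    correlation_mode: str = "signed"
    block_size: int = 2000
    shared_only: int = 1
    hub_metric: str = "degree"
    network_groups: dict[str, list[str]] | None = None
    n_clusters: int | dict[str, int] = 5
    cluster_method: str = "hierarchical_ward"
    go_filter: list[str] = field(default_factory=lambda: ["GO:0050896"])
    enrichment_method: str = "hypergeometric"
    pca_components: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError(f"r_threshold must be in (0, 1), got {self.r_threshold}")
        if self.correlation_mode not in ("signed", "absolute"):
            raise ValueError(f"unknown correlation mode {self.correlation_mode!r}")
        if not 0.0 < self.fdr_cutoff < 1.0:
            raise ValueError(f"fdr_cutoff must be in (0, 1), got {self.fdr_cutoff}")
        if self.log2fc_cutoff <= 0:
            raise ValueError("log2fc_cutoff must be positive")
        if self.shared_only < 1:
            raise ValueError("shared_only must be >= 1")
        if self.cluster_method not in ("hierarchical_ward", "kmeans"):
            raise ValueError(f"unknown cluster method {self.cluster_method!r}")
        if self.enrichment_method not in ("hypergeometric", "length_weighted"):
            raise ValueError(f"unknown enrichment method {self.enrichment_method!r}")
        out = Path(self.out_dir).resolve()
        for p in (self.counts, self.samples, self.annotation):
            if Path(p).resolve() == out:
                raise ValueError("out_dir must differ from every input path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# pipeline driver


def _cluster_count(cfg: PipelineConfig, group: str, n_genes: int) -> int:
    want = cfg.n_clusters.get(group, 5) if isinstance(cfg.n_clusters, dict) else cfg.n_clusters
    k = want
    if n_genes < want:
        k = max(2, n_genes)
        logger.warning("group %s: reducing k from %d to %d (only %d genes)", group, want, k, n_genes)
    return k


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full strategy and write all artifacts to out_dir.

    Raises on the first failing stage, naming it; on success, the run
    manifest records the config, package version, and per-stage counts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "stressgcn",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "complete": False,
    }
    t_start = time.time()

    stage = "load"
    try:
        exp, ann = load_experiment(config.counts, config.samples, config.annotation)
        manifest["stages"][stage] = {
            "n_genes": len(exp.gene_ids),
            "n_samples": len(exp.samples),
            "conditions": exp.conditions,
        }

        stage = "expression"
        fpkm_mat = fpkm(exp)
        log_expr = log_transform(fpkm_mat, pseudocount=1.0)
        fpkm_out = fpkm_mat.values.copy()
        fpkm_out.index.name = "gene_id"
        fpkm_out.round(6).to_csv(out / "fpkm.tsv", sep="\t", lineterminator="\n")
        n_comp = min(config.pca_components, len(exp.samples) - 1, len(exp.gene_ids))
        pca_res = pca(log_expr, n_components=n_comp)
        scores = pca_res.scores.copy()
        scores["condition"] = exp.samples["condition"]
        scores["time_point"] = exp.samples["time_point"]
        scores.index.name = "sample_id"
        scores.round(6).to_csv(out / "pca_scores.tsv", sep="\t", lineterminator="\n")
        manifest["stages"][stage] = {
            "pca_explained_variance_ratio": [
                round(float(v), 6) for v in pca_res.explained_variance_ratio
            ]
        }

        stage = "deg"
        deg_tables = []
        for cond in exp.conditions:
            deg_tables.append(
                call_degs(exp, cond, config.log2fc_cutoff, config.fdr_cutoff).table
            )
        degs = DegTable(
            table=pd.concat(deg_tables, ignore_index=True),
            log2fc_cutoff=config.log2fc_cutoff,
            fdr_cutoff=config.fdr_cutoff,
        )
        write_deg_table(degs, out / "deg_table.tsv")
        deg_sets = degs.deg_sets_by_condition()
        manifest["stages"][stage] = {
            "deg_counts": {c: len(s) for c, s in sorted(deg_sets.items())}
        }

        stage = "venn"
        if len(deg_sets) >= 2:
            venn = venn_partition(deg_sets)
            venn_rows = [
                {
                    "conditions": ";".join(sorted(subset)),
                    "n_genes": count,
                }
                for subset, count in sorted(
                    venn.cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
                )
            ]
            pd.DataFrame(venn_rows, columns=["conditions", "n_genes"]).to_csv(
                out / "venn_partition.tsv", sep="\t", index=False, lineterminator="\n"
            )
            manifest["stages"][stage] = {"union_size": venn.universe_size}
        else:
            manifest["stages"][stage] = {"skipped": "fewer than 2 conditions"}

        stage = "gcn"
        nets: dict[str, CoexpressionNetwork] = {}
        gcn_counts = {}
        for cond in exp.conditions:
            cond_samples = exp.samples_of(cond)
            net = build_gcn(
                log_expr.restrict_samples(cond_samples),
                sorted(deg_sets.get(cond, set())),
                r_threshold=config.r_threshold,
                mode=config.correlation_mode,
                source=cond,
                block_size=config.block_size,
            )
            net.annotate_nodes(ann)
            nets[cond] = net
            write_network_tables(net, out, prefix=f"gcn_{cond}")
            export_sif(net, out / f"gcn_{cond}.sif")
            export_graphml(net, out / f"gcn_{cond}.graphml")
            st = network_stats(net)
            gcn_counts[cond] = {"n_nodes": st.n_nodes, "n_edges": st.n_edges}
        manifest["stages"][stage] = gcn_counts

        groups = config.network_groups or {"integrated": exp.conditions}
        tf_genes = set(ann.index[ann["is_tf"]])
        go_terms = set(config.go_filter) or None

        stage = "integrate"
        integrated: dict[str, CoexpressionNetwork] = {}
        int_counts = {}
        for gname, conds in groups.items():
            members = [nets[c] for c in conds if c in nets]
            if len(members) < 2:
                merged = members[0] if members else None
                if merged is None:
                    continue
            else:
                merged = merge_networks(members, shared_only=config.shared_only)
            integrated[gname] = merged
            write_network_tables(merged, out, prefix=f"integrated_{gname}")
            export_sif(merged, out / f"integrated_{gname}.sif")
            export_graphml(merged, out / f"integrated_{gname}.graphml")
            decomp = shared_edge_decomposition(merged)
            rows = [
                {"sources": ";".join(sorted(k)), "n_edges": v}
                for k, v in sorted(decomp.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
            ]
            pd.DataFrame(rows, columns=["sources", "n_edges"]).to_csv(
                out / f"integrated_{gname}_edge_sources.tsv",
                sep="\t",
                index=False,
                lineterminator="\n",
            )
            int_counts[gname] = {"n_nodes": merged.n_nodes, "n_edges": merged.n_edges}
        manifest["stages"][stage] = int_counts

        stage = "core"
        core_counts = {}
        cores = {}
        for gname, merged in integrated.items():
            try:
                core = reconstruct_core(
                    merged, tf_genes, go_filter=go_terms, hub_metric=config.hub_metric
                )
            except ValueError as exc:
                logger.warning("group %s: core reconstruction skipped (%s)", gname, exc)
                core_counts[gname] = {"skipped": str(exc)}
                continue
            cores[gname] = core
            core_net = core.as_network()
            write_network_tables(core_net, out, prefix=f"core_{gname}")
            export_sif(core_net, out / f"core_{gname}.sif")
            export_graphml(core_net, out / f"core_{gname}.graphml")
            pd.DataFrame(
                core.hub_ranking, columns=["gene_id", "degree", "is_tf"]
            ).assign(is_tf=lambda d: d["is_tf"].astype(int)).to_csv(
                out / f"core_{gname}_hubs.tsv", sep="\t", index=False, lineterminator="\n"
            )
            core_counts[gname] = {"n_nodes": core.n_nodes, "n_edges": core.n_edges}
        manifest["stages"][stage] = core_counts

        stage = "enrich"
        background = sorted(set(exp.gene_ids) & set(ann.index))
        enr_counts = {}
        for gname, core in cores.items():
            genes = sorted(core.graph.nodes)
            if not genes:
                continue
            rows = enrich(
                genes,
                background,
                ann,
                method=config.enrichment_method,
                seed=config.seed,
            )
            pd.DataFrame(
                [
                    {
                        "go_id": r.go_id,
                        "k": r.k,
                        "K": r.K,
                        "n": r.n,
                        "N": r.N,
                        "p_value": f"{r.p_value:.6e}",
                        "fdr": f"{r.fdr:.6e}",
                    }
                    for r in rows
                ],
                columns=["go_id", "k", "K", "n", "N", "p_value", "fdr"],
            ).to_csv(
                out / f"enrichment_{gname}.tsv", sep="\t", index=False, lineterminator="\n"
            )
            enr_counts[gname] = {"n_terms": len(rows)}
        manifest["stages"][stage] = enr_counts

        stage = "profile"
        prof_counts = {}
        for gname, core in cores.items():
            genes = sorted(core.graph.nodes)
            if len(genes) < 2:
                prof_counts[gname] = {"skipped": "fewer than 2 core genes"}
                continue
            conds = set(groups[gname])
            sample_ids = [
                s for s in exp.samples.index if exp.samples.loc[s, "condition"] in conds
            ]
            sub = ExpressionMatrix(
                log_expr.values.loc[genes, sample_ids],
                log_transformed=True,
                samples=exp.samples.loc[sample_ids],
            )
            means = group_means(sub)
            z = zscore(means)
            zout = z.values.copy()
            zout.index.name = "gene_id"
            zout.round(6).to_csv(out / f"zscore_{gname}.tsv", sep="\t", lineterminator="\n")
            k = _cluster_count(config, gname, len(genes))
            clusters = cluster_profiles(z, k=k, method=config.cluster_method, seed=config.seed)
            pd.DataFrame(
                sorted(clusters.assignment.items()), columns=["gene_id", "cluster"]
            ).to_csv(out / f"clusters_{gname}.tsv", sep="\t", index=False, lineterminator="\n")
            order = render_heatmap(z, clusters, tf_genes, out / f"heatmap_{gname}.png")
            with open(out / f"heatmap_{gname}_row_order.txt", "w", encoding="utf-8") as fh:
                fh.write("\n".join(order) + "\n")
            prof_counts[gname] = {"n_genes": len(genes), "k": k}
        manifest["stages"][stage] = prof_counts
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["complete"] = True
    logger.info("pipeline finished in %.1f s", time.time() - t_start)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
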