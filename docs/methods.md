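# Methods

This note documents the models, defaults, and numerical choices behind
`stressgcn`, and what the synthetic-data experiments do and do not show
about real data.

## Pipeline model

### Normalization and expression

Counts are normalized to FPKM with per-sample totals computed over the
analyzed gene set. This diverges from the alignment-based definition
("per million *mapped* reads"): once the pipeline starts from a count
matrix, aligner totals are unavailable, and the gene-set total is the
reproducible substitute. Correlation, PCA and profiling operate on
`log2(FPKM + 1)`; the pseudocount of 1 FPKM stabilizes the variance of
weakly expressed genes and is the conventional choice. PCA centers genes
(per-gene mean subtracted) and by default does not scale them to unit
variance; a `scale` flag enables that.

### Differential expression

Each (condition, time point) comparison against its matched mock is
self-contained:

- **Size factors** — DESeq-style median-of-ratios over genes with nonzero
  counts in every sample of the comparison, rescaled to geometric mean 1.
  If no such gene exists, total-count ratios are used with a warning.
- **Dispersion** — per-gene method of moments on normalized counts,
  `alpha = max((var - mu)/mu^2, 1e-8)`, with the arm-mean difference
  removed before pooling the residual variance (a real treatment effect
  must not inflate the dispersion). There is no shrinkage across genes
  and no independent filtering; the test is deliberately a simplified,
  transparent NB Wald rather than a full DESeq2 reimplementation, because
  the package's contribution lies downstream of DE calling.
- **Test** — `log2FC = log2((mean_t + c)/(mean_m + c))` with `c = 0.5`
  normalized counts; the NB variance `mu + alpha mu^2` of each arm mean is
  propagated to the log2 scale by the delta method, and the Wald statistic
  is referred to a t distribution with `n_t + n_m - 2` degrees of freedom.
  The t reference is a small-sample calibration choice: with plug-in
  method-of-moments dispersions at 3–5 replicates per arm, a normal
  reference rejects ~8–11% of null genes at nominal 5%, while the t
  reference holds 4–5% (measured on 10,000 simulated NB null genes,
  alpha = 0.1; cross-checked against an exact permutation test, Spearman
  agreement of p-values > 0.99). All-zero genes return (0, 1) by
  convention; a zero standard error yields p = 1 when the fold change is
  zero and p = 0 otherwise.
- **Multiple testing** — Benjamini–Hochberg within each comparison
  (delegated to statsmodels; the test suite holds an independent
  hand-coded step-up oracle). A gene is a DEG of a condition if it passes
  `|log2FC| > log2fc_cutoff` and `FDR < fdr_cutoff` at any time point of
  that condition (union over time points, matching one DEG count per
  treatment).

Default cutoffs are `log2fc_cutoff = 1`, `fdr_cutoff = 0.05`. Both are
plain parameters; nothing downstream assumes their values.

### Co-expression networks

Pearson correlation is computed on log2(FPKM+1) across **all** samples of a
condition — mock and treated, every time point — because
treatment-induced variation is precisely the signal that makes
stress-responsive genes co-vary. Edges are kept when `r >= r_threshold`
(signed mode, the default, reading "correlation of 0.9 or more" as
positive co-expression) or `|r| >= r_threshold` (absolute mode). The
comparison is inclusive. Zero-variance genes are removed before
correlation; genes left without a retained edge are dropped, so node
counts are at most (and usually below) DEG counts. The pairwise
computation standardizes rows once and multiplies blocks of the
standardized matrix, with a `block_size` parameter bounding memory at
~`block_size^2` floats; results are identical for any block size.

### Integration, core reconstruction, hub ranking

Merging is a node/edge union across per-condition networks built with
identical parameters. Every node and edge carries the set of source
conditions that contributed it; an edge found in several conditions keeps
each per-condition correlation (`r_by_source`) and reports the
largest-magnitude one as its representative `r`. An optional
`shared_only = m` filter restricts to nodes present in at least m inputs
(m = 1, the default, is the pure union — integrated node counts in
multi-stress studies sit near the union, not the intersection, of the
per-condition networks).

Core reconstruction: (1) seed on TFs in the network that carry at least
one term of the GO filter set (default `{GO:0050896}`); (2) expand to
direct neighbours; (3) keep non-seed candidates only if they carry a
filter term; (4) take the induced subgraph (edges between two surviving
non-seeds are kept); (5) rank all core nodes by degree, ties broken
lexicographically. Degree is the hub metric because it is the minimal
defensible quantitative reading of "hub"; betweenness centrality is
available as a secondary option. GO terms are flat labels; there is no
ontology-DAG ancestor propagation — callers wanting descendant semantics
should pre-expand the filter set.

### Enrichment

GO over-representation is a one-sided hypergeometric tail by default. The
`length_weighted` mode emulates the length-bias correction of RNA-seq
enrichment tools in spirit: a logistic fit of set membership on log gene
length yields per-gene weights, and the null distribution of the overlap
count is built by seeded Monte-Carlo resampling (default 10,000 draws) of
weighted gene sets, with `p = (1 + #{k* >= k}) / (draws + 1)`. With equal
lengths the two modes agree to Monte-Carlo accuracy. BH adjustment is
applied across terms.

### Z-score profiling and clustering

Group-mean expression (arithmetic mean over replicates of each
(condition, time point, arm) group, groups ordered lexicographically) is
standardized per gene with the population (n) standard deviation.
Constant rows — detected by exact range, since floating-point roundoff
can leave a numerically tiny but nonzero sd on an exactly constant row —
become all zeros. Clustering is Ward linkage on Euclidean distance with
the tree cut at a user-supplied k (k is configuration, never inferred;
published multi-stress analyses report 5 and 8 clusters for their two
networks), or seeded k-means with 10 restarts. Heatmap rows are ordered
by cluster, then by dendrogram leaf order within each cluster, with a TF
indicator track.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with planted ground truth for scoring:

- **Design** — `n_conditions` stresses x `time_points` x {mock, treated}
  x `n_replicates`. Default 3 conditions, 3 time points, 3 replicates
  (replicate count per condition and time point is rarely reported in
  public multi-stress compendia; 3 is the common floor, and the
  recovery studies below use 5 per arm, a typical well-powered design).
- **Baseline expression** — per-gene log2 means uniform on (5, 10), i.e.
  expressed genes; NB dispersion 0.02 (well-replicated bulk RNA-seq);
  counts realized as a Gamma–Poisson mixture with a per-gene random
  stream keyed by (seed, gene index), so per-gene draws survive gene
  subsetting; library sizes log-uniform on (1e6, 5e6) and expected
  fragment counts proportional to expression x transcript length, so
  FPKM normalization is genuinely exercised.
- **Modules** — each module is a stress-responsive regulon: a latent
  activity factor shared by its members, with member loadings uniform on
  (0.6, 0.85) and the designated hub TF at loading 1.0. The factor has
  unit variance per sample, decomposed into a component shared by all
  replicates of a (condition, time point) group — mock and treated alike,
  a coordinated time-course response — plus per-sample jitter
  (`module_latent_within_group_sd = 0.3`). Member genes add independent
  noise (`module_noise_sd`, default 0.3); the hub adds only a third of
  that (`hub_noise_frac`), reflecting that the driver's expression *is*
  the module activity while members respond with extra gene-specific
  variation. This communality difference is what lets the hub property
  emerge in the built network: with equal noise, factor-model
  correlations saturate and the degree ranking among high-loading genes
  is essentially a coin flip at any threshold.
- **Differential expression** — each module is assigned to one condition
  (round-robin) and the module factor is shifted in that condition's
  treated arm by a signed magnitude drawn from `de_log2fc_range`, so a
  member's realized log2FC is loading x shift and module members are
  DEGs of their condition — the property that lets planted modules enter
  the DEG-restricted networks at all. Additional independent DE genes
  (individual arm shifts, random signs) are drawn to fill `de_fraction`
  per condition.
- **Annotation** — hubs are always TFs; a further `tf_fraction` of genes
  are TFs; module members carry the stress GO label with probability 1
  by default (configurable), background genes with
  `stress_go_fraction = 0.2`.

**What passing tests show, and what they do not.** The generator produces
clean factor-structured modules, exactly NB counts, no batch effects, no
outlier samples, no correlated errors between modules, and GO labels that
are correct by construction. Recovery results on it demonstrate that the
pipeline's inference machinery is correct and internally consistent — the
DEG caller is calibrated and powered under its own noise model, the
network builder is exact, the core reconstruction finds planted drivers —
not that real stress compendia have this signal-to-noise. On real data,
annotation errors, shared regulators across modules, and
treatment-correlated library artifacts will all lower recovery.

## Study conditions used by tests and the reproduction script

Planted-truth recovery runs the full pipeline on 1,000 genes, 3
conditions, three 20-gene modules (latent sd 1.0, member noise sd 0.3),
planted |log2FC| = 2, 5 replicates per arm, r threshold 0.9, 20 seeded
repetitions. Measured under those conditions: mean planted-DE recall
≈ 0.997, false discovery proportion ≤ 0.01, and the planted hub ranked
first among its module's TFs for ≈ 95% of modules (all three hubs first
in 16–18 of 20 runs, across several base seeds). Calibration uses 10,000
NB null genes at dispersion 0.1, 5 vs 5. The network-builder oracle
checks run up to 500 genes; set-algebra oracles up to 5 conditions and
1,000 genes. These sizes keep the full suite and the reproduction script
to a few minutes on one CPU while exercising every code path at the same
parameter values the studies document.

## Numerical choices and degenerate inputs

- BH ties are handled by stable sort; adjusted p-values are monotone by
  construction.
- Correlations are clipped to [-1, 1] after the blocked matrix product.
- `estimate_dispersion` floors at 1e-8 (under-dispersed and constant
  genes land on the floor, making the Wald test Poisson-like there).
- Cluster ids are relabelled 1..k in order of first appearance along the
  gene list so labellings are deterministic across runs.
- The heatmap row order is returned and written to disk so rendering
  determinism is checkable without parsing the image.
- Empty experiments (0 genes), empty DEG sets, single-member cores, and
  constant expression rows are all defined, tested paths rather than
  errors, except where the operation is meaningless (PCA with one sample,
  z-scores of a single group), which raise with a named cause.

## Known limitations

- The DE test has no dispersion shrinkage; at 2 replicates per arm its
  power is poor and its calibration degrades. Use 3+ replicates.
- Signed-only and absolute-only edge semantics are supported, but mixed
  per-edge sign handling (e.g. separate positive/negative networks) is
  not.
- The length-weighted enrichment null resamples whole gene sets, which is
  O(draws x set size); very large sets with many terms are slow.
- GraphML/SIF exports carry flattened (semicolon-joined) set attributes;
  round-tripping through external tools preserves topology and `r` but
  not Python-set types.
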