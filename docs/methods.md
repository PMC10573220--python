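# Methods

This note records the models, parameter choices and numerical
conventions behind `perionet`, and what the synthetic benchmarks do and
do not demonstrate.

## Study design assumed

Two conditions (a healthy baseline A and a disease contrast B, e.g.
periodontitis-affected oral mucosa) with a small number of biological
replicates each — four per condition by default, the typical scale of
a mouse ligature-induced periodontitis experiment.  All stages consume
a gene × sample matrix of non-negative integer counts plus a design
table; network stages additionally consume a directed TF → target
reference regulon and an undirected scored PPI table.

Gene identifiers are canonicalized to uppercase symbols before any
cross-referencing, because curated regulons are frequently
human-derived ("SPI1") while mouse expression data uses title-case
symbols ("Spi1"); a user-supplied synonym table can be layered on top.

## Normalization and differential expression

Size factors use the median-of-ratios estimator: for genes with no
zero count, $s_j = \mathrm{median}_g (K_{gj}/g_g)$ with $g_g$ the
geometric mean of gene $g$ across samples, rescaled so that the
factors have geometric mean 1 (tolerance 1e-9).  Estimation fails
loudly when no gene is positive in all samples.

The per-gene test operates on $\log_2(q+1)$ of normalized counts.
With three residual degrees of freedom per group, raw per-gene
variances are too unstable for a usable test, so the default is a
moderated two-sample *t*: the pooled within-group variance is shrunk
toward the across-gene median $v_0$ with a fixed prior weight,

$\tilde s^2_g = (d_0 v_0 + d\, s^2_g)/(d_0 + d)$, $d = n_1+n_2-2$,
$d_0 = 10$,

and the statistic is referred to a *t* distribution with $d+d_0$
degrees of freedom.  This is the standard empirical-Bayes remedy for
n-of-4 designs; plain Welch (per-group variances,
Welch–Satterthwaite df) remains available via `prior_df=None`.  A
variance floor of 1e-8 makes exact-equality groups deterministic
(equal means ⇒ p = 1).  The fold change is computed on normalized
means with a pseudocount of 1, $\log_2((\bar q_B + 1)/(\bar q_A + 1))$,
so context-specific zeros never produce infinities; the pseudocount is
configurable.  Adjustment is Benjamini–Hochberg
(statsmodels), and a gene is called `up`/`down` iff
$|\log_2\mathrm{FC}| \ge 1$ **and** $p_{adj} \le 0.05$ (both
thresholds are parameters).  The fold-change orientation is fixed as
disease over health; the design table determines which condition is
which.

qPCR relative quantification: $\Delta C_t$ per sample against the
reference gene (18S by default), $\Delta\Delta C_t$ against the
arithmetic mean $\Delta C_t$ of the calibrator condition,
$RQ = 2^{-\Delta\Delta C_t}$; the calibrator's RQ has geometric mean 1
by construction, and adding a constant to all of a sample's Ct values
cancels.  The RANKL/OPG ratio divides the two RQ vectors sample-wise;
zero OPG is flagged per sample (NaN) rather than raised.

## Co-expression modules

Correlation is unsigned Pearson $|\rho|$ on $\log_2(q+1)$; constant
genes are removed first (correlation undefined) and logged.  The soft
threshold is the smallest candidate power whose weighted-degree
distribution $d_g = \sum_h |\rho_{gh}|^\beta$ passes a scale-free fit:
degrees are binned in log10 space (10 bins) and the signed fit
$-\mathrm{sign}(\text{slope}) \cdot R^2$ of log-frequency on
log-degree must reach 0.8.  The sign convention (as in WGCNA's
`pickSoftThreshold`) rejects increasing distributions.  When no
candidate qualifies — common for small designs and non-scale-free
fixtures — the selection is flagged and downstream code falls back to
$\beta = 12$: at $n = 8$ samples, sampling noise alone produces
$|\rho|$ up to ~0.5, and a high power is what separates genuine
co-expression ($|\rho| \to 1$) from that noise floor.

Clustering is average-linkage on $1-|\rho|^\beta$ with a **static cut
at height 0.99** on the [0, 1] dissimilarity scale.  A static absolute
cut (rather than a quantile of merge heights) is the only
deterministic rule that can return a single module when all genes form
one block — any quantile below 1 necessarily splits the root merge.
Clusters smaller than `min_module_size` (default 30) are relabeled
`unassigned`; surviving modules are named M1… by decreasing size, ties
broken by the lexicographically smallest member.

Module activity is the mean across module genes of per-gene z-scores
of $\log_2(q+1)$ (constant genes score 0), averaged per condition;
it is invariant to per-gene affine rescaling and signs indicate
direction.  Over-representation uses the hypergeometric upper tail
$P(X \ge k)$ with BH across all (module, set) pairs; gene sets are
intersected with the universe first.  Per-module PPI subnetworks keep
pairs with combined score ≥ 0.7 (inclusive); hubs are the top-k nodes
by degree within the module's subnetwork, ties broken by gene id.

## Context-specific GRNs and differential topology

Reference regulons are merged by edge union with per-edge provenance;
self-loops are dropped unless explicitly permitted.  The context
filter keeps an edge iff its regulator TF has (i) normalized count
> 0 in at least one of the context's replicates and (ii) arithmetic
mean normalized count > 10 across them — both inequalities strict, so
a TF at exactly mean 10 is removed.  Target expression is
intentionally not a criterion.  TFs absent from the expression matrix
count as not expressed (logged, not an error).

The comparison unions the two context graphs and labels each edge and
node `both` / `A_only` / `B_only`.  Per node, the incident edge set
(incoming ∪ outgoing directed edges) in context A is scored against
context B: TP = shared, FN = A-only, FP = B-only,
$F_1 = 2TP/(2TP+FP+FN)$.  Incident edges — not larger motifs — are the
local-topology unit; the scope is configurable (`out`/`in`/`both`
semantics follow from passing the graphs accordingly).  A node with
edges in exactly one context scores $F_1 = 0$; a node with edges in
neither is skipped.  Varying genes are those with $F_1 < 0.99$
(strict), sorted by ascending $F_1$.  Swapping the contexts swaps
FP/FN and leaves $F_1$ unchanged.

The module subnetwork restricts the combined GRN to module-labeled
genes and removes nodes left without incident edges (count logged),
annotating survivors with module, context class and DE status.

## Master regulators

Master regulators are modeled as clusters of highly interconnected,
physically interacting TFs located few regulatory steps from
phenotype-effector genes.  The pipeline per seed group:

1. **Seeds**: each requested co-expression module is one group, plus a
   group for the extra seed genes (default *Tnfsf11*, *Tnfrsf11b* —
   the RANKL/OPG bone-remodeling axis).  Groups run independently and
   the MR sets are unioned; a pooled mode exists.
2. **Expansion**: all nodes within graph distance 2 of the seeds,
   undirected by default (`regulators` mode iterates in-neighbors
   only).  Non-TF nodes, then isolates, are removed from the induced
   subgraph.
3. **Pruning**: iteratively and simultaneously remove every node
   failing (in-degree ≥ 4 AND out-degree ≥ 4), recomputing degrees
   within the shrinking subnetwork (self-loops excluded), to a fixed
   point.  This monotone rule's fixed point is removal-order
   independent (verified against a sequential oracle).  An optional
   single preliminary pass removing nodes with both degrees ≤ 4 is
   provided but disabled by default: it would contradict the iterative
   criterion by deleting nodes with in = out = 4 — e.g. the complete
   5-TF digraph, which the iterative rule retains.
4. **PPI support**: a directed TF→TF edge survives only if the
   unordered pair has combined score ≥ 0.7 (inclusive,
   order-insensitive lookup; 0–1000-scaled tables are normalized on
   read).  Pruning is then re-applied.

Each surviving TF is reported with the Mann–Whitney
$U = \#\{(h,d) : d > h\} + \tfrac12 \#\{d = h\}$ over its normalized
expression values, oriented toward disease, so $U \in [0, n_1 n_2]$
and $U_{disease} + U_{health} = n_1 n_2$.  With 4 + 4 replicates the
calls are $U \le 5$ ⇒ `healthy_higher`, $U \ge 10$ ⇒ `disease_higher`,
otherwise `inconsistent`; the bounds are parameters, and all-tied data
yields $U = n_1 n_2 / 2$ ⇒ inconsistent.  `de_target_count` is the
number of direct GRN targets (self-loops excluded) with a non-`ns` DE
status.  Reported connectivity defaults to in+out degree in the full
combined GRN (scope configurable: a 26-node subnetwork cannot carry
the hundreds of connections a hub TF has in the full network, so the
full-network scope is the informative one).  Top targets are ordered
DE-first (ascending $p_{adj}$, ties by $|\log_2\mathrm{FC}|$
descending, then id), then non-DE by $|\log_2\mathrm{FC}|$; the order
is total, hence reproducible.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
with planted ground truth for every stage:

* **Regulon**: TF out-degrees follow a truncated discrete power law
  (exponent 2.5) rescaled by probabilistic rounding to
  `mean_out_degree` (default 8); structural edges count toward each
  TF's budget.  The planted MR core (default 10 TFs) is a circulant
  sub-digraph — core TF *i* regulates the next `mr_core_min_degree`
  (default 5) core TFs — so every core member has within-core in- and
  out-degree exactly at the floor.  Core TFs additionally regulate
  genes of the first planted block and the RANKL/OPG axis genes.  A
  fraction (default 0.1) of each TF's edges target other TFs.
* **Counts**: negative binomial with dispersion α (default 0.1),
  log-normal baselines (default log-mean 5, log-sd 1, i.e. median
  ~150 counts), per-sample library factors uniform in [0.5, 2].
  Planted DE genes (an exact, deterministic count: `frac_de` × genes)
  scale the disease mean by $2^{\pm \text{lfc}}$ (default |lfc| = 2).
  DE genes are drawn outside the planted blocks whenever possible so
  the two ground truths stay unconfounded.
* **Blocks**: genes of a block share a per-sample latent factor on the
  log2 scale (sd 1.0 — chosen so block correlation dominates NB noise
  at n = 8), plus per-gene noise `module_noise_sd`.  The block factors
  are **orthogonalized across blocks**: with 8 samples, independent
  factors would correlate above 0.5 by chance half the time and the
  planted partition would be unidentifiable by any method.
* **Context-specific TFs** (default 2, one per context) have hard-zero
  counts in the other condition and no incoming regulation, so their
  entire incident edge set — hence their differential-topology class
  and $F_1 = 0$ — is confined to one context.  Core and
  context-specific TFs get a baseline floor of 50 so the mean > 10
  expression filter is decided by the planted design, not by sampling.
* **PPI**: every within-core pair scores ≥ 0.7; a fraction
  `ppi_support_frac` (default 0.3) of other TF–TF regulatory pairs is
  supported; all remaining sampled pairs score < 0.7.  Pairs are
  stored once in lexicographic order.
* **Gene sets**: one exact-membership set per block plus random
  decoys, writable as GMT.

All generators are pure functions of (config, seed); sub-streams are
derived per component so regenerating one artifact does not disturb
the others.

## What the benchmarks show — and what they do not

The acceptance checks measure recovery of *planted* structure under
the generator's model: NB counts with log-normal baselines,
orthogonal block factors, a hard-wired core.  Real tissue RNA-seq
differs in ways the generator deliberately omits: modules are
correlated with the condition and with each other, dispersion varies
systematically with expression, reference regulons carry false and
missing edges, and PPI evidence is biased toward well-studied
proteins.  Passing the benchmarks therefore demonstrates correctness
of the implemented procedures and adequate power at the stated design
scale — not that the thresholds (mean > 10, score ≥ 0.7, degree ≥ 4,
U bounds 5/10) are optimal for any particular real dataset.  Those
remain scientific choices exposed as parameters.

Problem sizes used by the test-suite and the acceptance script — 50
TFs, 500 targets, 3 blocks of 100 genes, 20 seeded repetitions of each
stochastic measurement — were chosen as the smallest scale at which
the planted structures are comfortably identifiable; all recovery
statistics are medians over the repetitions.

## Reproducibility conventions

One global seed drives every generator; the pipeline's run report
echoes parameters, versions and per-stage counts, and omits wall-clock
timestamps unless explicitly requested so that identical (config,
seed) runs produce byte-identical artifacts.  Tables are tab-separated
with headers; networks are exported as SIF (relation `regulates` for
GRN edges, `pp` for PPI) and GraphML with node/edge attributes for
Cytoscape import.
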