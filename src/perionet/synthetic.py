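"""Seeded synthetic inputs with planted ground truth.

Emulates the data a two-condition (healthy vs periodontitis) bulk
RNA-seq network study consumes: a curated TF -> target reference
regulon with a heavy-tailed out-degree distribution and a densely
interconnected "master regulator" TF core, negative-binomial counts for
two conditions x 4 replicates with planted differentially expressed
genes and planted co-expression blocks, a STRING-like scored PPI table
that supports the core, and GMT gene sets matching the planted blocks.

Every generator is a pure function of (config, seed); component
sub-streams are derived deterministically so partial regeneration is
stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .grn import ReferenceRegulon
import networkx as nx

#: shared per-(block, sample) latent factor sd on the log2 scale; large
#: relative to module_noise_sd so within-block correlation dominates
BLOCK_LATENT_SD = 1.0

#: gene symbols given to two planted DE targets of the MR core so that
#: RANKL/OPG-style seed lists resolve on synthetic data
SPECIAL_TARGETS = ("Tnfsf11", "Tnfrsf11b")

CONDITIONS = ("healthy", "periodontitis")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults mirror the emulated study design
    (two conditions, four replicates each)."""

    n_tfs: int = 50
    n_targets: int = 500
    n_replicates_per_condition: int = 4
    mean_out_degree: float = 8.0
    mr_core_size: int = 10
    mr_core_min_degree: int = 5
    frac_de: float = 0.1
    planted_lfc: float = 2.0
    dispersion: float = 0.1
    base_mean_log_mu: float = 5.0
    base_mean_log_sd: float = 1.0
    n_modules: int = 3
    module_size: int = 100
    module_noise_sd: float = 0.3
    ppi_support_frac: float = 0.3
    rng_seed: int = 0
    # extensions beyond the minimal field list
    n_context_specific_tfs: int = 2
    tf_tf_frac: float = 0.1
    power_law_exponent: float = 2.5

    def validate(self) -> None:
        if self.mr_core_min_degree >= self.mr_core_size:
            raise ValueError(
                "mr_core_min_degree must be < mr_core_size: a core TF "
                "cannot exceed core-internal degree capacity"
            )
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for name in ("n_tfs", "n_targets", "n_replicates_per_condition",
                     "mr_core_size", "mr_core_min_degree", "n_modules",
                     "module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mr_core_size > self.n_tfs:
            raise ValueError("mr_core_size cannot exceed n_tfs")
        if self.n_modules * self.module_size > self.n_targets:
            raise ValueError("planted blocks exceed the target pool")
        if self.mean_out_degree <= 0 or self.module_noise_sd <= 0:
            raise ValueError("mean_out_degree and module_noise_sd must be > 0")


@dataclass
class GroundTruth:
    """Planted structure the generators guarantee."""

    de_genes: dict[str, float]  # gene -> signed planted log2FC
    module_labels: dict[str, str]  # gene -> planted block id
    mr_core: set[str]
    context_specific_tfs: dict[str, str]  # TF -> only-expressed context
    ppi_supported_edges: set[frozenset] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "de_genes": self.de_genes,
            "module_labels": self.module_labels,
            "mr_core": sorted(self.mr_core),
            "context_specific_tfs": self.context_specific_tfs,
            "ppi_supported_edges": sorted(
                sorted(pair) for pair in self.ppi_supported_edges
            ),
        }


def _rng(config: SyntheticConfig, component: int) -> np.random.Generator:
    # per-component sub-stream: stable under partial regeneration
    return np.random.default_rng([config.rng_seed & 0x7FFFFFFF, component])


def _gene_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    tfs = [f"Tf{i + 1:03d}" for i in range(config.n_tfs)]
    targets = [f"Gene{i + 1:04d}" for i in range(config.n_targets)]
    # the RANKL/OPG axis lives outside the planted blocks (block genes
    # occupy the target prefix)
    targets[-2], targets[-1] = SPECIAL_TARGETS
    return tfs, targets


def _power_law_degrees(rng: np.random.Generator, n: int, mean: float,
                       exponent: float, dmax: int) -> np.ndarray:
    """Truncated discrete power law rescaled to the requested mean."""
    ks = np.arange(1, dmax + 1, dtype=float)
    pmf = ks**-exponent
    pmf /= pmf.sum()
    raw = rng.choice(ks, size=n, p=pmf)
    scale = mean / (pmf * ks).sum()
    scaled = raw * scale
    # probabilistic rounding keeps the expected mean at `mean`
    lo = np.floor(scaled)
    deg = lo + (rng.random(n) < (scaled - lo))
    return np.clip(deg, 1, dmax).astype(int)


def generate_reference_regulon(
    config: SyntheticConfig,
) -> tuple[ReferenceRegulon, GroundTruth]:
    """Reference TF -> target network with a planted MR core.

    The core is a circulant sub-digraph: core TF i regulates the next
    ``mr_core_min_degree`` core TFs, so every core member has in- and
    out-degree exactly ``mr_core_min_degree`` within the core.  Core
    TFs additionally regulate planted DE targets inside block B1.  TF
    out-degrees follow a truncated discrete power law (exponent 2.5 by
    default) rescaled to ``mean_out_degree``.
    """
    config.validate()
    rng = _rng(config, 1)
    tfs, targets = _gene_ids(config)
    all_genes = tfs + targets

    # planted DE genes: deterministic count.  Drawn outside the planted
    # co-expression blocks where possible so the two ground truths stay
    # unconfounded (the block latent factor would otherwise mask the
    # planted shift); spills into block genes only if the free pool is
    # too small.
    n_de = int(round(config.frac_de * len(all_genes)))
    n_block = config.n_modules * config.module_size
    free_pool = [t for t in targets[n_block:] if t not in SPECIAL_TARGETS]
    block_pool = targets[:n_block]
    forced = list(SPECIAL_TARGETS)[: min(n_de, 2)]
    n_extra = max(0, n_de - len(forced))
    if n_extra <= len(free_pool):
        extra = rng.choice(free_pool, size=n_extra, replace=False)
    else:
        spill = rng.choice(block_pool, size=n_extra - len(free_pool),
                           replace=False)
        extra = np.concatenate([free_pool, spill])
    de_list = forced + sorted(extra.tolist())
    signs = rng.choice([-1.0, 1.0], size=len(de_list))
    signs[: len(forced)] = 1.0  # RANKL/OPG axis planted up in disease
    de_genes = {g: float(s * config.planted_lfc)
                for g, s in zip(de_list, signs)}

    # planted co-expression blocks over a prefix of the targets
    module_labels = {}
    for b in range(config.n_modules):
        for g in targets[b * config.module_size:(b + 1) * config.module_size]:
            module_labels[g] = f"B{b + 1}"

    core = tfs[: config.mr_core_size]
    g = nx.DiGraph()
    g.add_nodes_from(all_genes)
    # circulant MR core
    for i, tf in enumerate(core):
        for j in range(1, config.mr_core_min_degree + 1):
            g.add_edge(tf, core[(i + j) % config.mr_core_size],
                       sources=frozenset({"synthetic"}))
    # core TFs regulate genes of block B1 and the planted DE axis
    block1 = targets[: config.module_size]
    de_axis = [t for t in SPECIAL_TARGETS if t in de_genes] or de_list[:2]
    for tf in core:
        picks = rng.choice(block1, size=min(6, len(block1)), replace=False)
        for t in list(picks) + de_axis:
            g.add_edge(tf, t, sources=frozenset({"synthetic"}))

    # context-specific TFs: non-core, alternating contexts; they stay
    # pure sources (no incoming regulation) so their whole incident
    # edge set is confined to one context
    noncore = tfs[config.mr_core_size:]
    ctx_tfs = {}
    for i in range(min(config.n_context_specific_tfs, len(noncore))):
        ctx_tfs[noncore[i]] = CONDITIONS[i % 2]

    # heavy-tailed out-degree budgets; structural (core/block) edges
    # already placed count toward each TF's budget
    degs = _power_law_degrees(rng, config.n_tfs, config.mean_out_degree,
                              config.power_law_exponent,
                              dmax=config.n_targets)
    tf_arr = np.array([t for t in tfs if t not in ctx_tfs])
    tgt_arr = np.array(targets)
    for tf, d in zip(tfs, degs):
        need = int(d) - g.out_degree(tf)
        if need <= 0:
            continue
        n_tf_edges = int(round(need * config.tf_tf_frac))
        others = tf_arr[tf_arr != tf]
        tf_picks = rng.choice(others, size=min(n_tf_edges, len(others)),
                              replace=False)
        tgt_picks = rng.choice(tgt_arr, size=min(need - len(tf_picks),
                                                 len(tgt_arr)),
                               replace=False)
        for t in list(tf_picks) + list(tgt_picks):
            if t != tf and not g.has_edge(tf, t):
                g.add_edge(tf, t, sources=frozenset({"synthetic"}))

    truth = GroundTruth(de_genes=de_genes, module_labels=module_labels,
                        mr_core=set(core), context_specific_tfs=ctx_tfs)
    return ReferenceRegulon(graph=g, tfs=set(tfs)), truth


def _block_latents(rng: np.random.Generator, n_blocks: int,
                   n_samples: int) -> np.ndarray:
    """Mean-zero per-sample latent factors, one row per block.

    Rows are orthogonalized across blocks (when n_blocks < n_samples)
    so distinct planted blocks are uncorrelated by construction; with
    only a handful of samples, independent Gaussian factors would
    frequently correlate above 0.5 by chance and the planted partition
    would not be identifiable by any method.
    """
    raw = rng.normal(size=(n_blocks, n_samples))
    raw -= raw.mean(axis=1, keepdims=True)
    if n_blocks < n_samples:
        q, _ = np.linalg.qr(raw.T)  # orthonormal, still mean-zero
        raw = q.T[:n_blocks] * np.sqrt(n_samples)
    return raw * BLOCK_LATENT_SD


def generate_counts(
    regulon: ReferenceRegulon,
    truth: GroundTruth,
    config: SyntheticConfig,
) -> CountMatrix:
    """Negative-binomial counts for two conditions of n replicates.

    Gene baseline means are log-normal; planted DE genes scale the
    disease mean by 2^(signed lfc); genes sharing a planted block share
    a per-sample latent factor on the log2 mean (sd 1.0) plus gene noise
    (sd ``module_noise_sd``); context-specific TFs are hard zeros in
    the other context; per-sample library factors are uniform in
    [0.5, 2].
    """
    config.validate()
    if config.n_replicates_per_condition < 1:
        raise ValueError("each condition needs at least one replicate")
    rng = _rng(config, 2)
    genes = sorted(regulon.graph.nodes())
    n_rep = config.n_replicates_per_condition
    samples = [f"H{i + 1}" for i in range(n_rep)] + \
              [f"P{i + 1}" for i in range(n_rep)]
    cond_of = {s: CONDITIONS[0] if s.startswith("H") else CONDITIONS[1]
               for s in samples}

    base = rng.lognormal(config.base_mean_log_mu, config.base_mean_log_sd,
                         size=len(genes))
    base_by_gene = dict(zip(genes, base))
    # core and context-specific TFs get a floor so the expression filter
    # (mean > 10) is decided by the planted structure, not by chance
    for tf in truth.mr_core | set(truth.context_specific_tfs):
        base_by_gene[tf] = max(base_by_gene[tf], 50.0)

    lib = rng.uniform(0.5, 2.0, size=len(samples))
    blocks = sorted(set(truth.module_labels.values()))
    latent = dict(zip(blocks, _block_latents(rng, len(blocks), len(samples))))

    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    r = 1.0 / config.dispersion
    for i, gene in enumerate(genes):
        log2_mu = np.full(len(samples), np.log2(base_by_gene[gene]))
        lfc = truth.de_genes.get(gene)
        if lfc is not None:
            for j, s in enumerate(samples):
                if cond_of[s] == CONDITIONS[1]:
                    log2_mu[j] += lfc
        block = truth.module_labels.get(gene)
        if block is not None:
            log2_mu = log2_mu + latent[block] + \
                rng.normal(0.0, config.module_noise_sd, size=len(samples))
        mu = (2.0**log2_mu) * lib
        ctx = truth.context_specific_tfs.get(gene)
        if ctx is not None:
            mu = np.where([cond_of[s] == ctx for s in samples], mu, 0.0)
        pos = mu > 0
        p = r / (r + mu[pos])
        counts[i, pos] = rng.negative_binomial(r, p)

    design = pd.DataFrame(
        {
            "condition": [cond_of[s] for s in samples],
            "replicate": [int(s[1:]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                            columns=samples),
        design=design,
    )


def generate_ppi(
    regulon: ReferenceRegulon,
    truth: GroundTruth,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """STRING-like scored undirected TF pairs (scores in [0, 1]).

    Every within-core pair scores >= 0.7; a fraction
    ``ppi_support_frac`` of the other TF-TF regulatory pairs scores
    >= 0.7; remaining sampled pairs score < 0.7.  Each unordered pair
    is stored once (lexicographic order).  Updates
    ``truth.ppi_supported_edges`` in place.
    """
    rng = _rng(config, 3)
    core = sorted(truth.mr_core)
    rows: dict[tuple[str, str], float] = {}

    def put(a: str, b: str, score: float) -> None:
        key = (a, b) if a < b else (b, a)
        rows[key] = max(rows.get(key, 0.0), float(score))

    for i, a in enumerate(core):
        for b in core[i + 1:]:
            put(a, b, 0.7 + 0.3 * rng.random())

    noncore_pairs = sorted(
        {tuple(sorted((u, v)))
         for u, v in regulon.graph.edges()
         if u in regulon.tfs and v in regulon.tfs
         and not ({u, v} <= truth.mr_core)}
    )
    for pair in noncore_pairs:
        if rng.random() < config.ppi_support_frac:
            put(*pair, 0.7 + 0.3 * rng.random())
        else:
            put(*pair, 0.69 * rng.random())

    # background decoy pairs, always sub-threshold
    tfs = sorted(regulon.tfs)
    for _ in range(len(tfs)):
        a, b = rng.choice(tfs, size=2, replace=False)
        key = (a, b) if a < b else (b, a)
        if key not in rows:
            rows[key] = 0.69 * rng.random()

    truth.ppi_supported_edges = {
        frozenset(k) for k, v in rows.items() if v >= 0.7
    }
    out = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(rows.items())],
        columns=["protein1", "protein2", "combined_score"],
    )
    return out


def generate_gene_sets(
    truth: GroundTruth,
    n_decoys: int = 10,
    seed: int = 0,
    universe: list[str] | None = None,
) -> dict[str, set[str]]:
    """One gene set per planted block plus random decoy sets."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 4])
    sets: dict[str, set[str]] = {}
    blocks: dict[str, set[str]] = {}
    for gene, block in truth.module_labels.items():
        blocks.setdefault(block, set()).add(gene)
    for block in sorted(blocks):
        sets[f"SET_{block}"] = set(blocks[block])
    if universe is None:
        universe = sorted(set(truth.module_labels) | set(truth.de_genes))
    universe = sorted(universe)
    for i in range(n_decoys):
        size = int(rng.integers(20, max(21, len(universe) // 5)))
        members = rng.choice(universe, size=min(size, len(universe)),
                             replace=False)
        sets[f"DECOY_{i + 1:02d}"] = set(members.tolist())
    return sets


def validate_ground_truth(
    regulon: ReferenceRegulon,
    truth: GroundTruth,
    config: SyntheticConfig,
    counts: CountMatrix | None = None,
) -> None:
    """Cross-check emitted artifacts against the planted annotations."""
    genes = set(regulon.graph.nodes())
    if not truth.mr_core <= regulon.tfs:
        raise AssertionError("mr_core not a subset of the TF set")
    if not set(truth.de_genes) <= genes:
        raise AssertionError("planted DE genes missing from the regulon")
    core = sorted(truth.mr_core)
    sub = regulon.graph.subgraph(core)
    for tf in core:
        if sub.in_degree(tf) < config.mr_core_min_degree or \
                sub.out_degree(tf) < config.mr_core_min_degree:
            raise AssertionError(f"core TF {tf} under-connected in core")
    if any(u == v for u, v in regulon.graph.edges()):
        raise AssertionError("self-loop in reference regulon")
    if counts is not None:
        if set(counts.genes) != genes:
            raise AssertionError("count matrix gene set != regulon nodes")
        for tf, ctx in truth.context_specific_tfs.items():
            other = [s for s in counts.samples
                     if counts.design.loc[s, "condition"] != ctx]
            if counts.counts.loc[tf, other].to_numpy().any():
                raise AssertionError(
                    f"context-specific TF {tf} nonzero outside {ctx}")


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
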