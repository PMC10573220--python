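"""Co-expression module detection, activity, hubs and over-representation.

Modules are found WGCNA-style: Pearson correlation of log2(q + 1)
expression, a soft-threshold power beta chosen by scale-free topology
fit, average-linkage hierarchical clustering of the dissimilarity
1 - |rho|^beta, and a tree cut at a quantile of the merge heights.
Clusters below ``min_module_size`` are relabeled "unassigned"; surviving
modules are named M1, M2, ... by decreasing size.  Module activity is a
mean z-score summary; over-representation uses the hypergeometric upper
tail with Benjamini-Hochberg adjustment across all (module, set) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression import NormalizedMatrix, benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionConfig:
    beta_candidates: list[int] = field(
        default_factory=lambda: list(range(1, 21)))
    r2_target: float = 0.8
    min_module_size: int = 30
    correlation: str = "pearson"
    linkage: str = "average"
    #: static tree-cut height on the [0, 1] dissimilarity scale; pairs
    #: merging above it are split into separate clusters
    cut_height: float = 0.99
    signed: bool = False  # unsigned |rho| by default
    n_degree_bins: int = 10

    def validate(self) -> None:
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 < self.r2_target <= 1:
            raise ValueError("r2_target must lie in (0, 1]")
        if any(b < 1 for b in self.beta_candidates):
            raise ValueError("beta candidates must be positive integers")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must lie in (0, 1]")


#: fallback soft-threshold power when the scale-free fit is
#: inconclusive.  A high power sharpens the gap between genuine
#: co-expression (|rho| near 1) and the sampling-noise correlations
#: that small designs produce (|rho| up to ~0.5 at n = 8); 12 is the
#: conventional WGCNA power for signed networks and works well here.
DEFAULT_BETA = 12


@dataclass
class SoftThresholdResult:
    beta: int
    r2_by_beta: dict[int, float]
    flagged: bool  # True when no candidate reached the scale-free fit

    @property
    def effective_beta(self) -> int:
        """The selected beta, or the conventional default when the
        scale-free criterion offered no guidance."""
        return DEFAULT_BETA if self.flagged else self.beta


def _expression_values(norm: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    return np.log2(values + 1.0)


def _correlation(expr: pd.DataFrame, signed: bool) -> tuple[np.ndarray, list]:
    """|Pearson rho| (or signed) after removing constant genes."""
    arr = expr.to_numpy(dtype=float)
    keep = arr.std(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("excluding %d constant-expression genes before "
                       "correlation", dropped)
    genes = [g for g, k in zip(expr.index, keep) if k]
    rho = np.corrcoef(arr[keep])
    rho = np.clip(rho, -1.0, 1.0)
    return (rho if signed else np.abs(rho)), genes


def _scale_free_r2(degrees: np.ndarray, n_bins: int) -> float:
    """Signed scale-free fit: -sign(slope) * R^2 of log10(frequency)
    vs log10(degree) over degree bins.

    A power-law degree distribution has a *decreasing* log-log
    frequency curve, so fits with positive slope score negative
    (rejected), as in WGCNA's pickSoftThreshold.
    """
    d = degrees[degrees > 0]
    if d.size < 3 or np.ptp(np.log10(d)) < 1e-9:
        return np.nan  # no discrimination possible
    edges = np.linspace(np.log10(d.min()), np.log10(d.max()), n_bins + 1)
    idx = np.clip(np.digitize(np.log10(d), edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            xs.append(np.log10(d[mask]).mean())
            ys.append(np.log10(mask.sum() / d.size))
    if len(xs) < 3:
        return np.nan
    fit = stats.linregress(xs, ys)
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def select_soft_threshold(
    norm: NormalizedMatrix | pd.DataFrame,
    config: CoexpressionConfig | None = None,
) -> SoftThresholdResult:
    """Smallest beta whose weighted-degree distribution is scale-free.

    Weighted degree of gene g is sum_h |rho_gh|^beta (h != g).  Returns
    the smallest candidate with binned log-log fit R^2 >= r2_target; if
    none qualifies the maximum candidate is returned flagged.  Fully
    degenerate data (all correlations equal, no degree spread) returns
    the smallest candidate, flagged.
    """
    config = config or CoexpressionConfig()
    config.validate()
    expr = _expression_values(norm)
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to select a soft threshold")
    rho, _ = _correlation(expr, signed=False)
    np.fill_diagonal(rho, 0.0)
    r2s: dict[int, float] = {}
    for beta in sorted(config.beta_candidates):
        deg = (rho**beta).sum(axis=1)
        r2s[beta] = _scale_free_r2(deg, config.n_degree_bins)
        if np.isnan(r2s[beta]):
            continue
        if r2s[beta] >= config.r2_target:
            return SoftThresholdResult(beta=beta, r2_by_beta=r2s,
                                       flagged=False)
    if all(np.isnan(v) for v in r2s.values()):
        logger.warning("degree distribution offers no discrimination; "
                       "returning smallest beta candidate")
        return SoftThresholdResult(beta=min(config.beta_candidates),
                                   r2_by_beta=r2s, flagged=True)
    logger.warning("no beta reached R^2 >= %.2f; returning max candidate",
                   config.r2_target)
    return SoftThresholdResult(beta=max(config.beta_candidates),
                               r2_by_beta=r2s, flagged=True)


def detect_modules(
    norm: NormalizedMatrix | pd.DataFrame,
    beta: int,
    config: CoexpressionConfig | None = None,
) -> pd.Series:
    """Gene -> module label (M1..Mk by decreasing size, or "unassigned").

    Average-linkage clustering of 1 - |rho|^beta with a static tree cut
    at ``cut_height`` on the dissimilarity scale; clusters smaller than
    ``min_module_size`` are unassigned.  Deterministic for a fixed
    input.
    """
    config = config or CoexpressionConfig()
    config.validate()
    if beta < 1:
        raise ValueError("beta must be >= 1")
    expr = _expression_values(norm)
    all_genes = list(expr.index)
    labels = pd.Series("unassigned", index=pd.Index(all_genes, name="gene"))
    if len(all_genes) < config.min_module_size:
        return labels
    rho, genes = _correlation(expr, signed=config.signed)
    if len(genes) < config.min_module_size:
        return labels
    dissim = 1.0 - np.abs(rho)**beta
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    z = linkage(squareform(dissim, checks=False), method=config.linkage)
    raw = fcluster(z, t=config.cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    kept = [sorted(members) for members in clusters.values()
            if len(members) >= config.min_module_size]
    # M1 is the largest; ties broken by smallest member id
    kept.sort(key=lambda m: (-len(m), m[0]))
    for rank, members in enumerate(kept, start=1):
        labels.loc[members] = f"M{rank}"
    return labels


def module_activity(
    norm: NormalizedMatrix | pd.DataFrame,
    modules: pd.Series,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean z-score activity per module, per sample (or per condition).

    Each gene's log2(q + 1) profile is z-scored across samples
    (constant genes score 0); a module's activity in a sample is the
    mean over its genes.  With a design, activities are averaged per
    condition.  Invariant to per-gene affine rescaling of expression.
    """
    expr = _expression_values(norm)
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1, keepdims=True)
    mean = arr.mean(axis=1, keepdims=True)
    z = np.divide(arr - mean, sd, out=np.zeros_like(arr), where=sd > 0)
    zdf = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    module_names = sorted(set(modules) - {"unassigned"})
    rows = {}
    for m in module_names:
        genes = [g for g in modules.index[modules == m] if g in zdf.index]
        if not genes:
            logger.warning("module %s has no genes in the matrix; skipped", m)
            continue
        rows[m] = zdf.loc[genes].mean(axis=0)
    act = pd.DataFrame(rows).T
    act.index.name = "module"
    if design is not None and not act.empty:
        cond = design["condition"]
        by_cond = {
            c: act[[s for s in act.columns if cond.get(s) == c]].mean(axis=1)
            for c in dict.fromkeys(cond)
        }
        return pd.DataFrame(by_cond)
    return act


def ora(
    module_genes,
    gene_sets: dict[str, set[str]],
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in one module.

    p = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|set|, n=|module|),
    where k is the observed overlap.  Sets are intersected with the
    universe first; raw p only (adjust across modules with
    :func:`ora_modules`).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes) & universe
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        k = len(module & members)
        n_u, n_k, n_m = len(universe), len(members), len(module)
        p = float(stats.hypergeom.sf(k - 1, n_u, n_k, n_m)) if k > 0 else 1.0
        rows.append({"gene_set": name, "universe": n_u, "set_size": n_k,
                     "module_size": n_m, "overlap": k,
                     "pvalue": min(p, 1.0)})
    return pd.DataFrame(rows)


def ora_modules(
    modules: pd.Series,
    gene_sets: dict[str, set[str]],
    universe=None,
) -> pd.DataFrame:
    """ORA of every module against every set, BH across all pairs."""
    if universe is None:
        universe = list(modules.index)
    frames = []
    for m in sorted(set(modules) - {"unassigned"}):
        df = ora(modules.index[modules == m], gene_sets, universe)
        df.insert(0, "module", m)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["module", "gene_set", "universe",
                                     "set_size", "module_size", "overlap",
                                     "pvalue", "padj"])
    out = pd.concat(frames, ignore_index=True)
    out["padj"] = benjamini_hochberg(out["pvalue"].to_numpy())
    return out


def ppi_cooccurrence(
    modules: pd.Series,
    ppi: pd.DataFrame,
    min_score: float = 0.7,
) -> dict[str, nx.Graph]:
    """Per-module PPI subnetwork at combined score >= min_score.

    ``ppi`` columns: protein1, protein2, combined_score in [0, 1]; the
    score threshold is inclusive.
    """
    if (ppi["combined_score"] > 1.0).any() or (ppi["combined_score"] < 0).any():
        raise ValueError("PPI scores must be normalized to [0, 1]")
    g = nx.Graph()
    strong = ppi[ppi["combined_score"] >= min_score]
    for row in strong.itertuples(index=False):
        g.add_edge(row.protein1, row.protein2, score=row.combined_score)
    out = {}
    for m in sorted(set(modules) - {"unassigned"}):
        genes = [x for x in modules.index[modules == m] if x in g]
        out[m] = g.subgraph(genes).copy()
    return out


def identify_hubs(
    module_genes,
    network: nx.Graph,
    k: int = 10,
) -> list[tuple[str, int]]:
    """Top-k nodes by degree in the module-induced subnetwork.

    Ties broken by gene id (lexicographically smaller first).  Modules
    with no presence in the network yield an empty list.
    """
    present = [g for g in module_genes if g in network]
    if not present:
        logger.warning("module has no presence in the network; no hubs")
        return []
    sub = network.subgraph(present)
    ranked = sorted(sub.degree(), key=lambda t: (-t[1], t[0]))
    return ranked[:k]
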