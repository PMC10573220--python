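"""Master-regulator identification by iterative degree pruning.

Master regulators (MRs) are taken to be clusters of highly
interconnected, physically interacting TFs sitting few regulatory steps
from phenotype-effector genes.  Starting from seed genes (co-expression
modules of interest plus the RANKL/OPG axis), the combined GRN is
expanded to first and second neighbors, restricted to TFs, and pruned
iteratively: a node survives only while its in-degree AND out-degree
within the current subnetwork stay at or above the thresholds (4 by
default).  Edges lacking PPI support (combined score >= 0.7) are
removed and the pruning re-applied.  Each surviving TF gets a
Mann-Whitney U statistic comparing its normalized expression between
conditions, a condition call, its count of differentially expressed
targets, and a ranked target list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .grn import CombinedGRN, canonical, neighbor_expansion

logger = logging.getLogger(__name__)


@dataclass
class MRConfig:
    seed_modules: list[str] = field(
        default_factory=lambda: ["M1", "M3", "M8"])
    extra_seed_genes: list[str] = field(
        default_factory=lambda: ["Tnfsf11", "Tnfrsf11b"])
    neighbor_order: int = 2
    neighbor_mode: str = "undirected"  # or "regulators"
    initial_prune_both_le: int | None = None  # one-pass "both <= n" removal
    min_indegree: int = 4
    min_outdegree: int = 4
    ppi_min_score: float = 0.7
    u_low: int = 5
    u_high: int = 10
    top_n_targets: int = 50
    per_group_runs: bool = True
    connectivity_scope: str = "full"  # full | seed_subnetwork | mr_subnetwork

    def validate(self, n1: int | None = None, n2: int | None = None) -> None:
        if self.u_low >= self.u_high:
            raise ValueError("u_low must be < u_high")
        if n1 is not None and n2 is not None and self.u_high > n1 * n2:
            raise ValueError("u_high cannot exceed n1 * n2")
        if self.min_indegree < 1 or self.min_outdegree < 1:
            raise ValueError("degree thresholds must be >= 1")


@dataclass
class MasterRegulatorReport:
    mr_set: set[str]
    mr_subnetwork: nx.DiGraph
    table: pd.DataFrame  # tf, u, condition_call, de_target_count, ...
    top_targets: dict[str, list[str]]
    groups: dict[str, set[str]] = field(default_factory=dict)
    connectivity_scope: str = "full"


def mann_whitney_u(values_healthy, values_disease) -> float:
    """Mann-Whitney U oriented toward disease.

    U = number of (healthy, disease) pairs where the disease value is
    larger, counting ties as 0.5; ranges over [0, n1 * n2].
    """
    h = np.asarray(values_healthy, dtype=float)
    d = np.asarray(values_disease, dtype=float)
    if h.size == 0 or d.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = d[:, None] - h[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def assign_condition(
    u: float, n1: int, n2: int, u_low: float = 5, u_high: float = 10
) -> str:
    """Condition call from the U statistic.

    U <= u_low: consistently higher in health; U >= u_high:
    consistently higher in disease; otherwise inconsistent.
    """
    if not 0 <= u <= n1 * n2:
        raise ValueError(f"U = {u} outside [0, {n1 * n2}]")
    if u <= u_low:
        return "healthy_higher"
    if u >= u_high:
        return "disease_higher"
    return "inconsistent"


def _degrees_no_self(g: nx.DiGraph, node) -> tuple[int, int]:
    self_loop = 1 if g.has_edge(node, node) else 0
    return g.in_degree(node) - self_loop, g.out_degree(node) - self_loop


def prune_by_degree(
    subnetwork: nx.DiGraph,
    min_in: int = 4,
    min_out: int = 4,
    initial_both_le: int | None = None,
) -> nx.DiGraph:
    """Iterative simultaneous removal until every node keeps
    in-degree >= min_in AND out-degree >= min_out.

    Degrees are recomputed within the shrinking subnetwork each round;
    self-loops are excluded from the counts.  The optional initial pass
    removes, once, every node with in-degree <= initial_both_le AND
    out-degree <= initial_both_le.  The fixed point of the iterative
    rule is removal-order independent; an empty result is valid.
    """
    g = subnetwork.copy()
    if initial_both_le is not None:
        drop = [n for n in g
                if (lambda io: io[0] <= initial_both_le
                    and io[1] <= initial_both_le)(_degrees_no_self(g, n))]
        g.remove_nodes_from(drop)
    while True:
        drop = [n for n in g
                if (lambda io: io[0] < min_in or io[1] < min_out)(
                    _degrees_no_self(g, n))]
        if not drop:
            return g
        g.remove_nodes_from(drop)


def filter_edges_by_ppi(
    subnetwork: nx.DiGraph,
    ppi: pd.DataFrame | dict[frozenset, float],
    min_score: float = 0.7,
) -> nx.DiGraph:
    """Keep a directed edge (a, b) only if the unordered pair {a, b}
    has PPI combined score >= min_score (inclusive, order-insensitive).

    The node set is unchanged; isolates are handled by the subsequent
    degree pruning.
    """
    lookup = ppi if isinstance(ppi, dict) else ppi_score_lookup(ppi)
    g = subnetwork.copy()
    drop = [(u, v) for u, v in g.edges()
            if lookup.get(frozenset((u, v)), 0.0) < min_score]
    g.remove_edges_from(drop)
    return g


def ppi_score_lookup(ppi: pd.DataFrame) -> dict[frozenset, float]:
    """Order-insensitive {a, b} -> combined score map (canonical ids)."""
    if (ppi["combined_score"] > 1.0).any():
        raise ValueError("PPI scores must be normalized to [0, 1]")
    out: dict[frozenset, float] = {}
    for row in ppi.itertuples(index=False):
        key = frozenset((canonical(row.protein1), canonical(row.protein2)))
        out[key] = max(out.get(key, 0.0), float(row.combined_score))
    return out


def select_seeds(
    modules: pd.Series, config: MRConfig
) -> dict[str, set[str]]:
    """One seed group per requested module label plus the extra genes."""
    groups: dict[str, set[str]] = {}
    available = set(modules)
    for label in config.seed_modules:
        if label not in available:
            logger.warning("seed module %s not found; skipped", label)
            continue
        groups[label] = {canonical(g)
                         for g in modules.index[modules == label]}
    if config.extra_seed_genes:
        groups["extra"] = {canonical(g) for g in config.extra_seed_genes}
    if not any(groups.values()):
        raise ValueError("all seed groups are empty")
    return groups


def build_seed_subnetwork(
    grn: CombinedGRN | nx.DiGraph,
    seeds,
    tfs: set[str],
    config: MRConfig | None = None,
) -> nx.DiGraph:
    """Induced subgraph on the neighbor expansion of the seeds,
    restricted to TF-coding nodes, isolates dropped."""
    config = config or MRConfig()
    graph = grn.graph if isinstance(grn, CombinedGRN) else grn
    nodes = neighbor_expansion(graph, seeds, order=config.neighbor_order,
                               mode=config.neighbor_mode)
    sub = graph.subgraph(nodes).copy()
    sub.remove_nodes_from([n for n in list(sub) if n not in tfs])
    sub.remove_nodes_from([n for n in list(sub) if sub.degree(n) == 0])
    return sub


def count_de_targets(mr: str, grn: CombinedGRN | nx.DiGraph,
                     de: pd.DataFrame) -> int:
    """Number of the MR's direct targets that are differentially
    expressed (status != ns); self-loops excluded."""
    graph = grn.graph if isinstance(grn, CombinedGRN) else grn
    if mr not in graph:
        raise KeyError(f"unknown master regulator {mr!r}")
    de_set = {canonical(g) for g, s in de["status"].items() if s != "ns"}
    targets = {t for t in graph.successors(mr) if t != mr}
    return len(targets & de_set)


def rank_targets(
    mr: str,
    grn: CombinedGRN | nx.DiGraph,
    de: pd.DataFrame,
    top_n: int = 50,
) -> list[str]:
    """Targets of an MR ranked for reporting.

    DE targets first (ascending adjusted p, ties by |log2FC| descending
    then id), then the rest by |log2FC| descending then id; truncated
    to ``top_n``.  The ordering is a total order, so it is identical
    across runs.
    """
    graph = grn.graph if isinstance(grn, CombinedGRN) else grn
    if mr not in graph:
        return []
    info = {canonical(g): (row.padj, abs(row.log2fc), row.status != "ns")
            for g, row in de.iterrows()}
    targets = sorted(t for t in graph.successors(mr) if t != mr)

    def key(t: str):
        padj, alfc, is_de = info.get(t, (1.0, 0.0, False))
        if is_de:
            return (0, padj, -alfc, t)
        return (1, 0.0, -alfc, t)

    return sorted(targets, key=key)[:top_n]


def identify_master_regulators(
    grn: CombinedGRN,
    modules: pd.Series,
    norm,
    ppi: pd.DataFrame,
    de: pd.DataFrame,
    config: MRConfig | None = None,
    tfs: set[str] | None = None,
) -> MasterRegulatorReport:
    """Full MR pipeline over seed groups.

    Per group: seed subnetwork -> degree pruning -> PPI edge filter ->
    degree pruning again.  The MR set is the union over groups, the MR
    subnetwork the union of surviving (PPI-supported) TF-TF edges.
    """
    config = config or MRConfig()
    tfs = tfs if tfs is not None else grn.tfs
    groups = select_seeds(modules, config)
    if not config.per_group_runs:
        groups = {"pooled": set().union(*groups.values())}
    lookup = ppi_score_lookup(ppi)

    mr_net = nx.DiGraph()
    group_hits: dict[str, set[str]] = {}
    for name, seeds in groups.items():
        sub = build_seed_subnetwork(grn, seeds, tfs, config)
        pruned = prune_by_degree(sub, config.min_indegree,
                                 config.min_outdegree,
                                 config.initial_prune_both_le)
        supported = filter_edges_by_ppi(pruned, lookup, config.ppi_min_score)
        final = prune_by_degree(supported, config.min_indegree,
                                config.min_outdegree)
        group_hits[name] = set(final.nodes())
        mr_net.update(final)
        logger.info("seed group %s: %d seeds -> %d TFs in subnetwork -> "
                    "%d MRs", name, len(seeds), sub.number_of_nodes(),
                    final.number_of_nodes())

    mr_set = set(mr_net.nodes())
    healthy, disease = _condition_samples(norm)
    values = norm.values
    vlookup = {canonical(g): i for i, g in enumerate(values.index)}
    arr = values.to_numpy(dtype=float)
    n1, n2 = len(healthy), len(disease)
    config.validate(n1, n2)
    hi = [values.columns.get_loc(s) for s in healthy]
    di = [values.columns.get_loc(s) for s in disease]

    rows, top_targets = [], {}
    for mr in sorted(mr_set):
        i = vlookup.get(mr)
        if i is None:
            u, call = np.nan, "unknown"
        else:
            u = mann_whitney_u(arr[i, hi], arr[i, di])
            call = assign_condition(u, n1, n2, config.u_low, config.u_high)
        scope = {
            "full": grn.graph,
            "seed_subnetwork": mr_net,
            "mr_subnetwork": mr_net,
        }[config.connectivity_scope]
        cin, cout = _degrees_no_self(scope, mr) if mr in scope else (0, 0)
        tops = rank_targets(mr, grn, de, config.top_n_targets)
        top_targets[mr] = tops
        rows.append({
            "tf": mr,
            "u": u,
            "condition_call": call,
            "de_target_count": count_de_targets(mr, grn, de),
            "connectivity": cin + cout,
            "n_top_targets": len(tops),
        })
    table = pd.DataFrame(
        rows, columns=["tf", "u", "condition_call", "de_target_count",
                       "connectivity", "n_top_targets"])
    return MasterRegulatorReport(
        mr_set=mr_set, mr_subnetwork=mr_net, table=table,
        top_targets=top_targets, groups=group_hits,
        connectivity_scope=config.connectivity_scope)


def _condition_samples(norm) -> tuple[list[str], list[str]]:
    conds = list(dict.fromkeys(norm.design["condition"]))
    if len(conds) != 2:
        raise ValueError("exactly two conditions expected")
    return norm.samples_of(conds[0]), norm.samples_of(conds[1])
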