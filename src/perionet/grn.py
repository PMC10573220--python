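"""Reference regulon merging, context-specific GRNs and differential topology.

A reference regulon is a directed TF -> target network merged from one
or more curated edge lists (e.g. DoRoThEA-, TRRUST- or RegNetwork-style
tables).  A context-specific GRN keeps a reference edge only if its
regulator TF is expressed in that context: normalized count > 0 in at
least one replicate AND mean normalized count > tau_expr (both strict).
Two context GRNs are compared edge-wise; each node's incident edges in
context A are treated as the positives and those in context B as the
predictions, giving per-node TP/FP/FN and an F1 score.  F1 < 1 flags a
local topological change between health and disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


def canonical(gene: str, synonyms: dict[str, str] | None = None) -> str:
    """Canonical gene id: uppercase symbol, optional synonym mapping.

    Mouse symbols ("Spi1") and human-derived reference ids ("SPI1")
    collapse to one node; a user synonym table is applied first.
    """
    g = str(gene).strip()
    if synonyms:
        g = synonyms.get(g, synonyms.get(g.upper(), g))
    return g.upper()


@dataclass
class ReferenceRegulon:
    """Directed TF -> target edges with per-edge source provenance."""

    graph: nx.DiGraph
    tfs: set[str]

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    def provenance(self, regulator: str, target: str) -> frozenset[str]:
        return self.graph.edges[regulator, target]["sources"]


@dataclass
class ContextGRN:
    """Subgraph of the reference retained under one context's filter."""

    context: str
    graph: nx.DiGraph
    n_reference_edges: int = 0

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())


@dataclass
class CombinedGRN:
    """Union of two context GRNs with per-edge/per-node class and F1.

    Edge attribute ``cls`` and node attributes ``cls``, ``tp``, ``fp``,
    ``fn``, ``f1`` are in {both, A_only, B_only} / confusion counts.
    """

    graph: nx.DiGraph
    context_a: str
    context_b: str
    tfs: set[str] = field(default_factory=set)

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "node": n,
                "cls": d["cls"],
                "tp": d["tp"],
                "fp": d["fp"],
                "fn": d["fn"],
                "f1": d["f1"],
                "is_tf": n in self.tfs,
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"regulator": u, "target": v, "cls": d["cls"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows)


def merge_reference_networks(
    edge_tables: list[pd.DataFrame],
    source_names: list[str] | None = None,
    synonyms: dict[str, str] | None = None,
    allow_self_loops: bool = False,
) -> ReferenceRegulon:
    """Union of TF -> target edge tables with provenance tracking.

    Each table needs ``regulator`` and ``target`` columns.  Ids are
    canonicalized (uppercase + synonyms), duplicate edges are merged and
    their provenance sets unioned.  Merging is idempotent.
    """
    if source_names is None:
        source_names = [f"source{i + 1}" for i in range(len(edge_tables))]
    if len(source_names) != len(edge_tables):
        raise ValueError("one source name per edge table required")
    g = nx.DiGraph()
    tfs: set[str] = set()
    for table, name in zip(edge_tables, source_names):
        if not {"regulator", "target"}.issubset(table.columns):
            raise ValueError(
                f"edge table {name!r} must have regulator/target columns"
            )
        for lineno, row in enumerate(table.itertuples(index=False), start=2):
            reg = canonical(row.regulator, synonyms)
            tgt = canonical(row.target, synonyms)
            if not reg or not tgt or reg == "NAN" or tgt == "NAN":
                raise ValueError(f"malformed row {lineno} in {name!r}")
            if reg == tgt and not allow_self_loops:
                logger.warning("dropping self-loop %s -> %s (%s line %d)",
                               reg, tgt, name, lineno)
                continue
            tfs.add(reg)
            if g.has_edge(reg, tgt):
                g.edges[reg, tgt]["sources"] = (
                    g.edges[reg, tgt]["sources"] | {name}
                )
            else:
                g.add_edge(reg, tgt, sources=frozenset({name}))
    if g.number_of_edges() == 0:
        raise ValueError("merged reference network is empty")
    return ReferenceRegulon(graph=g, tfs=tfs)


def build_context_grn(
    reference: ReferenceRegulon,
    norm,
    context_samples: list[str],
    tau_expr: float = 10.0,
    context: str = "context",
    synonyms: dict[str, str] | None = None,
) -> ContextGRN:
    """Filter the reference to TFs expressed in one context.

    An edge is retained iff its regulator has normalized count > 0 in at
    least one of the context's replicates AND mean normalized count
    > tau_expr across them (both inequalities strict).  Target
    expression is not a criterion.  TFs absent from the expression
    matrix are treated as not expressed (logged).
    """
    if len(context_samples) == 0:
        raise ValueError("context has no samples")
    values = norm.values if hasattr(norm, "values") and not isinstance(
        norm, pd.DataFrame) else norm
    sub = values[list(context_samples)]
    lookup = {canonical(g, synonyms): i for i, g in enumerate(sub.index)}
    arr = sub.to_numpy(dtype=float)

    expressed: dict[str, bool] = {}
    missing: list[str] = []
    for tf in reference.tfs:
        i = lookup.get(tf)
        if i is None:
            missing.append(tf)
            expressed[tf] = False
            continue
        row = arr[i]
        expressed[tf] = bool((row > 0).any() and row.mean() > tau_expr)
    if missing:
        logger.info("%s: %d reference TFs absent from the expression "
                    "matrix, treated as not expressed", context, len(missing))

    g = nx.DiGraph()
    for u, v, d in reference.graph.edges(data=True):
        if expressed[u]:
            g.add_edge(u, v, **d)
    grn = ContextGRN(context=context, graph=g,
                     n_reference_edges=reference.graph.number_of_edges())
    assert grn.edges <= reference.edges
    return grn


def _incident(graph: nx.DiGraph, node: str) -> set[tuple[str, str]]:
    if node not in graph:
        return set()
    return set(graph.out_edges(node)) | set(graph.in_edges(node))


def node_f1(
    node: str, grn_a: ContextGRN | nx.DiGraph, grn_b: ContextGRN | nx.DiGraph
) -> tuple[int, int, int, float | None]:
    """Per-node confusion counts and F1 between two context GRNs.

    The node's incident edge set (incoming plus outgoing) in context A
    is compared against context B: TP = shared, FN = A-only, FP =
    B-only, F1 = 2TP / (2TP + FP + FN).  Returns F1 = None when the
    node has no incident edge in either context; raises if the node is
    unknown to both graphs.
    """
    ga = grn_a.graph if isinstance(grn_a, ContextGRN) else grn_a
    gb = grn_b.graph if isinstance(grn_b, ContextGRN) else grn_b
    if node not in ga and node not in gb:
        raise KeyError(f"node {node!r} unknown to both contexts")
    ea, eb = _incident(ga, node), _incident(gb, node)
    tp = len(ea & eb)
    fn = len(ea - eb)
    fp = len(eb - ea)
    if tp + fp + fn == 0:
        return tp, fp, fn, None
    return tp, fp, fn, 2.0 * tp / (2.0 * tp + fp + fn)


def compare_grns(grn_a: ContextGRN, grn_b: ContextGRN,
                 tfs: set[str] | None = None) -> CombinedGRN:
    """Union graph of two contexts with edge/node classes and F1."""
    ga, gb = grn_a.graph, grn_b.graph
    union = nx.DiGraph()
    for u, v in ga.edges():
        cls = "both" if gb.has_edge(u, v) else "A_only"
        union.add_edge(u, v, cls=cls)
    for u, v in gb.edges():
        if not ga.has_edge(u, v):
            union.add_edge(u, v, cls="B_only")
    for n in union.nodes():
        in_a, in_b = n in ga, n in gb
        cls = "both" if in_a and in_b else ("A_only" if in_a else "B_only")
        tp, fp, fn, f1 = node_f1(n, ga, gb)
        union.nodes[n].update(cls=cls, tp=tp, fp=fp, fn=fn, f1=f1)
    return CombinedGRN(graph=union, context_a=grn_a.context,
                       context_b=grn_b.context, tfs=tfs or set())


def select_varying_genes(combined: CombinedGRN,
                         f1_max: float = 0.99) -> list[str]:
    """Nodes whose local topology differs between contexts (F1 < f1_max).

    Strict inequality; sorted by ascending F1 then id.
    """
    hits = [
        (d["f1"], n)
        for n, d in combined.graph.nodes(data=True)
        if d["f1"] is not None and d["f1"] < f1_max
    ]
    return [n for _, n in sorted(hits)]


def module_subnetwork(
    combined: CombinedGRN,
    modules: pd.Series | dict[str, str],
    de: pd.DataFrame | None = None,
) -> nx.DiGraph:
    """Combined-GRN subgraph induced on module-labeled genes.

    Keeps regulatory edges among genes carrying a module label (not
    "unassigned"); nodes left without any incident edge are removed as
    isolates (count recorded in ``graph.graph['n_isolates_removed']``).
    Nodes are annotated with module, context class and DE status.
    """
    labels = dict(modules.items() if isinstance(modules, pd.Series)
                  else modules.items())
    keep = {canonical(g): m for g, m in labels.items() if m != "unassigned"}
    sub = combined.graph.subgraph(
        [n for n in combined.graph if n in keep]).copy()
    isolates = [n for n in sub if sub.degree(n) == 0]
    sub.remove_nodes_from(isolates)
    sub.graph["n_isolates_removed"] = len(isolates)
    if isolates:
        logger.info("module subnetwork: removed %d isolated nodes",
                    len(isolates))
    de_status = {}
    if de is not None:
        de_status = {canonical(g): s for g, s in de["status"].items()}
    for n in sub:
        sub.nodes[n]["module"] = keep[n]
        sub.nodes[n]["de_status"] = de_status.get(n, "ns")
    return sub


def neighbor_expansion(
    graph: nx.DiGraph,
    genes,
    order: int = 2,
    mode: str = "undirected",
) -> set[str]:
    """Input genes plus all nodes within ``order`` steps.

    ``undirected`` mode ignores edge direction; ``regulators`` mode
    iterates in-neighbors only (the regulators of the regulators).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if mode not in ("undirected", "regulators"):
        raise ValueError(f"unknown mode {mode!r}")
    frontier = {g for g in genes if g in graph}
    result = set(frontier)
    und = graph.to_undirected(as_view=True) if mode == "undirected" else None
    for _ in range(order):
        nxt = set()
        for n in frontier:
            if mode == "undirected":
                nxt.update(und.neighbors(n))
            else:
                nxt.update(graph.predecessors(n))
        frontier = nxt - result
        result |= nxt
        if not frontier:
            break
    return result
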