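"""Readers and writers for the pipeline's tabular and network formats.

Canonical dialect: tab-separated tables with header rows.  Networks are
written as SIF (relation "regulates" for GRN edges, "pp" for PPI) and
GraphML for Cytoscape import.  All round trips are loss-less on
canonical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .expression import CountMatrix

logger = logging.getLogger(__name__)


def _read_table(path, sep: str = "\t") -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep)
    except Exception as exc:  # re-raise with the file named
        raise ValueError(f"{path}: malformed table ({exc})") from exc


def read_counts(path, design_path=None, sep: str = "\t") -> CountMatrix:
    """Gene x sample count table; first column = gene ids."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    bad = df.index[df.lt(0).any(axis=1)]
    if len(bad):
        row = df.index.get_loc(bad[0]) + 2  # header + 1-based
        raise ValueError(f"{path}: negative count at line {row} "
                         f"(gene {bad[0]!r})")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene id {dup!r}")
    design = read_design(design_path, sep=sep) if design_path else \
        pd.DataFrame({"condition": "unknown", "replicate": 0},
                     index=df.columns)
    return CountMatrix(counts=df, design=design)


def read_design(path, sep: str = "\t") -> pd.DataFrame:
    df = _read_table(path, sep)
    needed = {"sample", "condition", "replicate"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: design needs columns {sorted(needed)}")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample id")
    return df.set_index("sample")


def write_design(design: pd.DataFrame, path) -> None:
    design.reset_index().rename(columns={"index": "sample"}).to_csv(
        path, sep="\t", index=False)


def read_edges(path, sep: str = "\t") -> pd.DataFrame:
    """Edge-list table with regulator/target (+ optional source)."""
    df = _read_table(path, sep)
    if not {"regulator", "target"}.issubset(df.columns):
        raise ValueError(f"{path}: needs regulator/target columns")
    na = df[["regulator", "target"]].isna().any(axis=1)
    if na.any():
        raise ValueError(f"{path}: malformed row at line "
                         f"{int(na.idxmax()) + 2}")
    extra = set(df.columns) - {"regulator", "target", "source"}
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, sorted(extra))
    return df


def read_ppi(path, sep: str = "\t") -> pd.DataFrame:
    """protein1/protein2/combined_score; 0-1000 scores auto-normalized."""
    df = _read_table(path, sep)
    needed = {"protein1", "protein2", "combined_score"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: PPI needs columns {sorted(needed)}")
    if df["combined_score"].max() > 1.0:
        logger.info("%s: scores look 0-1000 scaled; normalizing to [0, 1]",
                    path)
        df = df.assign(combined_score=df["combined_score"] / 1000.0)
    if ((df["combined_score"] < 0) | (df["combined_score"] > 1)).any():
        raise ValueError(f"{path}: PPI scores outside [0, 1] after scaling")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT rows need "
                                 "name, description and >= 1 member")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path,
              description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            members = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def write_sif(graph: nx.Graph, path, relation: str | None = None) -> None:
    """SIF export; 'regulates' for directed, 'pp' for undirected."""
    if relation is None:
        relation = "regulates" if graph.is_directed() else "pp"
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for n in sorted(nx.isolates(graph)):
            fh.write(f"{n}\n")


def read_sif(path, directed: bool = True) -> nx.Graph:
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif len(parts) >= 3:
                g.add_edge(parts[0], parts[2], relation=parts[1])
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML with attributes coerced to GraphML-safe scalars."""
    g = graph.copy()
    for _, d in g.nodes(data=True):
        _sanitize(d)
    for _, _, d in g.edges(data=True):
        _sanitize(d)
    g.graph.clear()
    nx.write_graphml(g, path)


def _sanitize(d: dict) -> None:
    for k, v in list(d.items()):
        if v is None:
            d[k] = ""
        elif isinstance(v, (frozenset, set, list, tuple)):
            d[k] = ",".join(sorted(map(str, v)))
        elif not isinstance(v, (str, int, float, bool)):
            d[k] = str(v)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def write_ground_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_synthetic_dataset(outdir, regulon, truth, counts, ppi,
                            gene_sets) -> dict[str, str]:
    """Write all synthetic artifacts to a directory; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "regulon": out / "reference_regulon.tsv",
        "regulon_sif": out / "reference_regulon.sif",
        "ppi": out / "ppi.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "ground_truth": out / "ground_truth.json",
    }
    counts.counts.to_csv(paths["counts"], sep="\t")
    write_design(counts.design, paths["design"])
    edges = pd.DataFrame(
        [(u, v, ",".join(sorted(d["sources"])))
         for u, v, d in sorted(regulon.graph.edges(data=True))],
        columns=["regulator", "target", "source"])
    edges.to_csv(paths["regulon"], sep="\t", index=False)
    write_sif(regulon.graph, paths["regulon_sif"])
    ppi.to_csv(paths["ppi"], sep="\t", index=False)
    write_gmt(gene_sets, paths["gene_sets"])
    write_ground_truth(truth, paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
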