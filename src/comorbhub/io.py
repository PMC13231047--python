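"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression and phenotype tables are TSV; gene sets are GMT; protein networks
are STRING-dialect TSV (node1, node2, combined_score on a 0-1000 integer
scale) or SIF; derived networks round-trip through SIF and GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import ExpressionMatrix, SyntheticTruth


# ---------------------------------------------------------------- expression

def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_expression_tsv(path, phenotype_path=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    group = surv = None
    if phenotype_path is not None:
        pheno = read_phenotype_tsv(phenotype_path)
        group = pheno["group"]
        if "time_days" in pheno.columns:
            surv = pheno.loc[pheno["time_days"].notna(), ["time_days", "event"]].copy()
            surv["event"] = surv["event"].astype(int)
    return ExpressionMatrix(df, group, surv)


def write_phenotype_tsv(expr: ExpressionMatrix, path) -> None:
    pheno = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
    pheno["group"] = expr.sample_group
    if expr.survival is not None:
        pheno["time_days"] = expr.survival["time_days"]
        pheno["event"] = expr.survival["event"]
    pheno.to_csv(path, sep="\t")


def read_phenotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ----------------------------------------------------------------------- GMT

def write_gmt(collection: dict[str, list[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in collection.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    collection: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {i}")
            collection[parts[0]] = parts[2:]
    return collection


# ------------------------------------------------------------------ networks

def write_string_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edge_table(path) -> pd.DataFrame:
    """Read a STRING-dialect TSV or SIF file into (node1, node2, combined_score).

    SIF carries no scores; its edges are assigned the maximum score 1000.
    """
    path = Path(path)
    if path.suffix.lower() == ".sif":
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}: malformed SIF line {i}")
                src, _rel, targets = parts[0], parts[1], parts[2:]
                for t in targets:
                    rows.append((src, t, 1000))
        return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])
    df = pd.read_csv(path, sep="\t")
    expected = {"node1", "node2", "combined_score"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}")
    if df[["node1", "node2", "combined_score"]].isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # +2: header + 1-based
        raise ValueError(f"{path}: malformed line {bad}")
    return df


def write_sif(graph: nx.Graph, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v, data in graph.edges(data=True):
            rel = data.get("relation", relation)
            fh.write(f"{u}\t{rel}\t{v}\n")
        for n in graph.nodes:
            if graph.degree(n) == 0:
                fh.write(f"{n}\n")


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if not parts or parts == [""]:
                continue
            if len(parts) == 1:
                g.add_node(parts[0])
            else:
                src, rel, targets = parts[0], parts[1], parts[2:]
                for t in targets:
                    g.add_edge(src, t, relation=rel)
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


# --------------------------------------------------------- tables, sets, JSON

def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_truth(truth: SyntheticTruth, path) -> None:
    write_json(truth.to_dict(), path)


def read_truth(path) -> SyntheticTruth:
    return SyntheticTruth.from_dict(read_json(path))
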