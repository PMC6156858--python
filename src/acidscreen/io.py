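"""Readers and writers for the plain-text formats the pipeline exchanges.

Ontologies travel either as a minimal OBO file (only ``[Term]``, ``id:``,
``name:`` and ``is_a:`` lines) or as a two-column child/parent edge list;
annotations as two-column gene/term TSV; plates as long-format CSV; count
matrices as TSV with genes in rows.
"""

from __future__ import annotations

import networkx as nx
import obonet
import pandas as pd

PLATE_COLUMNS = ["plate_id", "well", "role", "compound_id", "intensity"]


def read_obo(path) -> nx.DiGraph:
    """Read a (possibly minimal) OBO file into a child->parent DiGraph.

    Only ``is_a`` relationships are kept; node attribute ``name`` carries the
    term name when present.
    """
    multi = obonet.read_obo(path)
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, name=data.get("name", node))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return g


def write_obo(ontology: nx.DiGraph, path, ontology_name: str = "synthetic") -> None:
    """Write a child->parent term graph as a minimal OBO file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n")
        for term in sorted(ontology.nodes):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {ontology.nodes[term].get('name', term)}\n")
            for parent in sorted(ontology.successors(term)):
                fh.write(f"is_a: {parent}\n")


def read_edge_list(path) -> nx.DiGraph:
    """Read a two-column (child, parent) TSV into a DiGraph."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.DiGraph()
    for child, parent in df.itertuples(index=False):
        g.add_edge(child, parent)
    # isolated roots never appear as children; ensure all parents are nodes
    return g


def write_edge_list(ontology: nx.DiGraph, path) -> None:
    rows = sorted(ontology.edges)
    pd.DataFrame(rows, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read a two-column (gene, term) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["gene", "term"]
    return df


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations[["gene", "term"]].to_csv(path, sep="\t", index=False)


def read_plates(path) -> pd.DataFrame:
    """Read a long-format plate CSV (plate_id, well, role, compound_id, intensity)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str, "compound_id": str})
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    return df[PLATE_COLUMNS]


def write_plates(plates: pd.DataFrame, path) -> None:
    plates[PLATE_COLUMNS].to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count matrix TSV (gene ids in the first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression TSV (gene_id, log2fc, pvalue, padj)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = {"gene_id", "log2fc", "pvalue", "padj"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return df


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=False)
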