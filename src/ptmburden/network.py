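"""Interaction network of PTM^mut-harboring genes and patient-level
co-occurrence.

The network is the induced subgraph of the interaction edge list on the
genes carrying at least one PTM^mut; self-loops are kept as homotypic
interactions, and genes with no interaction among themselves are
excluded.  Node degree counts a homotypic self-interaction once (one
biological partner); functional flags mark genes whose PTM^mut overlap
an annotated functional region.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def build_network(
    ptm_genes: set,
    interactions: pd.DataFrame,
    functional_genes: set | None = None,
) -> nx.Graph:
    """Induced interaction subgraph on PTM^mut-harboring genes.

    Node attributes: ``total_degree`` (self-loop counted once),
    ``homotypic`` (has a self-interaction) and ``functional_flag``
    (PTM^mut in a functional region, from ``functional_genes``).
    """
    functional_genes = functional_genes or set()
    g = nx.Graph()
    for a, b in zip(interactions["gene_a"], interactions["gene_b"]):
        if a in ptm_genes and b in ptm_genes:
            g.add_edge(min(a, b), max(a, b))
    for node in g.nodes:
        has_loop = g.has_edge(node, node)
        g.nodes[node]["total_degree"] = g.degree(node) - (1 if has_loop else 0)
        g.nodes[node]["homotypic"] = has_loop
        g.nodes[node]["functional_flag"] = node in functional_genes
    return g


def network_table(g: nx.Graph) -> pd.DataFrame:
    """Node table (gene, total_degree, homotypic, functional_flag)."""
    rows = [
        {
            "gene": n,
            "total_degree": d["total_degree"],
            "homotypic": d["homotypic"],
            "functional_flag": d["functional_flag"],
        }
        for n, d in sorted(g.nodes(data=True))
    ]
    return pd.DataFrame(
        rows, columns=["gene", "total_degree", "homotypic", "functional_flag"]
    )


def patient_cooccurrence(
    annotated: pd.DataFrame, interactions: pd.DataFrame
) -> pd.DataFrame:
    """Samples carrying PTM^mut in both genes of an interacting pair.

    One row per (sample, unordered heterodimeric gene pair); homotypic
    (self) interactions are excluded.
    """
    ptm = annotated.loc[annotated["is_ptm_mut"], ["sample", "gene"]].drop_duplicates()
    edges = {
        (min(a, b), max(a, b))
        for a, b in zip(interactions["gene_a"], interactions["gene_b"])
        if a != b
    }
    pairs = ptm.merge(ptm, on="sample", suffixes=("_a", "_b"))
    pairs = pairs[pairs["gene_a"] < pairs["gene_b"]]
    keep = [
        (a, b) in edges for a, b in zip(pairs["gene_a"], pairs["gene_b"])
    ]
    out = pairs[keep].sort_values(
        ["sample", "gene_a", "gene_b"], ignore_index=True
    )
    return out[["sample", "gene_a", "gene_b"]]


def cooccurrence_test(
    n_cooccurring_matrisome: int,
    n_other_matrisome: int,
    n_cooccurring_rest: int,
    n_other_rest: int,
    yates: bool = False,
) -> dict:
    """Two-sided chi-square comparing co-occurring vs non-co-occurring
    PTM^mut counts between matrisome and rest gene sets."""
    table = np.array(
        [
            [n_cooccurring_matrisome, n_other_matrisome],
            [n_cooccurring_rest, n_other_rest],
        ],
        dtype=float,
    )
    if table.sum() == 0 or (table.sum(axis=1) == 0).any() or (
        table.sum(axis=0) == 0
    ).any():
        log.warning("cooccurrence_test: degenerate 2x2 table; p missing")
        return {"chi2": float("nan"), "p_value": float("nan")}
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return {"chi2": float(stat), "p_value": float(p)}


def healthy_filter(
    ptm_muts: pd.DataFrame,
    normal_variants: pd.DataFrame,
    key: tuple[str, ...] = ("gene", "position"),
) -> tuple[pd.DataFrame, int]:
    """Set-difference filter against variants seen in healthy samples.

    ``normal_variants`` is keyed by (gene, position) by default; the key
    may include an allele column for stricter matching.  Returns the
    retained records and the number removed.
    """
    if normal_variants.empty:
        return ptm_muts.copy(), 0
    mut_key_cols = {"gene": "gene", "position": "aa_start"}
    seen = set(
        zip(*(normal_variants[k] for k in key))
    )
    keys = zip(*(ptm_muts[mut_key_cols.get(k, k)] for k in key))
    keep = [k not in seen for k in keys]
    retained = ptm_muts[keep]
    return retained.reset_index(drop=True), int(len(ptm_muts) - len(retained))


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, str(path))


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [{"gene_a": min(a, b), "gene_b": max(a, b)} for a, b in g.edges]
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).sort_values(
        ["gene_a", "gene_b"]
    ).to_csv(path, sep="\t", index=False)
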