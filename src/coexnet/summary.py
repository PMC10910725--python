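"""Downstream network summaries.

Per-contrast hub genes (highest labelled degree), transcription-factor
first-neighbour subnetworks around the hubs, exclusive Venn overlaps of
gene sets across contrasts, and a hypergeometric over-representation test
of cluster members against GMT gene sets.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .pcit import LabeledNetwork
from .prep import bh_adjust

__all__ = [
    "hub_per_contrast",
    "tf_first_neighbors",
    "contrast_overlap",
    "enrichment_hypergeom",
]


def hub_per_contrast(network: LabeledNetwork) -> pd.DataFrame:
    """Most interconnected gene per contrast label.

    Degree counts edges of that label only; ties break by gene ID.  The
    degree share is hub degree / number of that label's edges.  Labels
    with no edges are omitted with a warning.
    """
    rows = []
    for label in sorted(network.label_counts):
        sub = network.edges[network.edges["label"] == label]
        if sub.empty:
            warnings.warn(f"contrast {label} has no edges; omitted from hub "
                          "report", stacklevel=2)
            continue
        deg = pd.concat([sub["gene_a"], sub["gene_b"]]).value_counts()
        top = deg.max()
        hub = min(deg.index[deg == top])
        tf_neighbors = []
        if "is_tf" in network.nodes.columns:
            nbrs = set(sub.loc[sub["gene_a"] == hub, "gene_b"]) | \
                set(sub.loc[sub["gene_b"] == hub, "gene_a"])
            tfs = set(network.nodes.index[network.nodes["is_tf"]])
            tf_neighbors = sorted(nbrs & tfs)
        rows.append({
            "label": label,
            "hub": hub,
            "degree": int(top),
            "degree_share": float(top) / len(sub),
            "tf_first_neighbors": tf_neighbors,
        })
    return pd.DataFrame(rows).set_index("label") if rows else \
        pd.DataFrame(columns=["hub", "degree", "degree_share",
                              "tf_first_neighbors"])


def tf_first_neighbors(
    network: LabeledNetwork, hubs, node_flags: pd.DataFrame | None = None
) -> nx.MultiGraph:
    """Induced subnetwork of hubs and their transcription-factor neighbours.

    Edges are restricted to hub-TF adjacencies with contrast labels
    preserved; a hub with no TF neighbours appears as an isolated node.
    """
    flags = node_flags if node_flags is not None else network.nodes
    hubs = list(hubs)
    node_universe = set(network.edges["gene_a"]) | set(network.edges["gene_b"])
    for h in hubs:
        if h not in node_universe:
            raise ValueError(f"hub {h!r} absent from network")
    tfs = set(flags.index[flags["is_tf"]]) if "is_tf" in flags.columns else set()
    g = nx.MultiGraph()
    for h in hubs:
        g.add_node(h, is_hub=True, is_tf=h in tfs)
    for row in network.edges.itertuples(index=False):
        for h, other in ((row.gene_a, row.gene_b), (row.gene_b, row.gene_a)):
            if h in hubs and other in tfs:
                if not g.has_node(other):
                    g.add_node(other, is_hub=other in hubs, is_tf=True)
                if not g.has_edge(h, other, key=row.label):
                    g.add_edge(h, other, key=row.label, label=row.label,
                               r=float(row.r))
                break
    return g


def contrast_overlap(sets: dict[str, set]) -> dict:
    """Exclusive Venn regions over named gene sets.

    Returns {"regions": {"A&B": count, ...}, "members": {...}} with one
    entry per non-empty combination of set names (2^k - 1 regions); region
    counts sum to the union size.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(sets)
    regions: dict[str, int] = {}
    members: dict[str, list] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set.union(set(), *(set(sets[n]) for n in names
                                         if n not in combo))
            exclusive = inside - outside
            key = "&".join(combo)
            regions[key] = len(exclusive)
            members[key] = sorted(exclusive)
    return {"regions": regions, "members": members}


def enrichment_hypergeom(
    cluster_genes, gene_sets: dict[str, set], universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a cluster.

    For each gene set: P(overlap >= observed) drawing |cluster| genes from
    the universe, of which |set ∩ universe| are marked.  BH correction is
    applied across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    cluster = set(cluster_genes)
    if not cluster <= universe:
        raise ValueError("cluster genes must be a subset of the universe")
    M, n_draw = len(universe), len(cluster)
    rows = []
    for name in sorted(gene_sets):
        marked = set(gene_sets[name]) & universe
        k = len(cluster & marked)
        p = float(hypergeom.sf(k - 1, M, len(marked), n_draw))
        rows.append({"gene_set": name, "overlap": k, "set_size": len(marked),
                     "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("gene_set") if rows else pd.DataFrame(
        columns=["overlap", "set_size", "pvalue"])
    if len(out):
        out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out
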