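"""PCIT edge significance and the labelled multi-contrast network.

For every trio of genes (x, y, z) the three first-order partial
correlations are computed; an information-theoretic tolerance

    eps = mean over defined terms of |r_xy.z / r_xy|, |r_xz.y / r_xz|,
          |r_yz.x / r_yz|

is averaged from them, and the direct edge (x, y) is eliminated if some z
dominates it: |r_xy| < eps * |r_xz| and |r_xy| < eps * |r_yz|.  Surviving
edges are additionally required to pass an absolute correlation floor
(|r| >= 0.8) and a distributional rule (|r| >= mean + 2 SD of all
off-diagonal |r|).  Per-contrast edge lists are merged into one labelled
multigraph keyed by (gene pair, contrast label).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CONTRAST_LABELS",
    "partial_correlation",
    "pcit_filter",
    "significant_edges",
    "build_network",
    "LabeledNetwork",
    "correlation_matrix",
]

CONTRAST_LABELS = ("RL", "RM", "DL", "DM", "BL", "BM")


def correlation_matrix(log_cpm: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlations of log-expression across samples.

    Constant genes correlate 0 with everything; the diagonal is 1.
    """
    E = log_cpm.to_numpy(dtype=float)
    c = E - E.mean(axis=1, keepdims=True)
    s = np.sqrt((c ** 2).sum(axis=1))
    zero = s == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant gene(s): correlations set to 0",
                      stacklevel=2)
    s[zero] = 1.0
    z = c / s[:, None]
    R = np.clip(z @ z.T, -1.0, 1.0)
    R[zero, :] = 0.0
    R[:, zero] = 0.0
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=log_cpm.index, columns=log_cpm.index)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z.

    Undefined when |r_xz| = 1 or |r_yz| = 1 (zero denominator): returns 0
    with a warning, mirroring how degenerate trios are flagged in the
    filter.
    """
    denom_sq = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if denom_sq <= 0.0:
        warnings.warn("degenerate trio (|r| = 1): partial correlation set to 0",
                      stacklevel=2)
        return 0.0
    return (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)


def _partials_given_z(R: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, ...]:
    """All-pairs first-order partials for a fixed conditioning gene z.

    a = R[:, z].  Returns (p_xy, p_xz, p_yz) where p_xy[x, y] = r_xy.z,
    p_xz[x, y] = r_xz.y and p_yz[x, y] = r_yz.x; degenerate denominators
    yield 0.
    """
    one_a = 1.0 - a ** 2                      # (n,)
    one_R = 1.0 - R ** 2                      # (n, n)

    def safe_div(num, d2):
        out = np.zeros_like(num)
        ok = d2 > 0
        out[ok] = num[ok] / np.sqrt(d2[ok])
        return out

    p_xy = safe_div(R - np.outer(a, a), np.outer(one_a, one_a))
    p_xz = safe_div(a[:, None] - R * a[None, :], one_R * one_a[None, :])
    p_yz = safe_div(a[None, :] - R * a[:, None], one_R * one_a[:, None])
    return p_xy, p_xz, p_yz


def pcit_filter(R: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Boolean matrix of PCIT-retained edges (True = edge survives).

    Vectorised over the conditioning gene: for each z, the tolerance eps is
    averaged over the ratio terms whose direct correlation is non-zero; a
    trio in which all three direct correlations are zero eliminates
    nothing.  With fewer than three genes every edge is retained.
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    retained = np.ones((n, n), dtype=bool)
    np.fill_diagonal(retained, False)
    if n < 3:
        return retained
    absR = np.abs(R)
    for z in range(n):
        a = R[:, z]
        p_xy, p_xz, p_yz = _partials_given_z(R, a)
        abs_a = np.abs(a)
        d_xy = absR > 0                       # direct corr defined for ratio
        d_xz = (abs_a > 0)[:, None] & np.ones((n, n), bool)
        d_yz = (abs_a > 0)[None, :] & np.ones((n, n), bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_xy = np.where(d_xy, np.abs(p_xy) / np.where(d_xy, absR, 1.0), 0.0)
            t_xz = np.where(d_xz, np.abs(p_xz) / np.where(d_xz, abs_a[:, None], 1.0), 0.0)
            t_yz = np.where(d_yz, np.abs(p_yz) / np.where(d_yz, abs_a[None, :], 1.0), 0.0)
        n_terms = d_xy.astype(int) + d_xz.astype(int) + d_yz.astype(int)
        valid = n_terms > 0
        eps = np.zeros((n, n))
        eps[valid] = (t_xy + t_xz + t_yz)[valid] / n_terms[valid]
        elim = valid & (absR < eps * abs_a[:, None]) & (absR < eps * abs_a[None, :])
        elim[z, :] = False
        elim[:, z] = False
        np.fill_diagonal(elim, False)
        retained &= ~elim
    return retained


def significant_edges(
    R: pd.DataFrame,
    retained: np.ndarray,
    label: str,
    abs_threshold: float = 0.8,
    sd_mult: float = 2.0,
) -> pd.DataFrame:
    """Edge list for one contrast: PCIT-retained AND |r| >= abs_threshold
    AND |r| >= mean + sd_mult * SD of all off-diagonal |r|.

    Rows are (gene_a < gene_b, r, label); a degenerate SD of 0 disables the
    distributional rule with a warning.
    """
    genes = R.index.to_numpy()
    mat = R.to_numpy(dtype=float)
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    absr = np.abs(mat[iu])
    if n < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r", "label"])
    sd = absr.std(ddof=0)
    if sd == 0:
        warnings.warn("degenerate |r| SD = 0: only the absolute threshold applies",
                      stacklevel=2)
        dist_cut = -np.inf
    else:
        dist_cut = absr.mean() + sd_mult * sd
    keep = retained[iu] & (absr >= abs_threshold) & (absr >= dist_cut)
    ga, gb = genes[iu[0][keep]], genes[iu[1][keep]]
    swap = ga > gb
    ga2 = np.where(swap, gb, ga)
    gb2 = np.where(swap, ga, gb)
    edges = pd.DataFrame(
        {"gene_a": ga2, "gene_b": gb2, "r": mat[iu][keep], "label": label}
    )
    return edges.sort_values(["gene_a", "gene_b"], kind="mergesort",
                             ignore_index=True)


@dataclass
class LabeledNetwork:
    """Union of per-contrast edge lists as a multigraph keyed by label.

    ``edges`` has columns gene_a, gene_b, r, label with gene_a < gene_b and
    no duplicate (pair, label); ``nodes`` carries the flag table restricted
    to genes with at least one significant edge.
    """

    edges: pd.DataFrame
    nodes: pd.DataFrame
    label_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_distinct_pairs(self) -> int:
        return len(self.edges[["gene_a", "gene_b"]].drop_duplicates())

    def to_multigraph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for gene, row in self.nodes.iterrows():
            g.add_node(gene, **{k: bool(v) if isinstance(v, (bool, np.bool_)) else v
                                for k, v in row.items()})
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, key=row.label,
                       r=float(row.r), label=row.label)
        return g

    def to_simple_graph(self) -> nx.Graph:
        """Collapse parallel labelled edges; labels retained as metadata."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes.index)
        for (a, b), grp in self.edges.groupby(["gene_a", "gene_b"], sort=True):
            g.add_edge(a, b, labels="|".join(sorted(grp["label"])),
                       r=float(grp["r"].iloc[0]))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_multigraph(), path)

    def write_gml(self, path) -> None:
        nx.write_gml(self.to_multigraph(), str(path))


def build_network(
    per_contrast_edges: dict[str, pd.DataFrame], nodes: pd.DataFrame
) -> LabeledNetwork:
    """Merge labelled edge lists; keep only nodes with >= 1 edge."""
    frames = []
    counts: dict[str, int] = {}
    for label, edges in sorted(per_contrast_edges.items()):
        if label not in CONTRAST_LABELS:
            raise ValueError(f"unknown contrast label {label!r}")
        counts[label] = len(edges)
        if len(edges):
            if (edges["label"] != label).any():
                raise ValueError(f"edge list for {label} carries foreign labels")
            frames.append(edges)
    if frames:
        edges = pd.concat(frames, ignore_index=True)
        if edges.duplicated(["gene_a", "gene_b", "label"]).any():
            raise ValueError("duplicate (pair, label) edge")
        if (edges["gene_a"] == edges["gene_b"]).any():
            raise ValueError("self-loop edge")
    else:
        edges = pd.DataFrame(columns=["gene_a", "gene_b", "r", "label"])
    connected = set(edges["gene_a"]) | set(edges["gene_b"])
    node_tab = nodes.loc[nodes.index.isin(connected)].copy()
    edges = edges.sort_values(["label", "gene_a", "gene_b"], kind="mergesort",
                              ignore_index=True)
    return LabeledNetwork(edges=edges, nodes=node_tab, label_counts=counts)
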