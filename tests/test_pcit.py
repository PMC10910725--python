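"""PCIT trio elimination, dual-threshold edges and the labelled network."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexnet.pcit import (CONTRAST_LABELS, build_network, correlation_matrix,
                          partial_correlation, pcit_filter, significant_edges)


# ------------------------------------------------- partial correlation

def test_partial_correlation_identity_when_z_uncorrelated():
    assert partial_correlation(0.6, 0.0, 0.0) == pytest.approx(0.6)


def test_partial_correlation_hand_value():
    # (0.9 - 0.64) / (1 - 0.64) = 0.7222...
    assert partial_correlation(0.9, 0.8, 0.8) == pytest.approx(0.26 / 0.36)


def test_partial_correlation_symmetric_in_xy():
    assert partial_correlation(0.5, 0.3, -0.7) == \
        pytest.approx(partial_correlation(0.5, -0.7, 0.3))


def test_partial_correlation_degenerate_returns_zero():
    with pytest.warns(UserWarning, match="degenerate"):
        assert partial_correlation(0.5, 1.0, 0.2) == 0.0


# ------------------------------------------------- pcit_filter

def _brute_force_pcit(R: np.ndarray) -> np.ndarray:
    """Plain triple loop written straight from the trio rule."""
    n = R.shape[0]
    keep = np.ones((n, n), bool)
    np.fill_diagonal(keep, False)

    def pc(a, b, c):
        d = (1 - b * b) * (1 - c * c)
        return 0.0 if d <= 0 else (a - b * c) / np.sqrt(d)

    for x, y in itertools.combinations(range(n), 2):
        for z in range(n):
            if z in (x, y):
                continue
            rxy, rxz, ryz = R[x, y], R[x, z], R[y, z]
            terms = []
            if rxy != 0:
                terms.append(abs(pc(rxy, rxz, ryz) / rxy))
            if rxz != 0:
                terms.append(abs(pc(rxz, rxy, ryz) / rxz))
            if ryz != 0:
                terms.append(abs(pc(ryz, rxy, rxz) / ryz))
            if not terms:
                continue
            eps = sum(terms) / len(terms)
            if abs(rxy) < eps * abs(rxz) and abs(rxy) < eps * abs(ryz):
                keep[x, y] = keep[y, x] = False
                break
    return keep


def test_pcit_two_nodes_retained():
    R = np.array([[1.0, 0.4], [0.4, 1.0]])
    assert pcit_filter(R)[0, 1]


def test_pcit_independent_third_gene_cannot_eliminate():
    R = np.eye(3)
    R[0, 1] = R[1, 0] = 0.9
    assert pcit_filter(R)[0, 1]


def test_pcit_weak_edge_dominated_by_third_gene():
    # x-y much weaker than both x-z and y-z: dominated, eliminated
    R = np.array([[1.0, 0.1, 0.5],
                  [0.1, 1.0, 0.5],
                  [0.5, 0.5, 1.0]])
    keep = pcit_filter(R)
    assert not keep[0, 1]
    assert keep[0, 2] and keep[1, 2]


def test_pcit_matches_brute_force_random_matrices():
    rng = np.random.default_rng(0)
    for _ in range(10):
        n = int(rng.integers(4, 14))
        A = rng.normal(size=(n, n + 3))
        R = np.corrcoef(A)
        assert np.array_equal(pcit_filter(R), _brute_force_pcit(R))


@settings(deadline=None, max_examples=15, derandomize=True)
@given(st.integers(0, 10_000))
def test_pcit_permutation_equivariant(seed):
    rng = np.random.default_rng(seed)
    n = 8
    R = np.corrcoef(rng.normal(size=(n, n + 4)))
    perm = rng.permutation(n)
    keep = pcit_filter(R)
    keep_p = pcit_filter(R[np.ix_(perm, perm)])
    assert np.array_equal(keep_p, keep[np.ix_(perm, perm)])


# ------------------------------------------------- significant_edges

def _frame(R, genes=None):
    genes = genes or [f"g{i}" for i in range(R.shape[0])]
    return pd.DataFrame(R, index=genes, columns=genes)


def test_edges_absolute_threshold_is_sharp():
    R = np.eye(3)
    R[0, 1] = R[1, 0] = 0.79
    R[0, 2] = R[2, 0] = 0.85
    Rf = _frame(R)
    keep = np.ones((3, 3), bool)
    edges = significant_edges(Rf, keep, "RL", abs_threshold=0.8, sd_mult=0.0)
    pairs = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
    assert ("g0", "g2") in pairs
    assert ("g0", "g1") not in pairs      # 0.79 < 0.80 stays out


def test_edges_degenerate_sd_keeps_absolute_rule():
    R = np.full((4, 4), 0.9)
    np.fill_diagonal(R, 1.0)
    keep = np.ones((4, 4), bool)
    with pytest.warns(UserWarning, match="degenerate"):
        edges = significant_edges(_frame(R), keep, "RL")
    assert len(edges) == 6                 # all pairs, |r| = 0.9 >= 0.8


def test_edges_rule_conjunction_matches_independent_oracle():
    rng = np.random.default_rng(5)
    n = 10
    base = rng.normal(size=(3, 40))
    A = base[rng.integers(0, 3, n)] + 0.45 * rng.normal(size=(n, 40))
    R = np.corrcoef(A)
    Rf = _frame(R)
    retained = pcit_filter(R)
    edges = significant_edges(Rf, retained, "DM")
    # oracle: apply the three rules independently
    absr = np.abs(R[np.triu_indices(n, 1)])
    cut = absr.mean() + 2.0 * absr.std()
    expect = set()
    for i, j in itertools.combinations(range(n), 2):
        if retained[i, j] and abs(R[i, j]) >= 0.8 and abs(R[i, j]) >= cut:
            expect.add((f"g{i}", f"g{j}"))
    got = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
    assert got == expect


def test_correlation_matrix_contract():
    rng = np.random.default_rng(2)
    E = pd.DataFrame(rng.normal(size=(6, 15)))
    E.iloc[3] = 2.5                        # constant gene
    with pytest.warns(UserWarning, match="constant"):
        R = correlation_matrix(E)
    mat = R.to_numpy()
    assert np.allclose(mat, mat.T, atol=1e-12)
    assert np.allclose(np.diag(mat), 1.0)
    assert (np.abs(mat) <= 1.0 + 1e-12).all()
    assert np.allclose(mat[3, [0, 1, 2, 4, 5]], 0.0)


# ------------------------------------------------- build_network

def _edge_df(pairs, label):
    return pd.DataFrame([{"gene_a": a, "gene_b": b, "r": r, "label": label}
                         for a, b, r in pairs])


def test_build_network_multigraph_counts():
    nodes = pd.DataFrame({"is_tf": [False] * 8, "is_secretome": [False] * 8},
                         index=[f"g{i}" for i in range(8)])
    rl = _edge_df([("g0", "g1", 0.9), ("g1", "g2", 0.85), ("g2", "g3", 0.95)], "RL")
    dl = _edge_df([("g0", "g1", 0.88), ("g3", "g4", 0.9), ("g4", "g5", 0.86),
                   ("g5", "g6", 0.84)], "DL")
    bm = _edge_df([("g1", "g2", 0.92), ("g0", "g2", 0.9), ("g0", "g3", 0.83),
                   ("g2", "g4", 0.81), ("g6", "g7", 0.89)], "BM")
    net = build_network({"RL": rl, "DL": dl, "BM": bm}, nodes)
    assert len(net.edges) == 12
    assert net.n_distinct_pairs == 10      # (g0,g1) and (g1,g2) shared
    assert net.label_counts == {"RL": 3, "DL": 4, "BM": 5}
    g = net.to_multigraph()
    assert g.number_of_edges() == 12
    assert net.to_simple_graph().number_of_edges() == 10


def test_build_network_empty_contrast_and_unknown_label():
    nodes = pd.DataFrame({"is_tf": [False]}, index=["g0"])
    empty = pd.DataFrame(columns=["gene_a", "gene_b", "r", "label"])
    net = build_network({"RL": empty}, nodes)
    assert net.label_counts["RL"] == 0 and len(net.edges) == 0
    with pytest.raises(ValueError, match="unknown"):
        build_network({"XX": empty}, nodes)


def test_build_network_drops_unconnected_nodes():
    nodes = pd.DataFrame({"is_tf": [True, False, False]},
                         index=["g0", "g1", "g2"])
    net = build_network({"RM": _edge_df([("g0", "g1", 0.9)], "RM")}, nodes)
    assert list(net.nodes.index) == ["g0", "g1"]


def test_contrast_labels_constant():
    assert set(CONTRAST_LABELS) == {"RL", "RM", "DL", "DM", "BL", "BM"}
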