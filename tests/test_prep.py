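"""Normalisation, filtering, BH and the NB-GLM contrast test."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexnet.prep import (ContrastResult, ContrastSpec, bh_adjust,
                          compute_cpm, de_test, filter_expressed,
                          select_top_fraction, standard_contrasts,
                          tmm_factors)
from coexnet.simulate import SimDesign, SimParams, simulate_counts


# ---------------------------------------------------------------- CPM

def test_cpm_basics():
    counts = pd.DataFrame({"a": [0, 50, 999950], "b": [10, 20, 30]},
                          index=["g1", "g2", "g3"])
    cpm = compute_cpm(counts)
    assert cpm.loc["g1", "a"] == 0.0
    assert cpm.loc["g2", "a"] == 50.0          # library is exactly 1e6


def test_cpm_zero_library_names_sample():
    counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(ValueError, match="b"):
        compute_cpm(counts)


def test_cpm_with_norm_factors_hand_oracle():
    counts = pd.DataFrame({"a": [10, 30, 60], "b": [5, 10, 35]},
                          index=["g1", "g2", "g3"])
    nf = pd.Series([2.0, 0.5], index=["a", "b"])
    cpm = compute_cpm(counts, nf)
    # effective libraries: 100*2=200, 50*0.5=25
    assert np.isclose(cpm.loc["g1", "a"], 10 / 200 * 1e6)
    assert np.isclose(cpm.loc["g3", "b"], 35 / 25 * 1e6)


# ---------------------------------------------------------------- filter

def test_filter_boundary_exactly_half():
    cpm = pd.DataFrame([[1.0, 1.0, 0.5, 0.5]], index=["g"])
    assert filter_expressed(cpm).loc["g"]          # 2 of 4 at >= 1 CPM


def test_filter_rule_counts():
    base = np.zeros((2, 10))
    base[0, :4] = 5.0      # 4 of 10 -> removed
    base[1, :5] = 5.0      # 5 of 10 -> retained
    mask = filter_expressed(pd.DataFrame(base, index=["g4", "g5"]))
    assert not mask.loc["g4"]
    assert mask.loc["g5"]


def test_filter_all_zero_removed_and_empty_errors():
    assert not filter_expressed(pd.DataFrame(np.zeros((1, 6)))).iloc[0]
    with pytest.raises(ValueError):
        filter_expressed(pd.DataFrame())


def test_filter_monotone_in_threshold(toy_counts):
    cpm = compute_cpm(toy_counts)
    kept_lo = filter_expressed(cpm, threshold=1.0).sum()
    kept_hi = filter_expressed(cpm, threshold=5.0).sum()
    assert kept_hi <= kept_lo


# ---------------------------------------------------------------- TMM

def test_tmm_identical_samples_unity():
    counts = pd.DataFrame(np.tile([[10], [200], [3000]], (1, 4)))
    assert np.allclose(tmm_factors(counts), 1.0)


def test_tmm_pure_scaling_gives_unit_factors():
    # doubling every count doubles the library; relative abundances are
    # unchanged, so all M-values vanish and both factors are 1
    rng = np.random.default_rng(0)
    a = rng.poisson(50, 200)
    counts = pd.DataFrame({"a": a, "b": 2 * a})
    assert np.allclose(tmm_factors(counts), [1.0, 1.0])


def _naive_tmm(counts: np.ndarray) -> np.ndarray:
    """Independent straight-line TMM: no vectorisation tricks."""
    lib = counts.sum(axis=0)
    q = [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])]
    ref = int(np.argmin([abs(x - np.mean(q)) for x in q]))
    out = []
    for j in range(counts.shape[1]):
        obs, refc = counts[:, j].astype(float), counts[:, ref].astype(float)
        nO, nR = lib[j], lib[ref]
        rows = [(np.log2((o / nO) / (r / nR)),
                 0.5 * (np.log2(o / nO) + np.log2(r / nR)),
                 (nO - o) / (nO * o) + (nR - r) / (nR * r))
                for o, r in zip(obs, refc) if o > 0 and r > 0]
        if not rows or max(abs(m) for m, _, _ in rows) < 1e-6:
            out.append(1.0)
            continue
        n = len(rows)

        def avg_ranks(vals):
            order = sorted(range(n), key=lambda i: vals[i])
            ranks = {}
            k = 0
            while k < n:
                j = k
                while j + 1 < n and vals[order[j + 1]] == vals[order[k]]:
                    j += 1
                mean_rank = (k + j) / 2 + 1
                for t in range(k, j + 1):
                    ranks[order[t]] = mean_rank
                k = j + 1
            return ranks

        rank_m = avg_ranks([r[0] for r in rows])
        rank_a = avg_ranks([r[1] for r in rows])
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        keep = [i for i in range(n)
                if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a]
        num = sum(rows[i][0] / rows[i][2] for i in keep)
        den = sum(1.0 / rows[i][2] for i in keep)
        out.append(2.0 ** (num / den))
    out = np.asarray(out)
    return out / np.exp(np.mean(np.log(out)))


def test_tmm_matches_naive_oracle():
    rng = np.random.default_rng(7)
    mu = rng.lognormal(3.0, 1.5, (250, 1)) * np.array([1.0, 1.8, 0.6, 1.2])
    counts = pd.DataFrame(rng.poisson(mu), columns=list("abcd"))
    # the naive oracle has no tie handling; perturb to make ranks unique
    counts += rng.integers(0, 2, counts.shape)
    got = tmm_factors(counts).to_numpy()
    want = _naive_tmm(counts.to_numpy())
    assert np.allclose(got, want, atol=1e-10)


def test_tmm_matches_edger(tmp_path):
    """Independent cross-check against Bioconductor edgeR::calcNormFactors."""
    rng = np.random.default_rng(42)
    mu = rng.lognormal(3.0, 1.5, (300, 1)) * np.array([1.0, 2.0, 0.5, 1.5])
    counts = pd.DataFrame(rng.poisson(mu), columns=list("abcd"))
    csv = tmp_path / "m.tsv"
    counts.to_csv(csv, sep="\t", index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(edgeR))
        m <- as.matrix(read.delim('{csv}'))
        cat(sprintf('%.12f', calcNormFactors(m, method='TMM')), sep='\\n')
    """)
    res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    want = np.array([float(x) for x in res.stdout.split()])
    got = tmm_factors(counts).to_numpy()
    assert np.allclose(got, want, atol=1e-8)


# ---------------------------------------------------------------- BH

def test_bh_hand_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)


def test_bh_single_and_ties():
    assert bh_adjust([0.37])[0] == pytest.approx(0.37)
    assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)


def test_bh_nan_excluded():
    with pytest.warns(UserWarning):
        q = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(q[1])
    # m = 2, not 3
    assert q[0] == pytest.approx(0.02)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
       st.randoms(use_true_random=False))
def test_bh_permutation_invariant(pvals, rnd):
    perm = list(range(len(pvals)))
    rnd.shuffle(perm)
    q = bh_adjust(pvals)
    q_perm = bh_adjust([pvals[i] for i in perm])
    assert np.allclose([q[i] for i in perm], q_perm)
    assert np.all((q >= np.asarray(pvals) - 1e-12) & (q <= 1.0 + 1e-12))


# ---------------------------------------------------------------- top-5%

def _fake_result(n, seed=0):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=n)
    tab = pd.DataFrame({"log2fc": rng.normal(size=n), "pvalue": p,
                        "qvalue": bh_adjust(p), "converged": True},
                       index=pd.Index([f"G{i:06d}" for i in range(n)],
                                      name="gene"))
    return ContrastResult(label="RL", table=tab, n_tested=n)


def test_top_fraction_floor_and_determinism():
    res = _fake_result(20)
    assert len(select_top_fraction(res)) == 1
    res = _fake_result(1000)
    sel = select_top_fraction(res)
    assert len(sel) == 50
    assert sel == select_top_fraction(res)
    assert len(sel) == len(set(sel))


def test_top_fraction_small_n_warns_empty():
    res = _fake_result(10)
    with pytest.warns(UserWarning):
        assert select_top_fraction(res) == []


def test_top_fraction_orders_by_qvalue():
    res = _fake_result(200, seed=1)
    sel = set(select_top_fraction(res))
    q = res.table["qvalue"]
    worst_in = max(q[g] for g in sel)
    best_out = min(q[g] for g in set(res.table.index) - sel)
    assert worst_in <= best_out


# ---------------------------------------------------------------- contrasts

def test_contrast_spec_validation():
    with pytest.raises(ValueError):
        ContrastSpec("liver", "diet", "HC", "ZG")      # missing timepoint
    with pytest.raises(ValueError):
        ContrastSpec("liver", "rfi", "High", "High")
    with pytest.raises(ValueError):
        ContrastSpec("liver", "size", "a", "b")


def test_standard_contrasts_full_design():
    d = SimDesign(n_genes=20, seed=0)
    _, tbl, _ = simulate_counts(d, SimParams(de_log2fc=0, n_de_per_contrast=0,
                                             n_modules=0, wired_coupling=0))
    specs = standard_contrasts(tbl)
    labels = sorted(s.label for s in specs)
    assert labels == ["BL", "BM", "DL", "DM", "RL", "RM"]
    diet = next(s for s in specs if s.factor == "diet")
    assert "timepoint" in diet.covariates


def test_de_identical_groups_zero_logfc():
    # identical counts in both groups, equal library sizes: log2FC must be 0
    genes = 30
    block = np.tile(np.arange(1, genes + 1)[:, None] * 40, (1, 6))
    counts = pd.DataFrame(np.hstack([block, block]),
                          index=[f"G{i}" for i in range(genes)],
                          columns=[f"s{j}" for j in range(12)])
    design = pd.DataFrame({
        "sample": counts.columns, "tissue": "liver", "breed": "CH",
        "rfi": ["High"] * 6 + ["Low"] * 6, "diet": "H1", "timepoint": 1,
        "animal": counts.columns,
    })
    res = de_test(counts, design, ContrastSpec("liver", "rfi", "High", "Low"))
    assert np.allclose(res.table["log2fc"], 0.0, atol=1e-6)
    assert (res.table["pvalue"] > 0.99).all()


def test_de_recovers_planted_logfc():
    meds = []
    for seed in range(3):
        d = SimDesign(n_genes=400, breeds=("CH",), diet_phases=("H1",),
                      tissues=("liver",), n_per_cell=10, seed=seed)
        p = SimParams(de_log2fc=2.0, n_de_per_contrast=40, n_modules=0,
                      wired_coupling=0.0)
        counts, tbl, truth = simulate_counts(d, p)
        res = de_test(counts, tbl, ContrastSpec("liver", "rfi", "High", "Low"))
        est = [res.table.loc[g, "log2fc"] * np.sign(lfc)
               for g, lfc in truth.de_genes["RL"].items()
               if g in res.table.index]
        meds.append(np.median(est))
    assert all(1.7 <= m <= 2.3 for m in meds)


def test_de_q_dominates_p(small_dataset):
    counts, tbl, _ = small_dataset
    res = de_test(counts, tbl, ContrastSpec("liver", "breed", "CH", "HF"))
    tab = res.table
    assert (tab["qvalue"] >= tab["pvalue"] - 1e-12).all()
    assert tab["qvalue"].between(0, 1).all()
    assert res.n_tested == len(tab)


def test_de_requires_three_samples_per_level():
    d = SimDesign(n_genes=50, breeds=("CH",), diet_phases=("H1",),
                  tissues=("liver",), n_per_cell=2, seed=0)
    counts, tbl, _ = simulate_counts(d, SimParams(**{
        "de_log2fc": 0.0, "n_de_per_contrast": 0, "n_modules": 0,
        "wired_coupling": 0.0}))
    with pytest.raises(ValueError, match="fewer than 3"):
        de_test(counts, tbl, ContrastSpec("liver", "rfi", "High", "Low"))
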