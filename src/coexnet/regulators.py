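"""Node annotation and Regulatory Impact Factor (RIF) scoring.

Network nodes carry three flags — differentially expressed (per contrast),
transcription factor, secretome — read from plain-text catalogues.  Each
regulator is then scored for differential wiring between the two conditions
of a contrast:

  RIF1_i = (1/n_de) * sum_j PIF_j * (r1_ij - r2_ij)^2,
           PIF_j = a_j * d_j,  a_j = (e1_j + e2_j)/2,  d_j = e1_j - e2_j
  RIF2_i = (1/n_de) * sum_j [(e1_j * r1_ij)^2 - (e2_j * r2_ij)^2]

where e1/e2 are mean log2(CPM+1) of DE target j in each condition and
r1/r2 the regulator-target Pearson correlations computed within each
condition's samples.  Both metrics are z-standardised across regulators;
|z| >= 1.96 is the conventional significance cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import read_gene_list

__all__ = [
    "annotate_nodes",
    "condition_correlations",
    "rif_scores",
    "rif_for_contrast",
    "RIF_Z_CUTOFF",
]

RIF_Z_CUTOFF = 1.96


def annotate_nodes(
    genes,
    tf_list_file,
    secretome_file,
    deg_sets: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Flag table over the gene universe: is_tf, is_secretome, deg_<label>.

    Matching is case-normalised and exact; catalogue entries absent from
    the universe are reported with a warning.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene universe")
    universe = {g.upper(): g for g in genes}
    nodes = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for flag, path in (("is_tf", tf_list_file), ("is_secretome", secretome_file)):
        entries = read_gene_list(path)
        matched = {universe[e.upper()] for e in entries if e.upper() in universe}
        missing = [e for e in entries if e.upper() not in universe]
        if missing:
            warnings.warn(
                f"{len(missing)} {flag} list entr(ies) not in gene universe "
                f"(e.g. {missing[:3]})", stacklevel=2)
        nodes[flag] = nodes.index.isin(matched)
    if deg_sets:
        for label, members in sorted(deg_sets.items()):
            nodes[f"deg_{label}"] = nodes.index.isin(set(members))
    return nodes


def _pearson_rows(E_reg: np.ndarray, E_tgt: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations: (R, S) x (T, S) -> (R, T).

    Zero-variance rows correlate 0 with everything (with a warning from the
    caller's side via the returned mask)."""
    def _std(E):
        c = E - E.mean(axis=1, keepdims=True)
        s = np.sqrt((c ** 2).sum(axis=1))
        zero = s == 0
        s[zero] = 1.0
        return c / s[:, None], zero

    zr, reg_zero = _std(E_reg)
    zt, tgt_zero = _std(E_tgt)
    r = np.clip(zr @ zt.T, -1.0, 1.0)
    r[reg_zero, :] = 0.0
    r[:, tgt_zero] = 0.0
    return r


def condition_correlations(
    log_cpm: pd.DataFrame,
    condition_labels: pd.Series,
    regulators,
    de_targets,
    condition_pair: tuple[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regulator x target Pearson matrices within each condition's samples."""
    regulators, de_targets = list(regulators), list(de_targets)
    out = []
    for cond in condition_pair:
        samples = condition_labels.index[condition_labels == cond]
        samples = [s for s in samples if s in log_cpm.columns]
        if len(samples) < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 samples")
        E = log_cpm.loc[:, samples]
        E_reg = E.loc[regulators].to_numpy(dtype=float)
        E_tgt = E.loc[de_targets].to_numpy(dtype=float)
        if (E_reg.std(axis=1) == 0).any() or (E_tgt.std(axis=1) == 0).any():
            warnings.warn(
                f"constant expression in condition {cond!r}; correlations set "
                "to 0 for the affected gene(s)", stacklevel=2)
        r = _pearson_rows(E_reg, E_tgt)
        out.append(pd.DataFrame(r, index=regulators, columns=de_targets))
    return out[0], out[1]


@dataclass
class RIFTable:
    """Raw and z-standardised RIF1/RIF2 per regulator for one condition pair."""

    table: pd.DataFrame
    condition_pair: tuple[str, str]
    n_de: int

    def significant(self, cutoff: float = RIF_Z_CUTOFF) -> pd.DataFrame:
        z = self.table[["rif1_z", "rif2_z"]].abs()
        return self.table[(z >= cutoff).any(axis=1)]


def rif_scores(
    e1: pd.Series,
    e2: pd.Series,
    r1: pd.DataFrame,
    r2: pd.DataFrame,
    condition_pair: tuple[str, str] = ("cond1", "cond2"),
) -> RIFTable:
    """RIF1/RIF2 over DE targets, z-standardised across regulators."""
    if not (r1.shape == r2.shape and len(e1) == len(e2) == r1.shape[1]):
        raise ValueError("inconsistent RIF input dimensions")
    if r1.shape[1] < 1:
        raise ValueError("RIF requires at least one DE target")
    e1v = e1.reindex(r1.columns).to_numpy(dtype=float)
    e2v = e2.reindex(r1.columns).to_numpy(dtype=float)
    a = (e1v + e2v) / 2.0
    d = e1v - e2v
    pif = a * d
    dw = (r1.to_numpy() - r2.to_numpy()) ** 2
    rif1 = (pif[None, :] * dw).mean(axis=1)
    rif2 = ((e1v[None, :] * r1.to_numpy()) ** 2
            - (e2v[None, :] * r2.to_numpy()) ** 2).mean(axis=1)
    tab = pd.DataFrame({"rif1_raw": rif1, "rif2_raw": rif2},
                       index=pd.Index(r1.index, name="regulator"))
    if len(tab) < 2:
        warnings.warn("single regulator: z-scores undefined, raw values only",
                      stacklevel=2)
        tab["rif1_z"] = np.nan
        tab["rif2_z"] = np.nan
    else:
        for col in ("rif1", "rif2"):
            raw = tab[f"{col}_raw"]
            sd = raw.std(ddof=1)
            tab[f"{col}_z"] = (raw - raw.mean()) / sd if sd > 0 else 0.0
    z = tab[["rif1_z", "rif2_z"]].abs()
    tab["significant"] = (z >= RIF_Z_CUTOFF).any(axis=1).fillna(False)
    return RIFTable(table=tab, condition_pair=condition_pair, n_de=r1.shape[1])


def rif_for_contrast(
    log_cpm: pd.DataFrame,
    condition_labels: pd.Series,
    regulators,
    de_targets,
    condition_pair: tuple[str, str],
) -> RIFTable:
    """Convenience wrapper: correlations, condition means, then RIF."""
    regulators = [g for g in regulators if g in log_cpm.index]
    de_targets = [g for g in de_targets if g in log_cpm.index]
    r1, r2 = condition_correlations(
        log_cpm, condition_labels, regulators, de_targets, condition_pair)
    means = []
    for cond in condition_pair:
        samples = [s for s in condition_labels.index[condition_labels == cond]
                   if s in log_cpm.columns]
        means.append(log_cpm.loc[de_targets, samples].mean(axis=1))
    return rif_scores(means[0], means[1], r1, r2, condition_pair)
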