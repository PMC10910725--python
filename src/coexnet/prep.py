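"""Count filtering, normalisation and per-contrast differential expression.

The workflow mirrors standard bulk RNA-seq practice: CPM on TMM-normalised
effective library sizes, an "at least 1 CPM in at least half of the
samples" expression filter applied per contrast, a negative-binomial
log-linear model per gene with likelihood-ratio testing of the contrast
factor, Benjamini-Hochberg correction, and selection of the top 5% of
tested genes by corrected p-value as that contrast's DEG set.

Six contrasts are run: residual feed intake (High vs Low), breed and diet
(high-concentrate vs zero-grazed grass, with the numeric phase order as a
covariate), each within liver and within muscle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from . import _nbglm
from .simulate import contrast_label

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "compute_cpm",
    "tmm_factors",
    "filter_expressed",
    "bh_adjust",
    "de_test",
    "select_top_fraction",
    "standard_contrasts",
]

_VALID_FACTORS = ("rfi", "breed", "diet")
#: design-table diet phases pooled into the "HC" (high concentrate) level
HC_PHASES = ("H1", "H2")


@dataclass(frozen=True)
class ContrastSpec:
    """One differential-expression comparison within a tissue.

    ``level_a`` vs ``level_b`` on ``factor``; log2FC is reported as A over
    B.  The diet contrast must carry the time-point covariate so the two
    high-concentrate phases are not conflated with the passage of time.
    """

    tissue: str
    factor: str
    level_a: str
    level_b: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.factor not in _VALID_FACTORS:
            raise ValueError(f"factor must be one of {_VALID_FACTORS}")
        if self.level_a == self.level_b:
            raise ValueError("contrast levels must differ")
        if self.factor == "diet" and "timepoint" not in self.covariates:
            raise ValueError("the diet contrast requires the timepoint covariate")

    @property
    def label(self) -> str:
        return contrast_label(self.tissue, self.factor)


@dataclass
class ContrastResult:
    """Per-gene DE table for one labelled contrast.

    ``table`` has columns log2fc, pvalue, qvalue, converged, indexed by
    gene; ``n_tested`` is the number of genes passing the expression
    filter for this contrast.
    """

    label: str
    table: pd.DataFrame
    n_tested: int
    spec: ContrastSpec | None = None
    samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_tested != len(self.table):
            raise ValueError("n_tested must equal the number of table rows")


def compute_cpm(
    counts: pd.DataFrame, norm_factors: pd.Series | None = None
) -> pd.DataFrame:
    """Counts per million on effective library sizes (lib size x factor)."""
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    eff = lib if norm_factors is None else lib * norm_factors.reindex(lib.index)
    return counts / eff * 1e6


def filter_expressed(
    cpm: pd.DataFrame, threshold: float = 1.0, min_fraction: float = 0.5
) -> pd.Series:
    """Boolean mask: gene kept iff CPM >= threshold in >= ceil(f * n) samples."""
    if cpm.empty:
        raise ValueError("empty CPM matrix")
    need = math.ceil(min_fraction * cpm.shape[1])
    return (cpm >= threshold).sum(axis=1) >= need


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float = 0.3, sum_trim: float = 0.05,
) -> float:
    """Trimmed weighted mean of M-values for one sample against the reference."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logR = np.log2((obs / n_obs) / (ref / n_ref))
        absE = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / n_obs / obs + (n_ref - ref) / n_ref / ref
    fin = np.isfinite(logR) & np.isfinite(absE) & (absE > -1e10)
    logR, absE, v = logR[fin], absE[fin], v[fin]
    if logR.size == 0:
        warnings.warn("sample shares no expressed genes with the reference; "
                      "TMM factor set to 1", stacklevel=3)
        return 1.0
    if np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    lo_l, hi_l = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_s, hi_s = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rR, rE = rankdata(logR), rankdata(absE)
    keep = (rR >= lo_l) & (rR <= hi_l) & (rE >= lo_s) & (rE <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors.

    Doubly trimmed (30% of M-values, 5% of A-values) weighted mean of
    M-values against the sample whose upper-quartile CPM is closest to the
    mean upper quartile; factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    q75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array([
        _tmm_pair(mat[:, j], mat[:, ref], lib[j], lib[ref])
        for j in range(mat.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate as NaN
    and are excluded from the number of tests."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() < p.size:
        warnings.warn("NaN p-values excluded from BH correction", stacklevel=2)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def standard_contrasts(design: pd.DataFrame) -> list[ContrastSpec]:
    """The six study contrasts (RFI, breed, diet x each tissue present).

    RFI is High vs Low, breed is first-listed vs second, diet is HC (both
    high-concentrate phases pooled, timepoint covariate) vs ZG.
    """
    specs = []
    for tissue in pd.unique(design["tissue"]):
        sub = design[design["tissue"] == tissue]
        rfi = sorted(pd.unique(sub["rfi"]))
        if len(rfi) == 2:
            a = "High" if "High" in rfi else rfi[0]
            b = next(x for x in rfi if x != a)
            specs.append(ContrastSpec(tissue, "rfi", a, b))
        breeds = sorted(pd.unique(sub["breed"]))
        if len(breeds) == 2:
            specs.append(ContrastSpec(tissue, "breed", breeds[0], breeds[1]))
        diets = set(pd.unique(sub["diet"]))
        if "ZG" in diets and diets & set(HC_PHASES):
            specs.append(ContrastSpec(tissue, "diet", "HC", "ZG",
                                      covariates=("timepoint",)))
    return specs


def _contrast_values(design: pd.DataFrame, spec: ContrastSpec) -> pd.Series:
    """Per-sample contrast level, with diet phases mapped onto HC/ZG."""
    if spec.factor == "diet":
        return design["diet"].map(lambda d: "HC" if d in HC_PHASES else d)
    return design[spec.factor]


def de_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    spec: ContrastSpec,
    cpm_threshold: float = 1.0,
    min_fraction: float = 0.5,
    prior_df: float = 4.0,
) -> ContrastResult:
    """NB-GLM likelihood-ratio test of one contrast.

    Subsets to the contrast's tissue and levels, recomputes TMM factors and
    the expression filter on that subset, fits gene-wise NB log-linear
    models with grid-profiled dispersions shrunk toward the common value,
    and tests the contrast coefficient with a chi-square(1) LRT.  Genes
    whose IRLS fit fails to converge are flagged and assigned p = 1.
    """
    design = design.set_index("sample") if "sample" in design.columns else design
    sub = design[design["tissue"] == spec.tissue]
    level = _contrast_values(sub.reset_index(), spec)
    level.index = sub.index
    sub = sub[level.isin([spec.level_a, spec.level_b])]
    level = level.loc[sub.index]
    for lv in (spec.level_a, spec.level_b):
        if (level == lv).sum() < 3:
            raise ValueError(f"contrast level {lv!r} has fewer than 3 samples")
    cols = [c for c in sub.index if c in counts.columns]
    counts_sub = counts[cols]
    level = level.loc[cols]

    factors = tmm_factors(counts_sub)
    cpm = compute_cpm(counts_sub, factors)
    mask = filter_expressed(cpm, cpm_threshold, min_fraction)
    Y = counts_sub.loc[mask].to_numpy(dtype=float)
    genes = counts_sub.index[mask]
    lib = counts_sub.sum(axis=0).to_numpy(dtype=float)
    offset = np.log(lib * factors.to_numpy())

    x_contrast = (level == spec.level_a).to_numpy(dtype=float)
    cov_cols = []
    for cov in spec.covariates:
        vals = sub.loc[cols, cov]
        if pd.api.types.is_numeric_dtype(vals):
            cov_cols.append(vals.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(vals, drop_first=True)
            cov_cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies)
    X_null = np.column_stack([np.ones(len(cols))] + cov_cols) \
        if cov_cols else np.ones((len(cols), 1))
    X_full = np.column_stack([X_null, x_contrast])
    # covariates that make the contrast unidentifiable are dropped
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        keep = [0]
        for j in range(1, X_null.shape[1]):
            trial = np.column_stack([X_null[:, keep + [j]], x_contrast])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                keep.append(j)
            else:
                warnings.warn("covariate column collinear with the contrast; "
                              "dropped", stacklevel=2)
        X_null = X_null[:, keep]
        X_full = np.column_stack([X_null, x_contrast])

    phi, _ = _nbglm.estimate_dispersions(Y, X_full, offset, prior_df=prior_df)
    stat, beta, converged = _nbglm.lrt(Y, X_full, X_null, offset, phi)
    p = stats.chi2.sf(stat, df=1)
    log2fc = beta[:, -1] / np.log(2.0)
    n_bad = int((~converged).sum())
    if n_bad:
        warnings.warn(f"{n_bad} gene(s) failed to converge; p set to 1",
                      stacklevel=2)
        p = np.where(converged, p, 1.0)
        log2fc = np.where(converged, log2fc, 0.0)
    table = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": p, "qvalue": bh_adjust(p),
         "converged": converged},
        index=pd.Index(genes, name="gene"),
    )
    return ContrastResult(label=spec.label, table=table, n_tested=len(table),
                          spec=spec, samples=tuple(cols))


def select_top_fraction(
    result: ContrastResult, fraction: float = 0.05
) -> list[str]:
    """The floor(fraction x n_tested) genes with smallest corrected p.

    Ties broken by raw p, then |log2FC| descending, then gene ID, so the
    selection is deterministic.
    """
    if result.n_tested == 0:
        raise ValueError("empty contrast result")
    k = math.floor(fraction * result.n_tested)
    if k == 0:
        warnings.warn("top-fraction selection is empty at this n_tested",
                      stacklevel=2)
        return []
    tab = result.table.copy()
    tab["_absfc"] = -tab["log2fc"].abs()
    tab = tab.sort_values(["qvalue", "pvalue", "_absfc", "gene"],
                          kind="mergesort")
    return tab.index[:k].tolist()
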