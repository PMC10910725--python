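"""Synthetic RNA-seq counts over a factorial feed-efficiency study design.

Emulates the statistical structure of a 2-breed x 2-RFI-group x 3-diet-phase
x 2-tissue bulk RNA-seq experiment: negative-binomial counts with log-normal
library sizes, planted per-contrast differential expression, latent-factor
co-expression modules, and one "differentially wired" regulator whose
coupling to its target genes flips sign between two conditions.  All ground
truth is recorded so every downstream stage (DE, RIF, PCIT, MCODE) can be
scored against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimDesign",
    "SimParams",
    "SimTruth",
    "simulate_counts",
    "write_fixture_lists",
    "contrast_label",
]

#: factor name -> one-letter code used in contrast labels (RL, DM, ...)
_FACTOR_CODE = {"rfi": "R", "diet": "D", "breed": "B"}


def contrast_label(tissue: str, factor: str) -> str:
    """Two-letter contrast label, e.g. ('liver', 'rfi') -> 'RL'."""
    if factor not in _FACTOR_CODE:
        raise ValueError(f"unknown contrast factor {factor!r}")
    return _FACTOR_CODE[factor] + tissue[0].upper()


@dataclass(frozen=True)
class SimDesign:
    """Factorial layout of the simulated study.

    Defaults reproduce the study design this generator emulates: Charolais
    and Holstein-Friesian steers, divergent High/Low residual feed intake
    within breed, sampled across a high-concentrate growing phase (H1), a
    zero-grazed grass phase (ZG) and a high-concentrate finishing phase (H2),
    in liver and longissimus muscle, with ~10 animals per breed x RFI cell.
    """

    n_genes: int = 2000
    breeds: tuple[str, ...] = ("CH", "HF")
    rfi_groups: tuple[str, ...] = ("High", "Low")
    diet_phases: tuple[str, ...] = ("H1", "ZG", "H2")
    tissues: tuple[str, ...] = ("liver", "muscle")
    n_per_cell: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        for name in ("breeds", "rfi_groups", "diet_phases", "tissues"):
            labels = getattr(self, name)
            if len(labels) == 0:
                raise ValueError(f"{name} must contain at least one label")
            if len(set(labels)) != len(labels):
                raise ValueError(f"{name} labels must be unique")

    @property
    def samples_per_tissue(self) -> int:
        return (
            len(self.breeds)
            * len(self.rfi_groups)
            * len(self.diet_phases)
            * self.n_per_cell
        )


@dataclass(frozen=True)
class SimParams:
    """Effect sizes and nuisance parameters of the generator.

    Baseline relative abundance is log-normal; gene-wise NB dispersion is
    gamma with Var = mu + phi * mu^2; library sizes are log-normal in the
    10^6-10^7 range.  Module co-expression is injected on the log2-mean
    scale through shared latent N(0,1) factors; the wired regulator carries
    its own latent signal that couples to its targets with coefficient +c in
    condition 1 and -c in condition 2 of the wired contrast.
    """

    abundance_sdlog: float = 1.5
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.1
    libsize_meanlog: float = float(np.log(3.0e6))
    libsize_sdlog: float = 0.3
    n_de_per_contrast: int = 80
    de_log2fc: float = 2.0
    n_modules: int = 5
    module_size: int = 20
    module_loading: float = 1.0
    module_noise_sd: float = 0.3
    n_tfs: int = 100
    n_secretome: int = 80
    n_wired_targets: int = 20
    wired_coupling: float = 0.8
    wired_factor: str = "rfi"

    def __post_init__(self) -> None:
        if self.dispersion_shape <= 0 or self.dispersion_mean <= 0:
            raise ValueError("NB dispersion parameters must be positive")
        if self.abundance_sdlog < 0 or self.libsize_sdlog < 0:
            raise ValueError("log-normal SDs must be non-negative")
        if np.exp(self.libsize_meanlog) <= 0:
            raise ValueError("library size mean must be positive")
        for name in (
            "n_de_per_contrast", "n_modules", "module_size",
            "n_tfs", "n_secretome", "n_wired_targets",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.module_noise_sd < 0:
            raise ValueError("module_noise_sd must be non-negative")
        if self.wired_factor not in _FACTOR_CODE:
            raise ValueError(f"unknown wired_factor {self.wired_factor!r}")


@dataclass
class SimTruth:
    """Everything that was planted, keyed the way downstream stages see it.

    de_genes maps a contrast label (RL, DM, ...) to {gene: signed log2FC of
    level A over level B}.  module_assignments maps a gene to its latent
    module index.  wired_regulator is the TF whose target coupling flips
    sign between wired_conditions (None when no wiring was planted).
    """

    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    module_assignments: dict[str, int] = field(default_factory=dict)
    regulator_ids: list[str] = field(default_factory=list)
    secretome_ids: list[str] = field(default_factory=list)
    wired_regulator: str | None = None
    wired_targets: list[str] = field(default_factory=list)
    wired_contrast: str | None = None
    wired_conditions: tuple[str, str] | None = None
    wired_coupling: float = 0.0

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        if payload["wired_conditions"] is not None:
            payload["wired_conditions"] = list(payload["wired_conditions"])
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        if payload.get("wired_conditions") is not None:
            payload["wired_conditions"] = tuple(payload["wired_conditions"])
        return cls(**payload)


def _build_design_table(design: SimDesign) -> pd.DataFrame:
    rows = []
    for tissue in design.tissues:
        for breed in design.breeds:
            for rfi in design.rfi_groups:
                for rep in range(design.n_per_cell):
                    animal = f"{breed}_{rfi}_{rep:02d}"
                    for t, diet in enumerate(design.diet_phases, start=1):
                        sample = f"{tissue[:3]}_{breed}_{rfi}_{diet}_{rep:02d}"
                        rows.append(
                            (sample, tissue, breed, rfi, diet, t, animal)
                        )
    return pd.DataFrame(
        rows,
        columns=["sample", "tissue", "breed", "rfi", "diet", "timepoint", "animal"],
    ).set_index("sample")


def _factor_sign(design_tbl: pd.DataFrame, design: SimDesign, factor: str) -> np.ndarray:
    """+1 for samples at the factor's first (A) level, -1 at the rest.

    For diet the A level is "high concentrate" = every non-ZG phase when a
    ZG phase exists, otherwise the first phase.
    """
    if factor == "rfi":
        a = design.rfi_groups[0]
        return np.where(design_tbl["rfi"] == a, 1.0, -1.0)
    if factor == "breed":
        a = design.breeds[0]
        return np.where(design_tbl["breed"] == a, 1.0, -1.0)
    if factor == "diet":
        if "ZG" in design.diet_phases:
            return np.where(design_tbl["diet"] == "ZG", -1.0, 1.0)
        a = design.diet_phases[0]
        return np.where(design_tbl["diet"] == a, 1.0, -1.0)
    raise ValueError(f"unknown factor {factor!r}")


def _wired_condition_levels(design: SimDesign, factor: str) -> tuple[str, str]:
    if factor == "rfi":
        return design.rfi_groups[0], design.rfi_groups[-1]
    if factor == "breed":
        return design.breeds[0], design.breeds[-1]
    return "HC", "ZG"


def simulate_counts(
    design: SimDesign, params: SimParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw one synthetic dataset.

    Returns (counts, design_table, truth): integer counts genes x samples,
    the per-sample factor table, and the planted ground truth.  Identical
    (design, params) — the seed lives on the design — give identical output.
    """
    params = params or SimParams()
    rng = np.random.default_rng(design.seed)
    genes = np.array([f"G{i:05d}" for i in range(design.n_genes)])
    design_tbl = _build_design_table(design)
    n_samples = len(design_tbl)

    # gene-level baselines
    rel = rng.lognormal(0.0, params.abundance_sdlog, design.n_genes)
    rel /= rel.sum()
    phi = rng.gamma(
        params.dispersion_shape,
        params.dispersion_mean / params.dispersion_shape,
        design.n_genes,
    )
    phi = np.maximum(phi, 1e-6)
    libsize = rng.lognormal(params.libsize_meanlog, params.libsize_sdlog, n_samples)

    truth = SimTruth()
    log2_delta = np.zeros((design.n_genes, n_samples))

    # planted per-contrast differential expression (half up, half down)
    factors = ["rfi", "breed"] if len(design.diet_phases) < 2 else ["rfi", "breed", "diet"]
    factors = [f for f in factors
               if len({"rfi": design.rfi_groups, "breed": design.breeds,
                       "diet": design.diet_phases}[f]) >= 2]
    for tissue in design.tissues:
        in_tissue = (design_tbl["tissue"] == tissue).to_numpy()
        for factor in factors:
            label = contrast_label(tissue, factor)
            n_de = params.n_de_per_contrast if params.de_log2fc != 0 else 0
            idx = rng.choice(design.n_genes, size=min(n_de, design.n_genes),
                             replace=False)
            signs = np.where(np.arange(len(idx)) % 2 == 0, 1.0, -1.0)
            truth.de_genes[label] = {
                genes[g]: float(s * params.de_log2fc)
                for g, s in zip(idx, signs)
            }
            if len(idx) == 0:
                continue
            x = _factor_sign(design_tbl, design, factor) * in_tissue
            # log2FC of A over B = de_log2fc: split the shift symmetrically
            log2_delta[idx, :] += np.outer(signs * params.de_log2fc / 2.0, x)

    # latent co-expression modules
    n_module_genes = params.n_modules * params.module_size
    if params.n_modules > 0 and n_module_genes <= design.n_genes and params.module_loading != 0:
        midx = rng.choice(design.n_genes, size=n_module_genes, replace=False)
        f = rng.normal(0.0, 1.0, (params.n_modules, n_samples))
        eps = rng.normal(0.0, params.module_noise_sd, (n_module_genes, n_samples))
        for m in range(params.n_modules):
            members = midx[m * params.module_size:(m + 1) * params.module_size]
            rows = slice(m * params.module_size, (m + 1) * params.module_size)
            log2_delta[members, :] += params.module_loading * f[m] + eps[rows]
            for g in members:
                truth.module_assignments[genes[g]] = m
    module_set = set(truth.module_assignments)

    # TF and secretome catalogues (may overlap modules and each other,
    # like the real lists)
    n_tfs = min(params.n_tfs, design.n_genes)
    tf_idx = rng.choice(design.n_genes, size=n_tfs, replace=False) if n_tfs else np.array([], int)
    truth.regulator_ids = sorted(genes[tf_idx])
    n_sec = min(params.n_secretome, design.n_genes)
    sec_idx = rng.choice(design.n_genes, size=n_sec, replace=False) if n_sec else np.array([], int)
    truth.secretome_ids = sorted(genes[sec_idx])

    # differentially wired regulator: own latent signal, sign-flipped
    # coupling to DE-gene targets of the wired contrast
    wire_on = (
        params.wired_coupling != 0
        and params.n_wired_targets > 0
        and len(tf_idx) > 0
    )
    if wire_on:
        tissue = design.tissues[0]
        label = contrast_label(tissue, params.wired_factor)
        # the wired regulator carries its own latent signal, so it must not
        # also load on a module factor
        non_module_tfs = [int(g) for g in tf_idx if genes[g] not in module_set]
        if not non_module_tfs:
            raise ValueError("no module-free TF available as wired regulator")
        reg = non_module_tfs[0]
        # targets are up-regulated DE genes of the wired contrast: RIF weights
        # targets by abundance x differential expression, and a coherently
        # coupled regulator has consistently-signed DE targets
        de_pool = [g for g in range(design.n_genes)
                   if truth.de_genes.get(label, {}).get(genes[g], 0) > 0
                   and g != reg and genes[g] not in module_set]
        pool = de_pool if len(de_pool) >= params.n_wired_targets else \
            [g for g in range(design.n_genes) if g != reg]
        targets = rng.choice(pool, size=min(params.n_wired_targets, len(pool)),
                             replace=False)
        u = rng.normal(0.0, 1.0, n_samples)
        in_tissue = (design_tbl["tissue"] == tissue).to_numpy()
        sign = _factor_sign(design_tbl, design, params.wired_factor)
        log2_delta[reg, :] += u * in_tissue
        log2_delta[targets, :] += np.outer(
            np.full(len(targets), params.wired_coupling), sign * u * in_tissue
        )
        truth.wired_regulator = genes[reg]
        truth.wired_targets = sorted(genes[targets])
        truth.wired_contrast = label
        truth.wired_conditions = _wired_condition_levels(design, params.wired_factor)
        truth.wired_coupling = params.wired_coupling

    mu = rel[:, None] * np.exp2(log2_delta) * libsize[None, :]
    mu = np.maximum(mu, 1e-12)
    r = 1.0 / phi
    counts = rng.negative_binomial(r[:, None], r[:, None] / (r[:, None] + mu))

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=design_tbl.index)
    return counts_df, design_tbl.reset_index(), truth


def write_fixture_lists(
    truth: SimTruth, tf_path: str | Path, secretome_path: str | Path
) -> None:
    """Write one-gene-per-line TF and secretome list files (sorted, unique)."""
    tf_path, secretome_path = Path(tf_path), Path(secretome_path)
    if tf_path.resolve() == secretome_path.resolve():
        raise ValueError("TF and secretome list paths collide")
    for path, ids in ((tf_path, truth.regulator_ids),
                      (secretome_path, truth.secretome_ids)):
        uniq = sorted(set(ids))
        path.write_text("".join(g + "\n" for g in uniq))
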