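"""Run configuration: validation and defaults for end-to-end pipelines."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import SimDesign, SimParams

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""


_THRESHOLD_DEFAULTS = {
    "cpm": 1.0,
    "min_fraction": 0.5,
    "fraction": 0.05,
    "abs_r": 0.8,
    "sd_mult": 2.0,
    "vwp": 0.2,
    "degree_cutoff": 2,
    "prior_df": 4.0,
}
_INPUT_KEYS = {"counts", "design", "tf_list", "secretome_list", "gene_sets"}
_TOP_KEYS = {"inputs", "simulate", "thresholds", "seed", "outdir"}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either ``simulate`` (a SimDesign plus SimParams) or ``inputs`` (paths
    to counts/design/list files) drives the run; thresholds carry the
    study's defaults (top 5% of tested genes, |r| >= 0.8, mean + 2 SD,
    MCODE vwp 0.2).  One master seed derives every per-stage seed.
    """

    outdir: str
    seed: int = 0
    simulate: tuple[SimDesign, SimParams] | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(_THRESHOLD_DEFAULTS))

    def stage_seed(self, stage: str) -> int:
        # stable stage-specific stream below 2**31
        h = 0
        for ch in stage:
            h = (h * 131 + ord(ch)) % 1_000_003
        return (self.seed * 1_000_003 + h) % (2 ** 31)

    def echo(self) -> dict:
        payload: dict = {
            "outdir": self.outdir,
            "seed": self.seed,
            "thresholds": dict(self.thresholds),
        }
        if self.simulate is not None:
            design, params = self.simulate
            payload["simulate"] = {"design": asdict(design),
                                   "params": asdict(params)}
        if self.inputs:
            payload["inputs"] = dict(self.inputs)
        return payload


def _check_thresholds(raw: dict, errors: list[str]) -> dict:
    thr = dict(_THRESHOLD_DEFAULTS)
    for key, value in raw.items():
        if key not in _THRESHOLD_DEFAULTS:
            errors.append(f"thresholds: unknown key {key!r}")
            continue
        thr[key] = value
    if not (0.0 < thr["fraction"] <= 0.5):
        errors.append("thresholds.fraction must lie in (0, 0.5]")
    if not (0.0 <= thr["abs_r"] <= 1.0):
        errors.append("thresholds.abs_r must lie in [0, 1]")
    if not (0.0 <= thr["vwp"] < 1.0):
        errors.append("thresholds.vwp must lie in [0, 1)")
    if thr["cpm"] < 0:
        errors.append("thresholds.cpm must be non-negative")
    if not (0.0 < thr["min_fraction"] <= 1.0):
        errors.append("thresholds.min_fraction must lie in (0, 1]")
    if thr["sd_mult"] < 0:
        errors.append("thresholds.sd_mult must be non-negative")
    if thr["degree_cutoff"] < 0:
        errors.append("thresholds.degree_cutoff must be non-negative")
    return thr


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw config mapping; raises ConfigError listing every
    problem found."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown top-level key {key!r}")
    outdir = raw.get("outdir")
    if not outdir:
        errors.append("outdir is required")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        errors.append("seed must be an integer")
        seed = 0
    thresholds = _check_thresholds(raw.get("thresholds") or {}, errors)

    simulate = None
    inputs: dict[str, str] = {}
    if "simulate" in raw and "inputs" in raw:
        errors.append("give either a simulate block or inputs, not both")
    elif "simulate" in raw:
        block = raw["simulate"] or {}
        unknown = set(block) - {"design", "params"}
        if unknown:
            errors.append(f"simulate: unknown keys {sorted(unknown)}")
        try:
            design = SimDesign(**{**(block.get("design") or {}), "seed": seed})
            params = SimParams(**(block.get("params") or {}))
            simulate = (design, params)
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate block invalid: {exc}")
    elif "inputs" in raw:
        inputs = dict(raw["inputs"] or {})
        unknown = set(inputs) - _INPUT_KEYS
        if unknown:
            errors.append(f"inputs: unknown keys {sorted(unknown)}")
        for req in ("counts", "design", "tf_list", "secretome_list"):
            if req not in inputs:
                errors.append(f"inputs.{req} is required")
    else:
        errors.append("either a simulate block or inputs is required")
    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(outdir=str(outdir), seed=seed, simulate=simulate,
                     inputs=inputs, thresholds=thresholds)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON config file and validate it."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return validate_config(raw)
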