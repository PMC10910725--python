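"""Readers/writers for the plain-text formats the pipeline exchanges.

Counts: TSV, first column gene ID, header = sample IDs.  Design: TSV with
columns sample, tissue, breed, rfi, diet, timepoint, animal.  Gene lists:
one symbol per line.  Gene sets: GMT (name, description, members...).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

DESIGN_COLUMNS = ["sample", "tissue", "breed", "rfi", "diet", "timepoint", "animal"]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene"
    return counts


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    return design


def read_gene_list(path: str | Path) -> list[str]:
    """One gene per line; blank lines ignored; order-preserving, de-duplicated."""
    seen: dict[str, None] = {}
    for line in Path(path).read_text().splitlines():
        g = line.strip()
        if g:
            seen.setdefault(g, None)
    return list(seen)


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: tab-separated name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + sorted(members))
        for name, members in sorted(sets.items())
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))
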