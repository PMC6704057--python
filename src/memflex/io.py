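"""File formats: GMT gene-set libraries, TSV tables, tidy CSV export.

Numeric CSV output is fixed at 12 significant digits so that repeated runs
under the same seed are byte-identical across platforms.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .enrichment import GeneSetLibrary

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression_tsv",
    "read_homolog_tsv",
    "write_table",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.12g"


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Parse a GMT library: one set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        genes = {g for g in fields[2:] if g}
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets[name] = genes
    return GeneSetLibrary(sets)


def write_gmt(library: GeneSetLibrary, path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([tf, description, *sorted(targets)])
        for tf, targets in sorted(library.sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene-expression table with columns gene, fpkm_1, fpkm_2, q_value."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene", "fpkm_1", "fpkm_2", "q_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def read_homolog_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV source_symbol<TAB>target_symbol; one-to-many allowed."""
    mapping: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        src, dst = parts
        mapping.setdefault(src, set()).add(dst)
    if not mapping:
        raise ValueError(f"{path}: homolog table is empty")
    return mapping


def write_table(frame: pd.DataFrame, path: str | Path, fmt: str = "csv") -> Path:
    """Write a DataFrame as CSV/TSV/JSON at 12 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    elif fmt == "tsv":
        frame.to_csv(path, index=False, sep="\t", float_format=FLOAT_FORMAT)
    elif fmt == "json":
        frame.to_json(path, orient="records", indent=2, double_precision=12)
    else:
        raise ValueError(f"unknown table format {fmt!r}")
    return path
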