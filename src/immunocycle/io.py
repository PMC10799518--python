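"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression TSV (genes as rows, header = sample ids), GMT gene-set files,
MAF-like mutation TSV, per-sample neoantigen TSV and clinical TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .immunogram import GeneSetCollection

__all__ = [
    "read_expression",
    "read_gmt",
    "write_gmt",
    "read_maf",
    "read_neoantigens",
    "read_clinical",
]

MAF_COLUMNS = ["sample_id", "gene", "impact", "ref_tri", "alt", "vaf"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample expression TSV; first column = gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("expression matrix has duplicate gene or sample ids")
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return df


def read_gmt(path: str | Path, axis_map: dict[str, str] | None = None) -> GeneSetCollection:
    """GMT: one set per line, tab-separated name, description, genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets=sets, axis_map=axis_map or {})


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "-"] + list(members)) + "\n")


def read_maf(path: str | Path) -> pd.DataFrame:
    """MAF-like mutation TSV with the catalog's required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table lacks columns: {missing}")
    bad = df[(df["vaf"] <= 0) | (df["vaf"] > 1)]
    if len(bad):
        raise ValueError(f"{len(bad)} mutation records have VAF outside (0, 1]")
    return df


def read_neoantigens(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(float)
    if (s < 0).any():
        raise ValueError("neoantigen counts must be >= 0")
    return s


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("os_time", "os_event"):
        if col not in df.columns:
            raise ValueError(f"clinical table lacks column {col!r}")
    if (df["os_time"] <= 0).any():
        raise ValueError("os_time values must be positive")
    if not df["os_event"].isin([0, 1]).all():
        raise ValueError("os_event must be coded 0/1")
    return df
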