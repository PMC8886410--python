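"""Readers and writers for the pipeline's tab-separated formats.

Counts are HTSeq-style gene x sample TSV; protein quantities come as a
MaxQuant proteinGroups-like table ("Protein IDs", "Mol. weight [kDa]", one
"iBAQ <sample>" column per sample); the sample sheet maps samples to
condition, replicate, and measured growth rate; gene sets are GMT.  All
readers validate strictly and name the offending row/column in errors.
Expression matrices are written with a JSON sidecar naming their unit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_design

__all__ = [
    "read_counts",
    "read_sample_sheet",
    "read_protein_groups",
    "read_gmt",
    "write_gmt",
    "write_expression_matrix",
    "read_expression_matrix",
]


def read_counts(path) -> pd.DataFrame:
    """Gene x sample raw counts from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene ids {dup[:5]}")
    bad_cols = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad_cols:
        raise ValueError(f"{path}: non-numeric count columns {bad_cols}")
    x = df.to_numpy()
    if (x < 0).any() or not np.array_equal(x, np.floor(x)):
        i, j = np.argwhere((x < 0) | (x != np.floor(x)))[0]
        raise ValueError(
            f"{path}: counts must be non-negative integers "
            f"(gene {df.index[i]!r}, sample {df.columns[j]!r})"
        )
    return df.astype(np.int64)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV with sample_id, condition, replicate, growth_rate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return validate_design(df)


def read_protein_groups(path, sample_ids=None) -> tuple[pd.DataFrame, pd.Series]:
    """proteinGroups-like TSV -> (iBAQ matrix proteins x samples, masses).

    Blank/zero iBAQ entries become NaN (not detected).  If ``sample_ids`` is
    given, every listed sample must have an iBAQ column.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("Protein IDs", "Mol. weight [kDa]"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["Protein IDs"].duplicated().any():
        dup = df.loc[df["Protein IDs"].duplicated(), "Protein IDs"].tolist()
        raise ValueError(f"{path}: duplicated protein ids {dup[:5]}")
    df = df.set_index("Protein IDs")
    ibaq_cols = [c for c in df.columns if c.startswith("iBAQ ")]
    if not ibaq_cols:
        raise ValueError(f"{path}: no 'iBAQ <sample>' columns found")
    ibaq = df[ibaq_cols].copy()
    ibaq.columns = [c[len("iBAQ ") :] for c in ibaq_cols]
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in ibaq.columns]
        if missing:
            raise ValueError(f"{path}: missing iBAQ columns for samples {missing}")
    ibaq = ibaq.apply(pd.to_numeric, errors="raise")
    ibaq = ibaq.where(ibaq > 0)  # zero or blank intensity = not detected
    masses = pd.to_numeric(df["Mol. weight [kDa]"], errors="raise")
    if (masses <= 0).any():
        bad = masses.index[masses <= 0].tolist()
        raise ValueError(f"{path}: non-positive molecular weights for {bad[:5]}")
    return ibaq, masses.rename("mass_kda")


def read_gmt(path) -> dict[str, set]:
    """GMT gene sets: name <tab> description <tab> members..."""
    sets: dict[str, set] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT lines need name, description, members")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{ln}: duplicated set name {name!r}")
        sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict, path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(map(str, members))])
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """TSV plus a '<path>.meta.json' sidecar recording the unit."""
    path = Path(path)
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")
    meta = {"unit": matrix.unit, "n_genes": int(matrix.data.shape[0]), "n_samples": int(matrix.data.shape[1])}
    path.with_name(path.name + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_expression_matrix(path) -> ExpressionMatrix:
    path = Path(path)
    meta = json.loads(path.with_name(path.name + ".meta.json").read_text())
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, unit=meta["unit"])
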