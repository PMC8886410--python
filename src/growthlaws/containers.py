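"""Unit-tagged expression matrices and design-sheet validation.

An :class:`ExpressionMatrix` is a plain genes x samples DataFrame plus a unit
tag.  The tag is carried through the pipeline so downstream stages can assert
they received the scale they expect (fractions for sector fits on proteins,
normalized counts for transcripts, z-scores for clustering, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recognised unit tags
UNITS = (
    "raw_count",
    "normalized_count",
    "mass_fraction",
    "number_fraction",
    "zscore",
    "residual_log2_ratio",
)

DESIGN_COLUMNS = ("sample_id", "condition", "replicate", "growth_rate")


@dataclass
class ExpressionMatrix:
    """Genes x samples values with a stated unit.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with one column per sample id.
    unit:
        One of :data:`UNITS`.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicated gene ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][:5].tolist()
            raise ValueError(f"duplicated sample ids: {dup}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def check(self, atol: float = 1e-9) -> None:
        """Validate the unit invariants (fractions sum to 1, z-score rows
        standardised, raw counts non-negative integers)."""
        x = self.values()
        if self.unit == "raw_count":
            finite = x[np.isfinite(x)]
            if (finite < 0).any() or not np.allclose(finite, np.round(finite)):
                raise ValueError("raw counts must be non-negative integers")
        elif self.unit in ("mass_fraction", "number_fraction"):
            sums = np.nansum(x, axis=0)
            if not np.allclose(sums, 1.0, atol=atol):
                raise ValueError("fraction columns must sum to 1")
        elif self.unit == "zscore":
            if not np.allclose(np.nanmean(x, axis=1), 0.0, atol=atol):
                raise ValueError("z-score rows must have mean 0")
            if not np.allclose(np.nanstd(x, axis=1, ddof=1), 1.0, atol=atol):
                raise ValueError("z-score rows must have sd 1")


def as_frame(matrix) -> pd.DataFrame:
    """Accept an ExpressionMatrix or a bare DataFrame and return the frame."""
    if isinstance(matrix, ExpressionMatrix):
        return matrix.data
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"expected ExpressionMatrix or DataFrame, got {type(matrix)!r}")


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet: required columns, unique ids and
    (condition, replicate) pairs, strictly positive growth rates."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample ids: {dup}")
    pairs = design[["condition", "replicate"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        raise ValueError("duplicated (condition, replicate) pairs in sample sheet")
    if (design["growth_rate"] <= 0).any():
        bad = design.loc[design["growth_rate"] <= 0, "sample_id"].tolist()
        raise ValueError(f"non-positive growth rates for samples: {bad}")
    return design


def mu_for_columns(design: pd.DataFrame, sample_ids) -> np.ndarray:
    """Growth rate vector aligned to a matrix's sample columns."""
    lut = design.set_index("sample_id")["growth_rate"]
    missing = [s for s in sample_ids if s not in lut.index]
    if missing:
        raise KeyError(f"samples absent from the sample sheet: {missing}")
    return lut.loc[list(sample_ids)].to_numpy(dtype=float)
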