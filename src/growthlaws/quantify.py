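"""Normalization and unit conversions.

Covers the per-sample quantities the downstream fits operate on: DESeq2-style
median-of-ratios size factors and normalized counts for RNA-seq, iBAQ-based
proteome mass fractions, protein and transcript number fractions, detection
filtering, per-gene z-scores, and growth-rate estimation from optical-density
regrowth curves.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, as_frame

__all__ = [
    "estimate_growth_rate",
    "size_factors",
    "normalize_counts",
    "mass_fractions",
    "number_fractions_protein",
    "number_fractions_rna",
    "filter_detected",
    "zscore",
]


def estimate_growth_rate(od_series: pd.DataFrame) -> float:
    """Exponential growth rate (1/h) from an OD time series.

    Least-squares slope of ln(OD) against time; the series must have
    ``time`` (h) and ``od`` columns, at least 3 points, and positive OD.
    """
    t = np.asarray(od_series["time"], dtype=float)
    od = np.asarray(od_series["od"], dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 OD points to fit a growth rate")
    if np.any(od <= 0):
        raise ValueError("OD values must be positive")
    slope, _ = np.polyfit(t, np.log(od), 1)
    return float(slope)


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the median over reference genes of count / geometric
    mean across samples; only genes with nonzero counts in every sample enter
    the reference set (the standard convention).
    """
    df = as_frame(counts)
    x = df.to_numpy(dtype=float)
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "size factors undefined: no gene has nonzero counts in all samples"
        )
    ref = x[all_nonzero]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(ref) - log_geo, axis=0))
    return pd.Series(sf, index=df.columns, name="size_factor")


def normalize_counts(counts, factors: pd.Series) -> ExpressionMatrix:
    """Normalized counts ``n = c / S`` per sample."""
    df = as_frame(counts)
    s = factors.reindex(df.columns)
    if s.isna().any():
        raise KeyError(f"missing size factors for samples: {s.index[s.isna()].tolist()}")
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    return ExpressionMatrix(df / s, unit="normalized_count")


def mass_fractions(ibaq, masses: pd.Series) -> ExpressionMatrix:
    """Proteome mass fractions ``phi = m_i B_i / sum_l m_l B_l`` per sample.

    Missing intensities contribute zero to the denominator and propagate as
    missing fractions.
    """
    df = as_frame(ibaq)
    m = masses.reindex(df.index)
    if m.isna().any():
        raise KeyError(f"missing masses for proteins: {m.index[m.isna()].tolist()}")
    if (m <= 0).any():
        raise ValueError("molecular masses must be positive")
    weighted = df.mul(m, axis=0)
    totals = weighted.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero total protein mass in samples: {bad}")
    return ExpressionMatrix(weighted / totals, unit="mass_fraction")


def number_fractions_protein(ibaq) -> ExpressionMatrix:
    """Proteome number fractions ``psi_P = B_i / sum_l B_l`` per sample."""
    df = as_frame(ibaq)
    totals = df.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        raise ValueError(
            f"zero total intensity in samples: {totals.index[totals <= 0].tolist()}"
        )
    return ExpressionMatrix(df / totals, unit="number_fraction")


def number_fractions_rna(normalized_counts, lengths: pd.Series) -> ExpressionMatrix:
    """Transcriptome number fractions ``psi_M = (n_i/l_i) / sum_l (n_l/l_l)``.

    Normalized counts are divided by transcript length (molecule counts are
    proportional to reads per nucleotide) before per-sample renormalization.
    """
    df = as_frame(normalized_counts)
    l = lengths.reindex(df.index)
    if l.isna().any():
        raise KeyError(f"missing lengths for genes: {l.index[l.isna()].tolist()}")
    if (l <= 0).any():
        raise ValueError("transcript lengths must be positive")
    per_nt = df.div(l, axis=0)
    totals = per_nt.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        raise ValueError("zero total molecule count in at least one sample")
    return ExpressionMatrix(per_nt / totals, unit="number_fraction")


def filter_detected(matrix, mode: str = "all_samples", design: pd.DataFrame | None = None):
    """Drop genes failing a detection criterion; returns (matrix, removed ids).

    Modes: ``all_samples`` keeps genes detected (finite, nonzero) everywhere;
    ``all_replicates_within_any_condition`` keeps genes detected in every
    replicate of at least one condition (requires ``design``);
    ``at_least_one`` keeps genes detected anywhere.
    """
    df = as_frame(matrix)
    detected = df.notna() & (df != 0)
    if mode == "all_samples":
        keep = detected.all(axis=1)
    elif mode == "at_least_one":
        keep = detected.any(axis=1)
    elif mode == "all_replicates_within_any_condition":
        if design is None:
            raise ValueError("per-condition filtering needs the sample sheet")
        cond = design.set_index("sample_id")["condition"].reindex(df.columns)
        keep = pd.Series(False, index=df.index)
        for _, cols in df.columns.to_series().groupby(cond.values):
            keep |= detected[cols].all(axis=1)
    else:
        raise ValueError(f"unknown detection filter mode {mode!r}")
    removed = df.index[~keep]
    out = df.loc[keep]
    if isinstance(matrix, ExpressionMatrix):
        out = ExpressionMatrix(out, unit=matrix.unit)
    return out, list(removed)


def zscore(matrix, on_constant: str = "error") -> ExpressionMatrix:
    """Per-gene z-scores ``(y - mean) / sd`` with the n-1 sd convention.

    Constant rows have no z-score; ``on_constant`` selects ``error`` (default)
    or ``drop`` (with a warning).
    """
    df = as_frame(matrix)
    if df.isna().any().any():
        raise ValueError("z-scoring requires a complete matrix (no missing values)")
    sd = df.std(axis=1, ddof=1)
    constant = sd <= 0
    if constant.any():
        if on_constant == "drop":
            warnings.warn(
                f"dropping {int(constant.sum())} constant rows before z-scoring",
                stacklevel=2,
            )
            df = df.loc[~constant]
            sd = sd.loc[~constant]
        else:
            raise ValueError(
                f"constant rows have undefined z-scores: {df.index[constant][:5].tolist()}"
            )
    z = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, unit="zscore")
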