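"""Cross-omics comparison of protein and mRNA number fractions.

Measurement noise attenuates observed correlations between two noisy
quantities below the latent correlation.  The Spearman attenuation
correction divides the observed cross-correlation by the geometric mean of
the two platforms' replicate reliabilities: r for each omics layer and
condition is the geometric mean of the pairwise Pearson correlations between
log2 number fractions of the three biological replicates, the raw
protein-mRNA estimate is the geometric mean over the unordered replicate
pairs, and the corrected estimate is R = rho_hat / sqrt(r_P r_M).

Also provides the residual log2 protein-to-mRNA ratio: the per-gene median
log-ratio (which tracks post-transcriptional amplification with expression
level) is removed so between-sample ratio differences are comparable across
genes of very different abundance.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .containers import as_frame

__all__ = [
    "replicate_reliability",
    "raw_cross_correlation",
    "corrected_correlation",
    "reliability_report",
    "residual_ratio",
]


def _condition_columns(design: pd.DataFrame, sample_ids) -> dict[str, list[str]]:
    """Map condition -> sample columns, ordered by replicate number."""
    sub = design[design["sample_id"].isin(sample_ids)]
    out: dict[str, list[str]] = {}
    for cond, grp in sub.groupby("condition", sort=True):
        out[cond] = grp.sort_values("replicate")["sample_id"].tolist()
    return out


def _pairwise_pearson_log2(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def _geomean(values: list[float], context: str) -> float:
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError(
            f"{context}: non-positive pairwise correlation(s) {arr.tolist()}; "
            "geometric mean undefined"
        )
    return float(np.exp(np.mean(np.log(arr))))


def replicate_reliability(number_fractions, design: pd.DataFrame) -> pd.DataFrame:
    """Per-condition reliability: geometric mean of the three pairwise
    Pearson correlations of log2 number fractions between replicates.

    Only genes detected (finite, positive) in all replicates of a condition
    enter that condition's correlations; the universe size is reported.
    """
    df = as_frame(number_fractions)
    rows = []
    for cond, cols in _condition_columns(design, df.columns).items():
        if len(cols) < 2:
            raise ValueError(f"condition {cond} has fewer than 2 replicates")
        block = df[cols]
        ok = (block.notna() & (block > 0)).all(axis=1)
        logged = np.log2(block.loc[ok].to_numpy(dtype=float))
        pair_r = {}
        for i, j in combinations_with_replacement(range(len(cols)), 2):
            if i == j:
                continue
            pair_r[f"rho_{i + 1}:{j + 1}"] = _pairwise_pearson_log2(
                logged[:, i], logged[:, j]
            )
        r = _geomean(list(pair_r.values()), f"reliability in condition {cond}")
        rows.append({"condition": cond, "reliability": r, "n_genes": int(ok.sum()), **pair_r})
    return pd.DataFrame(rows).set_index("condition")


def raw_cross_correlation(psi_p, psi_m, design: pd.DataFrame) -> pd.DataFrame:
    """Uncorrected protein-mRNA correlation per condition.

    Geometric mean over the unordered replicate pairs (k1 <= k2, including
    the diagonal: six terms for triplicates) of the Pearson correlations
    between log2 protein and log2 mRNA number fractions, on genes detected
    in all six samples of the condition.  All pairwise correlations are also
    returned.
    """
    dfp = as_frame(psi_p)
    dfm = as_frame(psi_m)
    shared = dfp.index.intersection(dfm.index)
    rows = []
    cond_p = _condition_columns(design, dfp.columns)
    cond_m = _condition_columns(design, dfm.columns)
    for cond in sorted(set(cond_p) & set(cond_m)):
        cols_p, cols_m = cond_p[cond], cond_m[cond]
        bp = dfp.loc[shared, cols_p]
        bm = dfm.loc[shared, cols_m]
        ok = (bp.notna() & (bp > 0)).all(axis=1) & (bm.notna() & (bm > 0)).all(axis=1)
        lp = np.log2(bp.loc[ok].to_numpy(dtype=float))
        lm = np.log2(bm.loc[ok].to_numpy(dtype=float))
        pair_r = {}
        used = []
        for k1 in range(len(cols_p)):
            for k2 in range(len(cols_m)):
                rho = _pairwise_pearson_log2(lp[:, k1], lm[:, k2])
                pair_r[f"rho_{k1 + 1}:{k2 + 1}"] = rho
                if k1 <= k2:
                    used.append(rho)
        rho_hat = _geomean(used, f"cross-correlation in condition {cond}")
        rows.append(
            {"condition": cond, "rho_hat": rho_hat, "n_genes": int(ok.sum()), **pair_r}
        )
    return pd.DataFrame(rows).set_index("condition")


def corrected_correlation(rho_hat, r_p, r_m):
    """Attenuation-corrected correlation R = rho_hat / sqrt(r_P r_M).

    Reliabilities must lie in (0, 1].  Values of |R| above 1 are possible
    when the correction overshoots; they are returned as-is (callers flag
    them), since clamping would bias averages over conditions.
    """
    rho_hat = np.asarray(rho_hat, dtype=float)
    r_p = np.asarray(r_p, dtype=float)
    r_m = np.asarray(r_m, dtype=float)
    if np.any((r_p <= 0) | (r_p > 1)) or np.any((r_m <= 0) | (r_m > 1)):
        raise ValueError("reliabilities must be in (0, 1]")
    out = rho_hat / np.sqrt(r_p * r_m)
    return float(out) if out.ndim == 0 else out


def reliability_report(psi_p, psi_m, design: pd.DataFrame) -> pd.DataFrame:
    """Per-condition reliabilities, raw and corrected protein-mRNA
    correlation, with a flag when |R| exceeds 1."""
    rel_p = replicate_reliability(psi_p, design)
    rel_m = replicate_reliability(psi_m, design)
    raw = raw_cross_correlation(psi_p, psi_m, design)
    conds = raw.index
    r = corrected_correlation(
        raw["rho_hat"].to_numpy(),
        rel_p.loc[conds, "reliability"].to_numpy(),
        rel_m.loc[conds, "reliability"].to_numpy(),
    )
    return pd.DataFrame(
        {
            "r_protein": rel_p.loc[conds, "reliability"],
            "r_mrna": rel_m.loc[conds, "reliability"],
            "rho_hat": raw["rho_hat"],
            "corrected_R": r,
            "exceeds_one": np.abs(r) > 1.0,
            "n_genes": raw["n_genes"],
        },
        index=conds,
    )


def residual_ratio(psi_p, psi_m) -> pd.DataFrame:
    """Residual log2 protein-to-mRNA ratio matrix.

    log2(psi_P / psi_M) minus the per-gene median over samples; only
    gene-sample pairs with both fractions positive contribute, and genes
    with fewer than 2 such samples are dropped (listed in the attrs of the
    result under ``dropped``).
    """
    dfp = as_frame(psi_p)
    dfm = as_frame(psi_m)
    shared_genes = dfp.index.intersection(dfm.index)
    shared_samples = dfp.columns.intersection(dfm.columns)
    p = dfp.loc[shared_genes, shared_samples].to_numpy(dtype=float)
    m = dfm.loc[shared_genes, shared_samples].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((p > 0) & (m > 0), np.log2(p / m), np.nan)
    n_valid = np.isfinite(ratio).sum(axis=1)
    keep = n_valid >= 2
    ratio = ratio[keep]
    med = np.nanmedian(ratio, axis=1, keepdims=True)
    out = pd.DataFrame(
        ratio - med, index=shared_genes[keep], columns=shared_samples
    )
    out.attrs["dropped"] = list(shared_genes[~keep])
    return out
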