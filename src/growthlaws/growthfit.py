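"""Robust growth-law fitting and sector assignment.

A growth law is a linear relation between a gene's relative expression and
the culture growth rate mu.  Because genes are frequently induced or
repressed in specific conditions on top of the growth trend, ordinary least
squares is easily distorted; fits here use the repeated-median linear model
(RMLM, the Siegel repeated-median estimator, breakdown ~50%): for each data
point the median pairwise slope and intercept to all other points is taken,
and the fit is the median of those per-point medians.

The dimensionless fold change FC = mu_max / (0.5 mu_max + b/a) compares the
steepness of growth laws across genes of different absolute abundance: 2
means pure proportionality to mu, 0 a flat line, negative values decreasing
expression.  Sectors: R (positive slope) and P (negative slope) when the
tail-based fdr of the fit is below 0.1, Q otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import as_frame, mu_for_columns
from .fdr import fdr_from_pvalues

__all__ = [
    "rmlm_fit",
    "rmlm_fit_matrix",
    "fold_change",
    "fit_statistics",
    "fdr_assign",
    "fit_all_genes",
    "setsum_profile",
    "bootstrap_growth_law",
    "GrowthLawBand",
    "ratio_trend",
]

MU_MAX_DEFAULT = 0.3
_TIE_TOL = 1e-12


def rmlm_fit_matrix(mu: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Repeated-median slope/intercept for many series at once.

    Parameters
    ----------
    mu:
        Growth rates, shape (N,) shared by all rows, or (G, N) per row.
    y:
        Observations, shape (G, N); NaN marks missing points.

    Returns
    -------
    (slope, intercept) arrays of shape (G,); rows with fewer than 3 finite
    points or fewer than 2 distinct mu come back NaN.

    Pairs closer than 1e-12 in mu are excluded from a point's pairwise
    medians (their slope is undefined); medians use the midpoint convention
    for even counts.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.asarray(mu, dtype=float)
    if mu.ndim == 1:
        mu_rows = np.broadcast_to(mu, y.shape)
    else:
        mu_rows = mu
    if mu_rows.shape != y.shape:
        raise ValueError("mu and y shapes do not match")

    m = np.where(np.isfinite(y), mu_rows, np.nan)
    dmu = m[:, None, :] - m[:, :, None]  # [g, i, j] = mu_j - mu_i
    with np.errstate(invalid="ignore", divide="ignore"):
        dy = y[:, None, :] - y[:, :, None]
        slope_pairs = dy / dmu
        icpt_pairs = (m[:, None, :] * y[:, :, None] - m[:, :, None] * y[:, None, :]) / dmu
    bad = ~np.isfinite(dmu) | (np.abs(dmu) < _TIE_TOL)
    slope_pairs[bad] = np.nan
    icpt_pairs[bad] = np.nan

    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)  # all-NaN slices are expected
        slope = np.nanmedian(np.nanmedian(slope_pairs, axis=2), axis=1)
        icpt = np.nanmedian(np.nanmedian(icpt_pairs, axis=2), axis=1)

    n_finite = np.isfinite(y).sum(axis=1)
    n_distinct = np.array(
        [np.unique(row[np.isfinite(row)]).size for row in m]
    )
    invalid = (n_finite < 3) | (n_distinct < 2)
    slope[invalid] = np.nan
    icpt[invalid] = np.nan
    return slope, icpt


def rmlm_fit(mu_vec, y_vec) -> tuple[float, float]:
    """Repeated-median fit for one series; raises on degenerate input."""
    mu_vec = np.asarray(mu_vec, dtype=float)
    y_vec = np.asarray(y_vec, dtype=float)
    ok = np.isfinite(mu_vec) & np.isfinite(y_vec)
    mu_vec, y_vec = mu_vec[ok], y_vec[ok]
    if mu_vec.size < 3:
        raise ValueError("repeated-median fit needs at least 3 finite points")
    if np.unique(mu_vec).size < 2:
        raise ValueError("all growth rates identical: slope undefined")
    slope, icpt = rmlm_fit_matrix(mu_vec, y_vec[None, :])
    return float(slope[0]), float(icpt[0])


def fold_change(slope, intercept, mu_max: float = MU_MAX_DEFAULT):
    """Growth-law fold change FC = mu_max / (0.5 mu_max + b/a).

    Equals (y(mu_max) - y(0)) / y(mu_max/2) on the fitted line.  A flat line
    (a = 0) maps to 0; a zero midpoint value (b = -0.5 mu_max a) is undefined
    and comes back NaN.
    """
    a = np.asarray(slope, dtype=float)
    b = np.asarray(intercept, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mid = 0.5 * mu_max + b / a
        fc = np.where(a == 0.0, 0.0, mu_max / mid)
    fc = np.where((a != 0.0) & (mid == 0.0), np.nan, fc)
    if np.isscalar(slope) and np.isscalar(intercept):
        return float(fc)
    return fc


def fit_statistics(mu, y, slope, intercept):
    """(R^2, normalized SSR, p) for RMLM fits.

    R^2 = 1 - SSR / SStot may be negative for a robust fit.  The normalized
    SSR is SSR / ((N-1) * mean(y)).  The p-value is the F(1, N-2) upper tail
    at F = max(R^2, 0)/(1 - max(R^2, 0)) * (N-2) -- the closest well-defined
    analogue of a least-squares regression F test for a robust fit; R^2 <= 0
    maps to p = 1.  Vectorized over rows when y is 2-D.
    """
    y_arr = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.asarray(mu, dtype=float)
    mu_rows = np.broadcast_to(mu, y_arr.shape) if mu.ndim == 1 else mu
    a = np.atleast_1d(np.asarray(slope, dtype=float))
    b = np.atleast_1d(np.asarray(intercept, dtype=float))

    resid = y_arr - (a[:, None] * mu_rows + b[:, None])
    n = np.isfinite(y_arr).sum(axis=1).astype(float)
    ssr = np.nansum(resid**2, axis=1)
    ybar = np.nanmean(y_arr, axis=1)
    sstot = np.nansum((y_arr - ybar[:, None]) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        r2 = 1.0 - ssr / sstot
        ssr_norm = np.where(ybar != 0.0, ssr / ((n - 1.0) * ybar), np.nan)
        r2c = np.clip(r2, 0.0, None)
        fstat = r2c / np.maximum(1.0 - r2c, np.finfo(float).tiny) * (n - 2.0)
        p = stats.f.sf(fstat, 1, n - 2.0)
    p = np.where(np.isfinite(r2) & (r2 > 0.0), p, 1.0)
    p = np.where(n >= 3, p, np.nan)
    if np.isscalar(slope):
        return float(r2[0]), float(ssr_norm[0]), float(p[0])
    return r2, ssr_norm, p


def fdr_assign(
    p_vec,
    slope_vec,
    q_threshold: float = 0.1,
    lfdr_threshold: float = 0.1,
    eta0: float | None = None,
) -> pd.DataFrame:
    """Sector assignment from fit p-values and slope signs.

    Computes tail-based fdr (q) and local fdr from the p-value distribution;
    genes with q below the threshold join R (positive slope) or P (negative
    slope), all others are Q.  The confident flag marks local fdr below its
    threshold.  NaN p-values (degenerate fits) are assigned Q with q = lfdr
    = NaN.
    """
    p = np.asarray(p_vec, dtype=float)
    a = np.asarray(slope_vec, dtype=float)
    ok = np.isfinite(p)
    q = np.full(p.shape, np.nan)
    lfdr = np.full(p.shape, np.nan)
    if ok.any():
        res = fdr_from_pvalues(p[ok], eta0=eta0)
        q[ok] = res.q
        lfdr[ok] = res.lfdr
    sector = np.full(p.shape, "Q", dtype=object)
    sig = ok & (q < q_threshold)
    sector[sig & (a > 0)] = "R"
    sector[sig & (a < 0)] = "P"
    confident = ok & (lfdr < lfdr_threshold)
    return pd.DataFrame(
        {"q": q, "lfdr": lfdr, "sector": sector, "confident": confident}
    )


def fit_all_genes(
    matrix,
    design: pd.DataFrame,
    mu_max: float = MU_MAX_DEFAULT,
    q_threshold: float = 0.1,
    lfdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-gene growth-law fit table (one GrowthFitRecord row per gene).

    Genes detected in only a subset of samples are fitted on the available
    points; N records how many entered each fit.  Missing = NaN; zeros are
    kept as observations.
    """
    df = as_frame(matrix)
    mu = mu_for_columns(design, df.columns)
    y = df.to_numpy(dtype=float)
    slope, icpt = rmlm_fit_matrix(mu, y)
    r2, ssr_norm, p = fit_statistics(mu, y, slope, icpt)
    fc = fold_change(slope, icpt, mu_max=mu_max)
    assign = fdr_assign(
        p, slope, q_threshold=q_threshold, lfdr_threshold=lfdr_threshold
    )
    out = pd.DataFrame(
        {
            "gene_id": df.index,
            "n_points": np.isfinite(y).sum(axis=1),
            "slope": slope,
            "intercept": icpt,
            "fc": fc,
            "r2": r2,
            "ssr_norm": ssr_norm,
            "p": p,
            "q": assign["q"].to_numpy(),
            "lfdr": assign["lfdr"].to_numpy(),
            "sector": assign["sector"].to_numpy(),
            "confident": assign["confident"].to_numpy(),
        }
    ).set_index("gene_id")
    return out


def setsum_profile(matrix, gene_set) -> tuple[pd.Series, dict]:
    """Per-sample sums over a gene set; returns (profile, membership report)."""
    df = as_frame(matrix)
    members = [g for g in gene_set if g in df.index]
    missing = [g for g in gene_set if g not in df.index]
    if not members:
        raise ValueError("gene set has no members in the matrix")
    profile = df.loc[members].sum(axis=0, skipna=True)
    report = {"n_in_matrix": len(members), "n_missing": len(missing), "missing": missing}
    return profile, report


@dataclass
class GrowthLawBand:
    """Bootstrap growth-law band on a mu grid."""

    grid: np.ndarray
    predicted: np.ndarray  # full-data RMLM prediction
    lower: np.ndarray  # 2.5th percentile of bootstrap predictions
    upper: np.ndarray  # 97.5th percentile
    fc_mean: float
    fc_sd: float
    slope: float
    intercept: float
    n_redraws: int  # resamples rejected for < 2 distinct mu


def bootstrap_growth_law(
    mu_vec,
    y_vec,
    n_boot: int = 1000,
    grid: np.ndarray | None = None,
    mu_max: float = MU_MAX_DEFAULT,
    seed: int = 0,
) -> GrowthLawBand:
    """Case-resampling bootstrap of the RMLM growth law.

    Pairs (mu, y) are resampled with replacement n_boot times; each resample
    is refitted and evaluated on the grid (default 101 points on
    [0, mu_max]).  Bands are the 2.5/97.5 percentiles of the predictions; FC
    is reported as mean +/- sd over bootstrap fits.  Resamples with fewer
    than 2 distinct mu are redrawn (counted).
    """
    mu_vec = np.asarray(mu_vec, dtype=float)
    y_vec = np.asarray(y_vec, dtype=float)
    ok = np.isfinite(mu_vec) & np.isfinite(y_vec)
    mu_vec, y_vec = mu_vec[ok], y_vec[ok]
    n = mu_vec.size
    if n < 4:
        raise ValueError("bootstrap needs at least 4 points")
    if grid is None:
        grid = np.linspace(0.0, mu_max, 101)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    n_redraws = 0
    while True:
        distinct = np.array([np.unique(mu_vec[row]).size for row in idx])
        bad = distinct < 2
        if not bad.any():
            break
        n_redraws += int(bad.sum())
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    slopes, icpts = rmlm_fit_matrix(mu_vec[idx], y_vec[idx])
    preds = slopes[:, None] * grid[None, :] + icpts[:, None]
    lower, upper = np.percentile(preds, [2.5, 97.5], axis=0)
    fcs = fold_change(slopes, icpts, mu_max=mu_max)
    a, b = rmlm_fit(mu_vec, y_vec)
    return GrowthLawBand(
        grid=grid,
        predicted=a * grid + b,
        lower=lower,
        upper=upper,
        fc_mean=float(np.nanmean(fcs)),
        fc_sd=float(np.nanstd(fcs)),
        slope=a,
        intercept=b,
        n_redraws=n_redraws,
    )


def ratio_trend(fit_a: tuple[float, float], fit_b: tuple[float, float], grid) -> pd.DataFrame:
    """Pointwise ratio of two fitted growth laws on a mu grid.

    Returns the grid, numerator/denominator predictions, their ratio, and a
    flag marking grid points where the denominator is zero or changes sign
    (the ratio diverges there).
    """
    grid = np.asarray(grid, dtype=float)
    num = fit_a[0] * grid + fit_a[1]
    den = fit_b[0] * grid + fit_b[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    flagged = (den == 0.0) | (np.sign(den) != np.sign(den[np.argmax(np.abs(den))]))
    return pd.DataFrame(
        {"mu": grid, "numerator": num, "denominator": den, "ratio": ratio, "flagged": flagged}
    )
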