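"""Tail-based and local false discovery rates from p-values.

This emulates the fdrtool-style two-component model for p-values: a null
proportion ``eta0`` is estimated by censoring large p-values, the tail-based
fdr (q-value) is ``eta0 * p / ECDF(p)`` with a monotonicity correction, and
the local fdr is ``eta0`` divided by a Grenander (decreasing, least concave
majorant) estimate of the p-value density.  With ``eta0`` forced to 1 the
tail-based fdr reduces exactly to Benjamini-Hochberg adjusted p-values.

The emulation is approximate by design: it reproduces the structure of the
procedure (censored eta0, Grenander density) rather than any particular
package's numerics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["FdrResult", "estimate_eta0", "tail_fdr", "grenander_lfdr", "fdr_from_pvalues"]

#: below this many p-values the two-component fit is unstable; fall back to BH
MIN_N_FOR_FIT = 50


@dataclass
class FdrResult:
    q: np.ndarray  # tail-based fdr per input p-value
    lfdr: np.ndarray  # local fdr per input p-value
    eta0: float  # estimated null proportion
    method: str  # "fndr" or "bh-fallback"


def estimate_eta0(p: np.ndarray, lambda_: float = 0.5) -> float:
    """Censored estimate of the null proportion.

    P-values above the censoring point ``lambda_`` are treated as pure null;
    under uniformity a fraction ``1 - lambda_`` of nulls lands there, so
    ``eta0 = #{p > lambda} / ((1 - lambda) n)``, clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    eta0 = np.sum(p > lambda_) / ((1.0 - lambda_) * n)
    return float(np.clip(eta0, 1.0 / n, 1.0))


def tail_fdr(p: np.ndarray, eta0: float = 1.0) -> np.ndarray:
    """Tail-based fdr ``q(p) = eta0 * p / ECDF(p)``, monotone in p, capped at 1.

    ECDF uses the maximal rank among ties; the monotone correction takes the
    running minimum from the largest p-value downward (the BH step-up shape).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    sorted_p = p[order]
    # maximal rank for ties
    idx = np.arange(1, n + 1, dtype=float)
    ties_last = np.searchsorted(sorted_p, sorted_p, side="right")
    ranks[order] = idx[ties_last - 1]
    q = eta0 * p * n / ranks
    q_sorted = q[order]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    out = np.empty(n, dtype=float)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


def _grenander_slopes(p_sorted: np.ndarray) -> np.ndarray:
    """Slopes of the least concave majorant of the p-value ECDF.

    Returns one (non-increasing) density value per sorted p-value.  The ECDF
    is anchored at (0, 0) and (1, 1) so the density integrates to one.
    """
    n = p_sorted.size
    xs = np.concatenate(([0.0], p_sorted, [1.0]))
    ys = np.concatenate(([0.0], np.arange(1, n + 1) / n, [1.0]))
    # collapse duplicate x (ties): keep the largest y at each x
    keep_x: list[float] = [xs[0]]
    keep_y: list[float] = [ys[0]]
    for x, y in zip(xs[1:], ys[1:]):
        if x == keep_x[-1]:
            keep_y[-1] = max(keep_y[-1], y)
        else:
            keep_x.append(x)
            keep_y.append(y)
    hx: list[float] = []
    hy: list[float] = []
    # upper (concave) hull via monotone stack
    for x, y in zip(keep_x, keep_y):
        hx.append(x)
        hy.append(y)
        while len(hx) >= 3:
            s1 = (hy[-2] - hy[-3]) / (hx[-2] - hx[-3])
            s2 = (hy[-1] - hy[-2]) / (hx[-1] - hx[-2])
            if s2 >= s1:  # middle point below the chord: not concave, drop it
                del hx[-2], hy[-2]
            else:
                break
    hx_arr = np.asarray(hx)
    hy_arr = np.asarray(hy)
    seg_slopes = np.diff(hy_arr) / np.diff(hx_arr)
    # locate each p in its hull segment
    seg = np.clip(np.searchsorted(hx_arr, p_sorted, side="right") - 1, 0, seg_slopes.size - 1)
    return seg_slopes[seg]


def grenander_lfdr(p: np.ndarray, eta0: float = 1.0) -> np.ndarray:
    """Local fdr ``min(1, eta0 / f_hat(p))`` with a Grenander density."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p, kind="mergesort")
    dens = _grenander_slopes(p[order])
    lfdr_sorted = np.clip(eta0 / np.maximum(dens, np.finfo(float).tiny), 0.0, 1.0)
    out = np.empty(p.size, dtype=float)
    out[order] = lfdr_sorted
    return out


def fdr_from_pvalues(
    p: np.ndarray,
    eta0: float | None = None,
    lambda_: float = 0.5,
    min_n: int = MIN_N_FOR_FIT,
) -> FdrResult:
    """Estimate (q, lfdr, eta0) from a vector of p-values.

    With fewer than ``min_n`` p-values the two-component model degenerates;
    the function then warns and returns BH-adjusted p-values (eta0 = 1) for
    both q and lfdr.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    if p.size < min_n and eta0 is None:
        warnings.warn(
            f"only {p.size} p-values (< {min_n}); falling back to "
            "Benjamini-Hochberg with eta0 = 1",
            stacklevel=2,
        )
        q = tail_fdr(p, eta0=1.0)
        return FdrResult(q=q, lfdr=q.copy(), eta0=1.0, method="bh-fallback")
    if eta0 is None:
        eta0 = estimate_eta0(p, lambda_=lambda_)
    q = tail_fdr(p, eta0=eta0)
    lfdr = grenander_lfdr(p, eta0=eta0)
    return FdrResult(q=q, lfdr=lfdr, eta0=float(eta0), method="fndr")
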