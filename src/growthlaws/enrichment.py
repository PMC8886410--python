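"""Functional enrichment: Fisher overlap tests and preranked GSEA.

Overlap enrichment of a query gene list against gene-set collections uses
one-sided hypergeometric tail probabilities with local-fdr significance
control (the same tail/local fdr machinery as sector assignment).

Preranked gene-set enrichment ranks genes by the signed significance of
their growth-law fit, -sign(a) log10(p), putting the R sector at the top
and the P sector at the bottom, and scores each set with the classical
weighted Kolmogorov-Smirnov running-sum enrichment statistic against a
gene-label permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fdr import fdr_from_pvalues, tail_fdr

__all__ = [
    "GeneSetCollection",
    "fisher_overlap",
    "enrich_fisher",
    "local_fdr",
    "rank_statistic",
    "enrichment_score",
    "preranked_gsea",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe; empty sets are rejected."""

    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty universe")
        restricted = {}
        for name, members in self.sets.items():
            kept = set(members) & self.universe
            if not kept:
                raise ValueError(f"gene set {name!r} has no members in the universe")
            restricted[name] = kept
        self.sets = restricted


def fisher_overlap(query_genes, gene_set, universe) -> tuple[int, float]:
    """One-sided (enrichment) Fisher test of the overlap of two gene lists.

    Returns (overlap size, hypergeometric upper-tail p-value
    P[X >= overlap] drawing |query| genes from a universe containing
    |set| successes).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    members = set(gene_set) & universe
    overlap = len(query & members)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
    return overlap, min(p, 1.0)


def enrich_fisher(query_genes, collection: GeneSetCollection) -> pd.DataFrame:
    """Fisher overlap test of one query list against every set, with tail
    and local fdr over the resulting p-values."""
    rows = []
    for name, members in sorted(collection.sets.items()):
        overlap, p = fisher_overlap(query_genes, members, collection.universe)
        rows.append(
            {"set": name, "set_size": len(members), "overlap": overlap, "p": p}
        )
    out = pd.DataFrame(rows).set_index("set")
    res = local_fdr(out["p"].to_numpy())
    out["q"] = res.q
    out["lfdr"] = res.lfdr
    return out


def local_fdr(p_vec, eta0: float | None = None):
    """Tail and local fdr for enrichment p-values (shared fdr machinery)."""
    return fdr_from_pvalues(np.asarray(p_vec, dtype=float), eta0=eta0)


def rank_statistic(fit_table: pd.DataFrame) -> pd.Series:
    """Signed significance ranking value -sign(slope) * log10(p).

    Positive-slope genes with small p get large positive values (R sector at
    the top of the ranking).  p = 0 maps to +/-(largest finite magnitude +
    1), preserving the ordering; zero slopes map to 0.
    """
    a = fit_table["slope"].to_numpy(dtype=float)
    p = fit_table["p"].to_numpy(dtype=float)
    sign = np.sign(a)
    with np.errstate(divide="ignore"):
        val = -sign * np.log10(p)
    finite = np.isfinite(val)
    cap = (np.max(np.abs(val[finite])) if finite.any() else 0.0) + 1.0
    val = np.where(p == 0.0, sign * cap, val)
    val = np.where(sign == 0.0, 0.0, val)
    return pd.Series(val, index=fit_table.index, name="rank_stat")


def enrichment_score(
    values: np.ndarray, is_member: np.ndarray, weight: float = 1.0
) -> tuple[float, int]:
    """Weighted KS enrichment score for one set on a ranked list.

    ``values`` must already be sorted in decreasing order; hits advance the
    running sum by |value|^weight (normalized), misses retreat by
    1/(N - set size).  Returns (signed extremum of the running sum, index of
    the extremum).
    """
    hits = np.abs(values) ** weight * is_member
    hit_total = hits.sum()
    if hit_total <= 0:
        hits = is_member.astype(float)  # all-zero weights: unweighted fallback
        hit_total = hits.sum()
    n_miss = is_member.size - int(is_member.sum())
    if n_miss == 0:
        return 0.0, 0
    running = np.cumsum(hits / hit_total - (~is_member.astype(bool)) / n_miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def preranked_gsea(
    ranked_values: pd.Series,
    gene_sets: dict,
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 3,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Classical preranked GSEA with a gene-label permutation null.

    For each set the enrichment score (ES) is compared against scores from
    ``n_perm`` random sets of the same size; NES divides the ES by the mean
    magnitude of same-sign null scores, the permutation p-value is BH
    adjusted across sets, and the leading edge lists the members up to the
    running-sum extremum.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse", stacklevel=2)
    vals = ranked_values.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("ranking values must be finite")
    order = np.argsort(-vals, kind="mergesort")
    vals_sorted = vals[order]
    genes_sorted = ranked_values.index.to_numpy()[order]
    pos = {g: i for i, g in enumerate(genes_sorted)}
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sorted(gene_sets.items()):
        idx = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        if not (min_size <= idx.size <= max_size):
            continue
        member_mask = np.zeros(vals_sorted.size, dtype=bool)
        member_mask[idx] = True
        es, cut = enrichment_score(vals_sorted, member_mask, weight=weight)
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_mask = np.zeros(vals_sorted.size, dtype=bool)
            perm_mask[rng.choice(vals_sorted.size, size=idx.size, replace=False)] = True
            null_es[b], _ = enrichment_score(vals_sorted, perm_mask, weight=weight)
        same_sign = null_es * np.sign(es) > 0
        n_same = int(same_sign.sum())
        if n_same:
            p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
            nes = es / np.mean(np.abs(null_es[same_sign]))
        else:
            p = 1.0 / (1 + n_perm)
            nes = 0.0 if es == 0 else np.sign(es) * np.inf
        if es >= 0:
            leading = [g for g in genes_sorted[: cut + 1] if g in members]
        else:
            leading = [g for g in genes_sorted[cut:] if g in members]
        rows.append(
            {
                "set": name,
                "size": idx.size,
                "es": es,
                "nes": nes,
                "p": p,
                "leading_edge": ",".join(map(str, leading)),
            }
        )
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p", "leading_edge"]
    )
    if len(out):
        out["p_adj"] = tail_fdr(out["p"].to_numpy(), eta0=1.0)
    return out
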