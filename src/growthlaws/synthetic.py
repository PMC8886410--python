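"""Synthetic benchmark generator.

Emulates the study design the analysis assumes: K nutrient conditions grown
in continuous culture at condition-specific growth rates (three biological
replicates each), per-gene relative abundances that depend linearly on the
growth rate plus optional condition-specific log2 offsets, negative-binomial
RNA-seq counts, and lognormal iBAQ protein intensities with missingness.

The growth dependence is planted on relative abundances (the scale the
growth-law fits operate on); the count and intensity layers only add
measurement structure on top.  Slopes and intercepts are parameterized by the
growth-law fold change FC = mu_max / (0.5 mu_max + b/a): a gene with target
FC and mid-growth level m gets slope a = m FC / mu_max and intercept
b = m (1 - FC/2), so the planted FC is exactly recovered by the fit on
noiseless data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .containers import validate_design

__all__ = [
    "generate_design",
    "generate_gene_parameters",
    "latent_levels",
    "simulate_rna_counts",
    "simulate_protein_ibaq",
    "simulate_od_curve",
    "to_protein_groups_table",
]

MU_MAX_DEFAULT = 0.3  # h^-1, upper end of the growth-law grid


def generate_design(
    n_conditions: int = 8,
    n_replicates: int = 3,
    mu_low: float = 0.05,
    mu_high: float = 0.28,
    replicate_jitter: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample sheet for a K-condition, n-replicate continuous-culture design.

    Condition-level mean growth rates are spread evenly over
    [mu_low, mu_high]; each replicate's measured rate is the condition mean
    times exp(N(0, jitter)).
    """
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    if not (0 < mu_low < mu_high):
        raise ValueError("growth rates must satisfy 0 < mu_low < mu_high")
    if replicate_jitter < 0:
        raise ValueError("replicate jitter must be non-negative")
    rng = child_rng(seed, "design")
    means = np.linspace(mu_low, mu_high, n_conditions)
    rows = []
    for j in range(n_conditions):
        cond = f"C{j + 1:02d}"
        for k in range(1, n_replicates + 1):
            mu = means[j] * np.exp(rng.normal(0.0, replicate_jitter))
            rows.append(
                {
                    "sample_id": f"{cond}_r{k}",
                    "condition": cond,
                    "replicate": k,
                    "growth_rate": mu,
                }
            )
    return validate_design(pd.DataFrame(rows))


def generate_gene_parameters(
    n_genes: int,
    sector_props: tuple[float, float, float] = (0.30, 0.25, 0.45),
    fc_range: tuple[float, float] = (0.5, 2.0),
    n_conditions: int = 8,
    condition_effect_fraction: float = 0.20,
    condition_effect_range: tuple[float, float] = (0.5, 1.5),
    wfsp_fraction: float = 0.0,
    deterministic_sectors: bool = False,
    mu_max: float = MU_MAX_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth generative parameters per gene.

    Sectors R/P/Q are drawn with the given proportions (exact counts in
    deterministic mode).  R and P genes get growth-law fold changes of
    magnitude uniform in ``fc_range`` (positive for R, negative for P); Q
    genes have slope 0.  A fraction of genes carries a condition-specific
    log2 offset in one random condition; ``wfsp_fraction`` instead plants a
    bimodal +/- offset over a fixed alternating half-split of the conditions
    (a condition-specific expression mode orthogonal to the growth trend).
    """
    props = np.asarray(sector_props, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("sector proportions must sum to 1 (within 1e-9)")
    rng = child_rng(seed, "gene-parameters")
    if deterministic_sectors:
        counts = np.floor(props * n_genes).astype(int)
        counts[2] += n_genes - counts.sum()
        sectors = np.repeat(np.array(["R", "P", "Q"]), counts)
    else:
        sectors = rng.choice(np.array(["R", "P", "Q"]), size=n_genes, p=props)

    base = rng.lognormal(mean=0.0, sigma=1.8, size=n_genes)  # mid-growth level
    fc_mag = rng.uniform(fc_range[0], fc_range[1], size=n_genes)
    fc_true = np.where(sectors == "R", fc_mag, np.where(sectors == "P", -fc_mag, 0.0))
    slope = base * fc_true / mu_max
    intercept = base * (1.0 - 0.5 * fc_true)

    cond_fx = np.zeros((n_genes, n_conditions))
    u = rng.uniform(size=n_genes)
    hit = u < condition_effect_fraction
    wfsp = (u >= condition_effect_fraction) & (
        u < condition_effect_fraction + wfsp_fraction
    )
    which_cond = rng.integers(0, n_conditions, size=n_genes)
    magnitude = rng.uniform(*condition_effect_range, size=n_genes) * rng.choice(
        [-1.0, 1.0], size=n_genes
    )
    cond_fx[np.arange(n_genes), which_cond] = np.where(hit, magnitude, 0.0)
    half = np.arange(n_conditions) % 2 == 0  # fixed alternating condition split
    wfsp_pattern = np.where(half, 1.0, -1.0)
    cond_fx[wfsp] += np.abs(magnitude[wfsp])[:, None] * wfsp_pattern[None, :]

    truth = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:05d}" for i in range(n_genes)],
            "sector_true": sectors,
            "fc_true": fc_true,
            "slope_true": slope,
            "intercept_true": intercept,
            "dispersion": np.exp(rng.normal(np.log(0.05), 0.3, size=n_genes)),
            "noise_cv": np.full(n_genes, 0.35),
            "length": rng.integers(300, 6000, size=n_genes),
            "mass": np.round(rng.lognormal(np.log(45.0), 0.5, size=n_genes), 2),
            "detect_prob": np.where(
                rng.uniform(size=n_genes) < 0.85,
                1.0,
                rng.uniform(0.5, 1.0, size=n_genes),
            ),
        }
    ).set_index("gene_id")
    for j in range(n_conditions):
        truth[f"cond_fx_{j + 1:02d}"] = cond_fx[:, j]
    return truth


def _condition_effect_matrix(truth: pd.DataFrame, design: pd.DataFrame) -> np.ndarray:
    """Per-gene x per-sample log2 condition offsets aligned to the design."""
    fx_cols = sorted(c for c in truth.columns if c.startswith("cond_fx_"))
    conditions = sorted(design["condition"].unique())
    if len(fx_cols) != len(conditions):
        raise ValueError(
            f"truth has {len(fx_cols)} condition-effect columns but the design "
            f"has {len(conditions)} conditions"
        )
    fx = truth[fx_cols].to_numpy(dtype=float)
    cond_index = {c: j for j, c in enumerate(conditions)}
    cols = design["condition"].map(cond_index).to_numpy()
    return fx[:, cols]


def latent_levels(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    floor: float = 0.0,
    warn_on_clamp: bool = True,
) -> pd.DataFrame:
    """Noise-free relative abundance of each gene in each sample.

    ``(slope * mu + intercept) * 2**condition_effect``, clamped at ``floor``
    (negative means can arise from steep negative slopes at high growth).
    """
    mu = design["growth_rate"].to_numpy(dtype=float)
    a = truth["slope_true"].to_numpy(dtype=float)[:, None]
    b = truth["intercept_true"].to_numpy(dtype=float)[:, None]
    levels = (a * mu[None, :] + b) * 2.0 ** _condition_effect_matrix(truth, design)
    n_clamped = int((levels < floor).sum())
    if n_clamped and warn_on_clamp:
        warnings.warn(
            f"clamped {n_clamped} negative latent means to the floor {floor}",
            stacklevel=2,
        )
    levels = np.maximum(levels, floor)
    return pd.DataFrame(levels, index=truth.index, columns=design["sample_id"].to_numpy())


def expected_rna_means(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    mean_depth: float | None = None,
    lib_factors: np.ndarray | None = None,
    floor: float = 0.0,
) -> pd.DataFrame:
    """Deterministic NB count means for given library factors (default 1)."""
    levels = latent_levels(truth, design, floor=floor, warn_on_clamp=False)
    if mean_depth is None:
        mean_depth = 600.0 * len(truth)
    lib = mean_depth * (
        np.ones(len(design)) if lib_factors is None else np.asarray(lib_factors, float)
    )
    norm = np.mean(levels.to_numpy().sum(axis=0))
    return levels * (lib / norm)


def simulate_rna_counts(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    mean_depth: float | None = None,
    depth_sd: float = 0.15,
    lib_factors: np.ndarray | None = None,
    floor: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial RNA-seq counts (genes x samples).

    Count means are the latent relative levels scaled by a per-sample library
    factor (lognormal around ``mean_depth`` expected counts per gene, or the
    explicit ``lib_factors``; the normalizer is a fixed constant so the means
    stay linear in both the levels and the library factors).  Variance
    follows mean + dispersion * mean^2; a gene's dispersion of exactly 0 is
    the documented noiseless switch (counts equal rounded means).
    """
    validate_design(design)
    rng = child_rng(seed, "rna-counts")
    levels = latent_levels(truth, design, floor=floor).to_numpy()
    if mean_depth is None:
        mean_depth = 600.0 * len(truth)
    if lib_factors is None:
        lib = mean_depth * np.exp(rng.normal(0.0, depth_sd, size=len(design)))
    else:
        lib = mean_depth * np.asarray(lib_factors, dtype=float)
    norm = np.mean(levels.sum(axis=0))  # fixed normalizer: means stay linear in levels
    means = levels * (lib[None, :] / norm)
    disp = truth["dispersion"].to_numpy(dtype=float)[:, None]
    counts = np.rint(means)
    stoch = (disp > 0.0) & np.isfinite(means)
    if stoch.any():
        n_param = 1.0 / np.broadcast_to(disp, means.shape)[stoch]
        m = means[stoch]
        p_param = n_param / (n_param + m)
        counts[stoch] = rng.negative_binomial(n_param, p_param)
    out = pd.DataFrame(
        counts.astype(np.int64), index=truth.index, columns=design["sample_id"].to_numpy()
    )
    return out


def simulate_protein_ibaq(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    intensity_scale: float = 1.0,
    floor: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Label-free iBAQ intensities with lognormal noise and missingness.

    Intensity = latent abundance x exp(N(0, sigma)) with
    sigma = sqrt(ln(1 + cv^2)) from the per-gene noise CV; detection is
    Bernoulli(detect_prob) per gene and sample, missing values are NaN.
    """
    validate_design(design)
    rng = child_rng(seed, "protein-ibaq")
    levels = latent_levels(truth, design, floor=floor).to_numpy()
    cv = truth["noise_cv"].to_numpy(dtype=float)[:, None]
    sigma = np.sqrt(np.log1p(cv**2))
    noise = np.exp(rng.normal(0.0, 1.0, size=levels.shape) * sigma)
    intensities = intensity_scale * levels * noise
    detect = rng.uniform(size=levels.shape) < truth["detect_prob"].to_numpy()[:, None]
    intensities = np.where(detect, intensities, np.nan)
    return pd.DataFrame(
        intensities, index=truth.index, columns=design["sample_id"].to_numpy()
    )


def to_protein_groups_table(ibaq: pd.DataFrame, masses: pd.Series) -> pd.DataFrame:
    """MaxQuant proteinGroups-like table: Protein IDs, mass, iBAQ columns."""
    table = pd.DataFrame({"Protein IDs": ibaq.index, "Mol. weight [kDa]": masses.reindex(ibaq.index).to_numpy()})
    for col in ibaq.columns:
        table[f"iBAQ {col}"] = ibaq[col].to_numpy()
    return table


def simulate_od_curve(
    mu: float,
    od0: float = 0.2,
    duration: float = 1.0,
    interval: float = 30.0 / 3600.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential regrowth OD series sampled every ``interval`` hours.

    od(t) = od0 * exp(mu t) * exp(N(0, noise_sd)), inclusive of both
    endpoints (30-s sampling over 1 h gives 121 points).
    """
    if mu <= 0 or od0 <= 0:
        raise ValueError("growth rate and initial OD must be positive")
    rng = child_rng(seed, "od-curve")
    n = int(round(duration / interval)) + 1
    t = np.arange(n) * interval
    od = od0 * np.exp(mu * t) * np.exp(rng.normal(0.0, noise_sd, size=n))
    return pd.DataFrame({"time": t, "od": od})
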