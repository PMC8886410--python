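"""End-to-end orchestration: configuration, stage order, outputs, manifest.

The full analysis runs seven stages in the order the method prescribes:
load inputs, normalize, growth-law fits (with gene-set growth laws),
unsupervised structure, cross-omics comparison, growth-rate-removed
differential expression, and functional enrichment.  Every output is a TSV
under the output directory and a manifest records inputs (hashed), seeds,
per-stage gene counts, and collected warnings.  Reruns with the same
configuration are byte-identical.

Also provides the default synthetic benchmark: a generated data set with
the assumed structure (8 conditions x 3 replicates, growth rates spanning
0.05-0.28 1/h, planted R/P/Q sectors and condition effects) written in the
same file formats the readers accept.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossomics, enrichment, growthde, growthfit, quantify, structure, synthetic
from ._seeds import child_seed
from .io import (
    read_counts,
    read_gmt,
    read_protein_groups,
    read_sample_sheet,
    write_expression_matrix,
    write_gmt,
)

__all__ = ["PipelineConfig", "run_full_analysis", "simulate_benchmark"]

STAGES = (
    "load_inputs",
    "normalize",
    "growth_fits",
    "structure",
    "cross_omics",
    "growth_removed_de",
    "enrichment",
)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of the full analysis.

    Defaults are the method's stated operating points: mu_max 0.3 1/h,
    sector tail-fdr 0.1 (confident at local fdr 0.1), DE at adjusted p 0.01
    with |log2 FC| 0.5, enrichment at local fdr 0.05.
    """

    counts: str
    sample_sheet: str
    protein_groups: str | None = None
    gene_lengths: str | None = None
    gene_sets: str | None = None
    mu_max: float = 0.3
    sector_fdr: float = 0.1
    confident_lfdr: float = 0.1
    de_padj: float = 0.01
    de_lfc: float = 0.5
    enrich_lfdr: float = 0.05
    detection_mode: str = "all_samples"
    k_clusters: int = 10
    n_boot: int = 1000
    gsea_n_perm: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("sector_fdr", self.sector_fdr, 0, 1),
            ("confident_lfdr", self.confident_lfdr, 0, 1),
            ("de_padj", self.de_padj, 0, 1),
            ("enrich_lfdr", self.enrich_lfdr, 0, 1),
        ):
            if not (lo < value < hi):
                raise ValueError(f"{name}={value} outside ({lo}, {hi})")
        if self.mu_max <= 0 or self.de_lfc < 0:
            raise ValueError("mu_max must be positive and de_lfc non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class _StageError(RuntimeError):
    pass


def run_full_analysis(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write all result tables; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages": [],
        "inputs": {},
        "warnings": [],
        "counts": {},
    }
    stage = "load_inputs"
    collected: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            result = _run_stages(config, outdir, manifest)
            collected = [str(w.message) for w in wlist]
    except Exception as exc:  # annotate with the failing stage
        stage = manifest["stages"][-1] if manifest["stages"] else stage
        raise _StageError(f"stage {manifest.get('failed_stage', stage)!r} failed: {exc}") from exc
    manifest["warnings"] = collected
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _run_stages(config: PipelineConfig, outdir: Path, manifest: dict) -> dict:
    # --- load_inputs ---------------------------------------------------
    manifest["failed_stage"] = "load_inputs"
    counts = read_counts(config.counts)
    design = read_sample_sheet(config.sample_sheet)
    manifest["inputs"]["counts"] = _sha256(config.counts)
    manifest["inputs"]["sample_sheet"] = _sha256(config.sample_sheet)
    ibaq = masses = None
    if config.protein_groups:
        ibaq, masses = read_protein_groups(
            config.protein_groups, sample_ids=design["sample_id"]
        )
        manifest["inputs"]["protein_groups"] = _sha256(config.protein_groups)
    else:
        manifest["protein_mode"] = "absent: running the RNA-only subset"
    lengths = None
    if config.gene_lengths:
        lengths = pd.read_csv(config.gene_lengths, sep="\t", index_col=0)["length"]
        manifest["inputs"]["gene_lengths"] = _sha256(config.gene_lengths)
    gene_sets = None
    if config.gene_sets:
        gene_sets = read_gmt(config.gene_sets)
        manifest["inputs"]["gene_sets"] = _sha256(config.gene_sets)
    manifest["counts"]["genes_in"] = int(len(counts))
    manifest["counts"]["samples"] = int(len(design))
    manifest["stages"].append("load_inputs")

    # --- normalize ------------------------------------------------------
    manifest["failed_stage"] = "normalize"
    sf = quantify.size_factors(counts)
    sf.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t")
    norm = quantify.normalize_counts(counts, sf)
    write_expression_matrix(norm, outdir / "normalized_counts.tsv")
    phi = psi_p = psi_m = None
    if ibaq is not None:
        ibaq_f, removed = quantify.filter_detected(
            ibaq, mode="all_replicates_within_any_condition", design=design
        )
        manifest["counts"]["proteins_removed_by_detection"] = len(removed)
        phi = quantify.mass_fractions(ibaq_f, masses)
        write_expression_matrix(phi, outdir / "mass_fractions.tsv")
        psi_p = quantify.number_fractions_protein(ibaq_f)
        write_expression_matrix(psi_p, outdir / "number_fractions_protein.tsv")
    if lengths is not None:
        psi_m = quantify.number_fractions_rna(norm, lengths)
        write_expression_matrix(psi_m, outdir / "number_fractions_rna.tsv")
    manifest["stages"].append("normalize")

    # --- growth_fits ----------------------------------------------------
    manifest["failed_stage"] = "growth_fits"
    fits_rna = growthfit.fit_all_genes(
        norm,
        design,
        mu_max=config.mu_max,
        q_threshold=config.sector_fdr,
        lfdr_threshold=config.confident_lfdr,
    )
    fits_rna.to_csv(outdir / "growth_fits_rna.tsv", sep="\t")
    manifest["counts"]["rna_sector_R"] = int((fits_rna["sector"] == "R").sum())
    manifest["counts"]["rna_sector_P"] = int((fits_rna["sector"] == "P").sum())
    fits_prot = None
    if phi is not None:
        fits_prot = growthfit.fit_all_genes(
            phi,
            design,
            mu_max=config.mu_max,
            q_threshold=config.sector_fdr,
            lfdr_threshold=config.confident_lfdr,
        )
        fits_prot.to_csv(outdir / "growth_fits_protein.tsv", sep="\t")
    if gene_sets:
        set_matrix = phi if phi is not None else norm
        rows = []
        mu = design.set_index("sample_id").loc[set_matrix.data.columns, "growth_rate"]
        for name, members in sorted(gene_sets.items()):
            try:
                profile, report = growthfit.setsum_profile(set_matrix, members)
            except ValueError:
                continue
            band = growthfit.bootstrap_growth_law(
                mu.to_numpy(),
                profile.to_numpy(),
                n_boot=config.n_boot,
                mu_max=config.mu_max,
                seed=child_seed(config.seed, f"bootstrap:{name}"),
            )
            rows.append(
                {
                    "set": name,
                    "n_in_matrix": report["n_in_matrix"],
                    "slope": band.slope,
                    "intercept": band.intercept,
                    "fc_mean": band.fc_mean,
                    "fc_sd": band.fc_sd,
                }
            )
        pd.DataFrame(rows).set_index("set").to_csv(
            outdir / "setsum_growth_laws.tsv", sep="\t"
        )
    manifest["stages"].append("growth_fits")

    # --- structure ------------------------------------------------------
    manifest["failed_stage"] = "structure"
    norm_detected, _ = quantify.filter_detected(norm, mode=config.detection_mode)
    z_rna = quantify.zscore(norm_detected, on_constant="drop")
    clusters = structure.hierarchical_clusters(
        z_rna, k=min(config.k_clusters, len(z_rna.data))
    )
    clusters.labels.to_frame().to_csv(outdir / "clusters_rna.tsv", sep="\t")
    z_struct = z_rna
    if phi is not None:
        phi_detected, _ = quantify.filter_detected(phi, mode="all_samples")
        z_struct = quantify.zscore(phi_detected, on_constant="drop")
    pca = structure.pca_structure(z_struct)
    pca.gene_scores.to_csv(outdir / "pca_gene_scores.tsv", sep="\t")
    pca.sample_pattern.to_csv(outdir / "pca_sample_pattern.tsv", sep="\t")
    pd.DataFrame(
        {"variance_explained": pca.variance_explained},
        index=pca.sample_pattern.columns,
    ).to_csv(outdir / "pca_variance.tsv", sep="\t")
    wfsp = structure.wfsp_classify(z_struct, pca)
    wfsp.to_frame().to_csv(outdir / "wfsp_labels.tsv", sep="\t")
    if phi is not None:
        barcode = structure.barcode_lengths(phi, design)
        barcode.lengths.to_csv(outdir / "barcode_lengths.tsv", sep="\t")
    manifest["counts"]["wfsp_plus"] = int((wfsp == "plus").sum())
    manifest["counts"]["wfsp_minus"] = int((wfsp == "minus").sum())
    manifest["stages"].append("structure")

    # --- cross_omics ----------------------------------------------------
    manifest["failed_stage"] = "cross_omics"
    if psi_p is not None and psi_m is not None:
        report = crossomics.reliability_report(psi_p, psi_m, design)
        report.to_csv(outdir / "reliability_report.tsv", sep="\t")
        resid = crossomics.residual_ratio(psi_p, psi_m)
        resid.to_csv(outdir / "residual_log2_ratio.tsv", sep="\t")
        manifest["counts"]["cross_omics_conditions"] = int(len(report))
    else:
        manifest["counts"]["cross_omics_conditions"] = 0
    manifest["stages"].append("cross_omics")

    # --- growth_removed_de ----------------------------------------------
    manifest["failed_stage"] = "growth_removed_de"
    screen = growthde.anova_variability_screen(norm, design)
    screen.to_csv(outdir / "anova_screen.tsv", sep="\t")
    manifest["counts"]["anova_variable"] = int(screen["variable"].sum())
    gn = growthde.growth_normalization_factors(counts, sf, fits_rna, design)
    manifest["counts"]["de_genes_excluded"] = len(gn.excluded)
    de_table = growthde.nb_de_test(counts, gn)
    de_table, union, signature = growthde.call_de(
        de_table, padj_threshold=config.de_padj, lfc_threshold=config.de_lfc
    )
    de_table.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    signature.to_csv(outdir / "de_signature.tsv", sep="\t")
    union.to_frame("de").to_csv(outdir / "de_union.tsv", sep="\t")
    manifest["counts"]["de_genes"] = int(union.sum())
    manifest["stages"].append("growth_removed_de")

    # --- enrichment -----------------------------------------------------
    manifest["failed_stage"] = "enrichment"
    if gene_sets:
        universe = set(map(str, gn.pred_raw.index))
        usable = {
            n: set(map(str, m)) & universe
            for n, m in gene_sets.items()
            if set(map(str, m)) & universe
        }
        if usable:
            collection = enrichment.GeneSetCollection(sets=usable, universe=universe)
            query = set(map(str, union[union].index))
            fisher = enrichment.enrich_fisher(query, collection)
            fisher["significant"] = fisher["lfdr"] < config.enrich_lfdr
            fisher.to_csv(outdir / "enrichment_fisher.tsv", sep="\t")
        ranks = enrichment.rank_statistic(fits_rna.dropna(subset=["p"]))
        gsea = enrichment.preranked_gsea(
            ranks,
            gene_sets,
            n_perm=config.gsea_n_perm,
            seed=child_seed(config.seed, "gsea"),
        )
        gsea.to_csv(outdir / "enrichment_gsea.tsv", sep="\t")
    manifest["stages"].append("enrichment")
    del manifest["failed_stage"]
    return manifest


def simulate_benchmark(
    outdir,
    n_genes: int = 5000,
    n_proteins: int = 2000,
    n_conditions: int = 8,
    n_replicates: int = 3,
    seed: int = 0,
) -> PipelineConfig:
    """Write the default synthetic benchmark inputs and its configuration.

    Produces counts, proteinGroups-like quantities for a random subset of
    genes, the sample sheet, transcript lengths, ground-truth parameters,
    and a small gene-set collection (the true R and P sectors plus random
    sets), then returns a ready PipelineConfig pointing at the files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = synthetic.generate_design(
        n_conditions=n_conditions, n_replicates=n_replicates, seed=child_seed(seed, "bench-design")
    )
    truth = synthetic.generate_gene_parameters(
        n_genes, n_conditions=n_conditions, seed=child_seed(seed, "bench-truth")
    )
    counts = synthetic.simulate_rna_counts(
        truth, design, seed=child_seed(seed, "bench-rna")
    )
    rng = np.random.default_rng(child_seed(seed, "bench-protein-subset"))
    protein_genes = np.sort(rng.choice(truth.index.to_numpy(), size=n_proteins, replace=False))
    ibaq = synthetic.simulate_protein_ibaq(
        truth.loc[protein_genes], design, seed=child_seed(seed, "bench-protein")
    )
    table = synthetic.to_protein_groups_table(ibaq, truth["mass"])

    counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    design.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    table.to_csv(outdir / "protein_groups.tsv", sep="\t", index=False)
    truth[["length"]].to_csv(outdir / "gene_lengths.tsv", sep="\t", index_label="gene_id")
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index_label="gene_id")

    sets = {
        "R_true": set(truth.index[truth["sector_true"] == "R"][:200]),
        "P_true": set(truth.index[truth["sector_true"] == "P"][:200]),
    }
    for i in range(8):
        sets[f"random_{i + 1}"] = set(
            rng.choice(truth.index.to_numpy(), size=50, replace=False)
        )
    write_gmt(sets, outdir / "gene_sets.gmt")

    config = PipelineConfig(
        counts=str(outdir / "counts.tsv"),
        sample_sheet=str(outdir / "samples.tsv"),
        protein_groups=str(outdir / "protein_groups.tsv"),
        gene_lengths=str(outdir / "gene_lengths.tsv"),
        gene_sets=str(outdir / "gene_sets.gmt"),
        seed=seed,
    )
    (outdir / "benchmark.yaml").write_text(yaml.safe_dump(asdict(config)))
    return config
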