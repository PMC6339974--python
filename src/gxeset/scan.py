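"""Genome-wide gene-based and single-marker G-by-E scans.

Orchestrates ingestion, QC, gene windowing and per-gene testing with any
configured subset of the implemented tests, flagging gene p-values below the
gene-based genome-wide threshold 2.5e-6 (0.05 / 20,000 genes) and the
suggestive threshold 5e-5 (1 / 20,000); single-SNP interaction results are
flagged at the SNP-level genome-wide threshold 5e-8.  Per-gene seeds are
derived deterministically from the base seed and gene id, so serial and
parallel executions agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _version
from .adabf import ResamplingConfig, adabf_test, derive_gene_seed
from .genotype_io import (
    GenotypeMatrix,
    map_gene_windows,
    mean_impute,
    qc_filter,
    read_gene_table,
    read_matrix_tsv,
    read_phenotype_table,
    read_plink_raw,
    read_vcf,
)
from .glm_engine import batch_interaction_fits, scale_exposure, standardize_trait, as_exposure
from .sberia import main_effect_filter, sberia_test, snp_e_filter
from .vc_test import vc_score_test

logger = logging.getLogger("gxeset")

GENE_GENOMEWIDE_P = 2.5e-6
GENE_SUGGESTIVE_P = 5e-5
SNP_GENOMEWIDE_P = 5e-8
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549...

AVAILABLE_TESTS = ("adabf", "sberia_main", "sberia_snpe", "vc_fixed", "vc_ridge")


@dataclass
class ScanConfig:
    genotype_path: str
    pheno_path: str
    trait: str
    exposure: str
    gene_table_path: str | None = None
    genotype_format: str = "tsv"  # tsv | raw | vcf
    snp_info_path: str | None = None
    bed: bool = False
    family: str = "gaussian"
    covariates: list[str] = field(default_factory=list)
    tests: list[str] = field(default_factory=lambda: ["adabf", "sberia_main", "vc_fixed"])
    flank: int = 50_000
    genomewide: float = GENE_GENOMEWIDE_P
    suggestive: float = GENE_SUGGESTIVE_P
    seed: int = 0
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    qc: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.genomewide < 1 and 0 < self.suggestive < 1):
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.genomewide > self.suggestive:
            raise ValueError("genome-wide threshold must not exceed the suggestive one")
        bad = [t for t in self.tests if t not in AVAILABLE_TESTS]
        if bad:
            raise ValueError(f"unknown tests {bad}; available: {AVAILABLE_TESTS}")


@dataclass
class ScanReport:
    genes: pd.DataFrame | None
    snps: pd.DataFrame | None
    lambda_gc: float | None
    config: dict

    def metadata_block(self) -> str:
        lines = [f"# gxeset {_version}"]
        for k, v in self.config.items():
            lines.append(f"# {k} = {v}")
        if self.lambda_gc is not None:
            lines.append(f"# lambda_gc = {self.lambda_gc:.4f}")
        return "\n".join(lines) + "\n"

    def write_gene_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.metadata_block())
            self.genes.to_csv(fh, sep="\t", index=False)

    def write_snp_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.metadata_block())
            self.snps.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _load_genotypes(cfg: ScanConfig) -> GenotypeMatrix:
    snp_info = None
    if cfg.snp_info_path:
        snp_info = pd.read_csv(cfg.snp_info_path, sep="\t")
    if cfg.genotype_format == "tsv":
        return read_matrix_tsv(cfg.genotype_path, snp_info)
    if cfg.genotype_format == "raw":
        return read_plink_raw(cfg.genotype_path, snp_info)
    if cfg.genotype_format == "vcf":
        return read_vcf(cfg.genotype_path)
    raise ValueError(f"unknown genotype format {cfg.genotype_format!r}")


def load_scan_inputs(cfg: ScanConfig):
    """Load and align genotypes and the phenotype table; apply QC.

    Samples with missing trait or exposure are dropped (and counted in the
    log) — the exposure non-response handling.
    """
    gm = _load_genotypes(cfg)
    if gm.n_snps == 0:
        raise ValueError(f"no SNPs loaded from {cfg.genotype_path}")
    pheno = read_phenotype_table(cfg.pheno_path)
    for col in [cfg.trait, cfg.exposure, *cfg.covariates]:
        if col not in pheno.columns:
            raise ValueError(f"phenotype table lacks required column {col!r}")
    shared = [s for s in gm.samples if s in pheno.index]
    if not shared:
        raise ValueError("no overlapping sample ids between genotypes and phenotypes")
    pheno = pheno.loc[shared]
    complete = pheno[[cfg.trait, cfg.exposure, *cfg.covariates]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d samples with missing trait/exposure/covariates", n_dropped)
    pheno = pheno.loc[complete]
    gm = gm.take_samples(list(pheno.index))
    if cfg.qc:
        gm, report = qc_filter(gm)
        logger.info("QC: %s", report)
    Y = pheno[cfg.trait].to_numpy(dtype=float)
    E = pheno[cfg.exposure].to_numpy(dtype=float)
    X = pheno[cfg.covariates].to_numpy(dtype=float) if cfg.covariates else None
    return gm, Y, E, X


# ---------------------------------------------------------------------------
# single-marker scan
# ---------------------------------------------------------------------------

def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor: median association chi-square / 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


def run_single_marker_scan(cfg: ScanConfig, chunk: int = 2_000) -> ScanReport:
    """Per-SNP interaction scan: one GLM per SNP, Wald p for the G-by-E term."""
    gm, Y, E, X = load_scan_inputs(cfg)
    ev = scale_exposure(as_exposure(E))
    Yw = standardize_trait(Y) if cfg.family == "gaussian" else Y
    counts = mean_impute(gm.counts)
    betas = np.empty(gm.n_snps)
    ses = np.empty(gm.n_snps)
    ok_all = np.zeros(gm.n_snps, dtype=bool)
    for start in range(0, gm.n_snps, chunk):
        sl = slice(start, min(start + chunk, gm.n_snps))
        b, v, ok = batch_interaction_fits(Yw, counts[:, sl], ev.values, X, cfg.family)
        betas[sl], ses[sl], ok_all[sl] = b, np.sqrt(v), ok
    with np.errstate(invalid="ignore"):
        wald = betas / ses
        pvals = 2.0 * stats.norm.sf(np.abs(wald))
    df = gm.snps.copy()
    df["beta_ge"] = betas
    df["se"] = ses
    df["wald"] = wald
    df["p"] = pvals
    df["converged"] = ok_all
    df["genomewide"] = (df["p"] < SNP_GENOMEWIDE_P) & ok_all
    lam = genomic_inflation(np.clip(pvals[ok_all], 1e-300, 1.0))
    logger.info("single-marker scan: %d SNPs, lambda_GC = %.3f", gm.n_snps, lam)
    return ScanReport(genes=None, snps=df, lambda_gc=lam, config=_cfg_dict(cfg))


# ---------------------------------------------------------------------------
# gene-based scan
# ---------------------------------------------------------------------------

def _gene_tests(Y, G, E, X, family, tests, seed, resampling):
    out = {}
    for t in tests:
        try:
            if t == "adabf":
                cfg = ResamplingConfig(resampling.b_min, resampling.b_max,
                                       resampling.stop_multiplier, seed)
                out[t] = adabf_test(Y, G, E, X, family, cfg=cfg).p_value
            elif t == "sberia_main":
                out[t] = sberia_test(Y, G, E, X, family, main_effect_filter(Y, G, X, family))
            elif t == "sberia_snpe":
                out[t] = sberia_test(Y, G, E, X, family, snp_e_filter(E, G, X))
            elif t == "vc_fixed":
                out[t] = vc_score_test(Y, G, E, X, family, "fixed").p_value
            elif t == "vc_ridge":
                out[t] = vc_score_test(Y, G, E, X, family, "ridge").p_value
        except Exception as exc:  # a single gene must not kill the scan
            logger.warning("test %s failed for this gene: %s", t, exc)
            out[t] = np.nan
    return out


def run_gene_scan(cfg: ScanConfig) -> ScanReport:
    """Gene-based scan over all annotated genes with >= 1 assigned SNP."""
    if cfg.gene_table_path is None:
        raise ValueError("gene-based scan requires a gene annotation table")
    gm, Y, E, X = load_scan_inputs(cfg)
    genes = read_gene_table(cfg.gene_table_path, bed=cfg.bed)
    windows = map_gene_windows(genes, gm, cfg.flank)
    counts = mean_impute(gm.counts)
    rows = []
    for win in windows:
        if win.n_snps == 0:
            logger.info("gene %s skipped: no SNPs in window", win.gene_id)
            continue
        seed = derive_gene_seed(cfg.seed, win.gene_id)
        G = counts[:, win.snp_indices]
        ps = _gene_tests(Y, G, E, X, cfg.family, cfg.tests, seed, cfg.resampling)
        row = {"gene_id": win.gene_id, "chrom": win.chrom,
               "window_start": win.window_start, "window_end": win.window_end,
               "n_snps": win.n_snps}
        for t in cfg.tests:
            row[f"p_{t}"] = ps[t]
        best = np.nanmin([ps[t] for t in cfg.tests])
        row["genomewide"] = bool(best < cfg.genomewide)
        row["suggestive"] = bool(best < cfg.suggestive)
        rows.append(row)
        logger.info("gene %s: %s", win.gene_id,
                    ", ".join(f"{t}={ps[t]:.3g}" for t in cfg.tests))
    df = pd.DataFrame(rows)
    return ScanReport(genes=df, snps=None, lambda_gc=None, config=_cfg_dict(cfg))


def _cfg_dict(cfg: ScanConfig) -> dict:
    d = asdict(cfg)
    d["resampling"] = (f"b_min={cfg.resampling.b_min},b_max={cfg.resampling.b_max},"
                       f"stop={cfg.resampling.stop_multiplier}")
    return d
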