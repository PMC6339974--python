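"""Genotype, phenotype and gene-annotation ingestion with SNP/sample QC.

Genotypes are held as an n x L matrix of minor-allele counts (0, 1, 2, or
missing).  Quality control follows common GWAS practice: SNPs are dropped for
low genotyping call rate (< 95%), Hardy-Weinberg disequilibrium
(P < 5.7e-7), or monomorphism; samples are pruned for cryptic relatedness
using the PI-HAT score, PI-HAT = Pr(IBD=2) + 0.5 * Pr(IBD=1), removing one
member of every pair with PI-HAT > 0.1.  Gene windows extend each gene by a
50 kb flank on both sides (the conventional allowance for nearby regulatory
regions); SNP-to-window assignment is inclusive at both bounds, with 1-based
GRCh37-style coordinates throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("gxeset")

SNP_COLUMNS = ["id", "chrom", "pos", "minor_allele", "major_allele"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """An n x L minor-allele count matrix with per-SNP metadata.

    ``counts`` entries are in {0, 1, 2} or NaN (missing).  On construction the
    matrix is sorted by (chrom, pos) and any SNP whose non-missing allele
    frequency exceeds 0.5 is reflected (g -> 2 - g, allele labels swapped) so
    that the stored frequency is always a minor-allele frequency.
    """

    samples: list[str]
    snps: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x SNPs)")
        n, L = self.counts.shape
        if len(self.samples) != n:
            raise ValueError("sample ids do not match the number of count rows")
        if len(self.snps) != L:
            raise ValueError("SNP table does not match the number of count columns")
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"SNP table lacks columns {missing}")
        vals = self.counts[~np.isnan(self.counts)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing genotype entries must be 0, 1 or 2")
        self.samples = [str(s) for s in self.samples]
        self.snps = self.snps.reset_index(drop=True).copy()
        self.snps["chrom"] = self.snps["chrom"].astype(str)
        self.snps["pos"] = self.snps["pos"].astype(int)
        # enforce minor-allele orientation before sorting
        freq = self._allele_freq()
        flip = freq > 0.5
        if flip.any():
            self.counts[:, flip] = 2.0 - self.counts[:, flip]
            minor = self.snps.loc[flip, "minor_allele"].copy()
            self.snps.loc[flip, "minor_allele"] = self.snps.loc[flip, "major_allele"]
            self.snps.loc[flip, "major_allele"] = minor
        order = self.snps.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        self.counts = self.counts[:, order]
        self.snps = self.snps.iloc[order].reset_index(drop=True)
        self.snps["maf"] = self._allele_freq()

    def _allele_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.counts, axis=0) / 2.0

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return self.snps["maf"].to_numpy()

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.counts).mean(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP (n_AA, n_Aa, n_aa) counts, major homozygote first."""
        out = np.zeros((self.n_snps, 3), dtype=int)
        for g in (0, 1, 2):
            out[:, g] = np.nansum(self.counts == g, axis=0)
        return out

    def take_snps(self, index) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return GenotypeMatrix(self.samples, self.snps.iloc[idx], self.counts[:, idx])

    def take_samples(self, keep) -> "GenotypeMatrix":
        keep = [s for s in self.samples if s in set(keep)] if not isinstance(keep, np.ndarray) else keep
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in keep], dtype=int)
        return GenotypeMatrix(list(keep), self.snps, self.counts[idx])


@dataclass
class GeneWindow:
    """A gene's analysis region (flank-expanded) and its assigned SNP columns."""

    gene_id: str
    chrom: str
    gene_start: int
    gene_end: int
    window_start: int
    window_end: int
    snp_indices: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


@dataclass
class QCReport:
    n_input_snps: int = 0
    n_removed_callrate: int = 0
    n_removed_hwe: int = 0
    n_removed_monomorphic: int = 0
    n_retained: int = 0
    n_removed_samples_relatedness: int = 0

    def __post_init__(self) -> None:
        removed = self.n_removed_callrate + self.n_removed_hwe + self.n_removed_monomorphic
        if self.n_retained != self.n_input_snps - removed:
            raise ValueError("QC tallies are inconsistent")


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg proportions.

    Expected genotype counts use the sample allele frequency.  Monomorphic
    SNPs return p = 1 by convention.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotyped samples: HWE test undefined")
    q = (counts[1] + 2 * counts[2]) / (2 * n)  # frequency of the 'a' allele
    if q == 0.0 or q == 1.0:
        return 1.0
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(gm: GenotypeMatrix, call_rate_min: float = 0.95,
              hwe_p_min: float = 5.7e-7) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs failing call rate, then HWE, then monomorphism; tally each stage.

    Boundary convention mirrors "rate < 95% removed": a SNP at exactly the
    threshold is retained.
    """
    n_input = gm.n_snps
    keep = gm.call_rate() >= call_rate_min
    n_callrate = int(n_input - keep.sum())
    gm2 = gm.take_snps(np.flatnonzero(keep))
    gcounts = gm2.genotype_counts()
    hwe_p = np.array([hwe_test(*row) for row in gcounts])
    keep2 = hwe_p >= hwe_p_min
    n_hwe = int(len(keep2) - keep2.sum())
    gm3 = gm2.take_snps(np.flatnonzero(keep2))
    mono = np.array([np.unique(col[~np.isnan(col)]).size <= 1 for col in gm3.counts.T])
    n_mono = int(mono.sum())
    gm4 = gm3.take_snps(np.flatnonzero(~mono))
    report = QCReport(n_input_snps=n_input, n_removed_callrate=n_callrate,
                      n_removed_hwe=n_hwe, n_removed_monomorphic=n_mono,
                      n_retained=gm4.n_snps)
    return gm4, report


def pi_hat(pr_ibd1: float, pr_ibd2: float) -> float:
    """Relatedness score Pr(IBD=2) + 0.5 * Pr(IBD=1)."""
    if pr_ibd1 < 0 or pr_ibd2 < 0 or pr_ibd1 + pr_ibd2 > 1:
        raise ValueError("IBD probabilities must be non-negative and sum to <= 1")
    return pr_ibd2 + 0.5 * pr_ibd1


def relatedness_filter(pairs, threshold: float = 0.1) -> set[str]:
    """Greedily remove one member of every pair with PI-HAT strictly above threshold.

    Repeatedly removes the sample involved in the most remaining flagged pairs
    (ties broken by removing the lexicographically later id) until no flagged
    pair remains; returns the removed set.
    """
    edges = {(str(a), str(b)) for a, b, score in pairs if score > threshold}
    removed: set[str] = set()
    while edges:
        degree: dict[str, int] = {}
        for a, b in edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        top = max(degree.values())
        victim = max(s for s, d in degree.items() if d == top)
        removed.add(victim)
        edges = {e for e in edges if victim not in e}
    return removed


def mean_impute(counts: np.ndarray) -> np.ndarray:
    """Impute missing genotypes to the SNP's mean non-missing count.

    Keeps the sample size constant across the SNPs of one gene window, which
    complete-case analysis would not.
    """
    out = np.array(counts, dtype=float)
    col_mean = np.nanmean(out, axis=0)
    mask = np.isnan(out)
    if mask.any():
        out[mask] = np.take(col_mean, np.nonzero(mask)[1])
    return out


# ---------------------------------------------------------------------------
# gene windows
# ---------------------------------------------------------------------------

def map_gene_windows(genes: pd.DataFrame, gm: GenotypeMatrix,
                     flank: int = 50_000) -> list[GeneWindow]:
    """Expand each gene by ``flank`` bp both sides and assign SNP columns.

    ``genes`` needs columns gene_id, chrom, start, end (1-based inclusive).
    Windows are clamped at position 1; assignment is inclusive at both bounds.
    Genes with zero assigned SNPs are returned with empty indices (a scan
    skips them).
    """
    windows = []
    chrom = gm.snps["chrom"].to_numpy()
    pos = gm.snps["pos"].to_numpy()
    for i, row in genes.reset_index(drop=True).iterrows():
        try:
            gid = str(row["gene_id"])
            gchrom = str(row["chrom"])
            start, end = int(row["start"]), int(row["end"])
            if start > end:
                raise ValueError(f"start {start} > end {end}")
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed gene annotation row {i + 1}: {exc}") from exc
        wstart = max(1, start - flank)
        wend = end + flank
        idx = np.flatnonzero((chrom == gchrom) & (pos >= wstart) & (pos <= wend))
        windows.append(GeneWindow(gid, gchrom, start, end, wstart, wend, idx))
    return windows


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _snp_table(ids, snp_info: pd.DataFrame | None) -> pd.DataFrame:
    """Build the SNP metadata table, joining an optional info table on id."""
    base = pd.DataFrame({"id": [str(s) for s in ids]})
    if snp_info is None:
        base["chrom"] = "0"
        base["pos"] = np.arange(1, len(base) + 1)
        base["minor_allele"] = "A"
        base["major_allele"] = "B"
        return base
    info = snp_info.copy()
    info["id"] = info["id"].astype(str)
    merged = base.merge(info, on="id", how="left", validate="one_to_one")
    if merged["pos"].isna().any():
        missing = merged.loc[merged["pos"].isna(), "id"].tolist()[:5]
        raise ValueError(f"SNP info table lacks entries for {missing} ...")
    return merged


def read_plink_raw(path, snp_info: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a PLINK additive-recode text file (.raw dialect).

    Columns FID IID PAT MAT SEX PHENOTYPE then one column per SNP named
    ``<id>_<counted allele>`` with values 0/1/2/NA.  Positional metadata is
    taken from ``snp_info`` (columns id, chrom, pos, minor_allele,
    major_allele) when given.
    """
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in df.columns:
        raise ValueError("PLINK .raw file lacks an IID column")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    if not snp_cols:
        raise ValueError("PLINK .raw file contains no SNP columns")
    ids, counted = [], []
    for c in snp_cols:
        sid, _, allele = c.rpartition("_")
        ids.append(sid if sid else c)
        counted.append(allele if sid else "A")
    counts = df[snp_cols].to_numpy(dtype=float)
    snps = _snp_table(ids, snp_info)
    if snp_info is None:
        snps["minor_allele"] = counted
    return GenotypeMatrix(df["IID"].astype(str).tolist(), snps, counts)


def read_matrix_tsv(path, snp_info: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read the internal TSV dialect: first column sample id, header = SNP ids."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("genotype TSV needs a sample-id column plus SNP columns")
    samples = df.iloc[:, 0].astype(str).tolist()
    counts = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(samples, _snp_table(df.columns[1:], snp_info), counts)


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF, converting GT calls to minor-allele counts."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        counts = np.where(gt == 3, 2.0, gt)
        counts[gt == 2] = np.nan
        rows.append(counts)
        meta.append({"id": var.ID or f"{var.CHROM}:{var.POS}", "chrom": str(var.CHROM),
                     "pos": int(var.POS), "minor_allele": var.ALT[0] if var.ALT else "N",
                     "major_allele": var.REF})
    if not rows:
        raise ValueError(f"no variants found in {path}")
    return GenotypeMatrix(samples, pd.DataFrame(meta), np.column_stack(rows))


def read_gene_table(path, bed: bool = False) -> pd.DataFrame:
    """Read a gene annotation table.

    Default dialect: >= 4 columns (gene_id, chrom, start, end), 1-based
    inclusive.  With ``bed=True`` the columns are BED order (chrom, start,
    end, name), 0-based half-open, and are converted.
    """
    df = pd.read_csv(path, sep="\t", header=None if bed else 0, comment="#")
    if bed:
        if df.shape[1] < 4:
            raise ValueError("BED gene file needs chrom, start, end, name columns")
        out = pd.DataFrame({
            "gene_id": df.iloc[:, 3].astype(str),
            "chrom": df.iloc[:, 0].astype(str),
            "start": df.iloc[:, 1].astype(int) + 1,
            "end": df.iloc[:, 2].astype(int),
        })
        return out
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table lacks columns {sorted(required - set(df.columns))}")
    return df[["gene_id", "chrom", "start", "end"]].astype(
        {"gene_id": str, "chrom": str, "start": int, "end": int})


def read_phenotype_table(path, sample_col: str | None = None) -> pd.DataFrame:
    """Read a phenotype/exposure/covariate TSV, indexed by sample id."""
    df = pd.read_csv(path, sep="\t")
    col = sample_col or df.columns[0]
    if col not in df.columns:
        raise ValueError(f"phenotype table lacks sample column {col!r}")
    df[col] = df[col].astype(str)
    return df.set_index(col)
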