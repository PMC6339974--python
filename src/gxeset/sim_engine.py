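"""Simulation framework: LD-structured genotypes, trait models, experiments.

Genotypes are generated from a Gaussian copula: each haplotype is a
thresholded draw from an AR(1)-correlated multivariate normal, so adjacent
SNPs are in linkage disequilibrium with tunable strength and every SNP's
minor-allele frequency is drawn from a configurable range.  Phenotypes follow
the standard simulation design for gene-environment interaction studies: a
binary exposure E ~ Bernoulli(0.5) and

    continuous:  Y = sum_d bG_l G_l + sum_d bGE_l G_l E + e,  e ~ N(0, 1)
    binary:      logit P(Y=1) = -0.4 + sum_d bG_l G_l + sum_d bGE_l G_l E

with the intercept log(0.4/0.6) = -0.4 giving a baseline prevalence of 0.4
(the worldwide adult hypertension prevalence).  The 11 power scenarios
combine d = 1 or 4 interacting SNPs with sign patterns of main and
interaction effects; effect magnitudes are drawn uniformly from three levels
(continuous: [0.08, 0.12], [0.13, 0.17], [0.18, 0.22]; binary log-odds:
[log 1.05, log 1.15], [log 1.25, log 1.35], [log 1.45, log 1.55]).

Experiment runners estimate empirical type-I error over a grid of nominal
levels (null phenotypes over fixed genotypes) and empirical power at a given
alpha, for any configured subset of the implemented tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .adabf import ResamplingConfig, adabf_test
from .genotype_io import GenotypeMatrix
from .sberia import main_effect_filter, sberia_test, snp_e_filter
from .vc_test import vc_score_test

logger = logging.getLogger("gxeset")

LOGISTIC_INTERCEPT = np.log(0.4 / 0.6)  # baseline prevalence 0.4


# ---------------------------------------------------------------------------
# scenarios and effect sizes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Sign pattern of SNP main and interaction effects for one scenario."""

    label: str
    main_signs: tuple
    inter_signs: tuple

    def __post_init__(self):
        if len(self.main_signs) != len(self.inter_signs):
            raise ValueError("main and interaction sign vectors must share length")

    @property
    def d(self) -> int:
        return len(self.inter_signs)


SCENARIOS: dict[str, ScenarioSpec] = {s.label: s for s in [
    ScenarioSpec("1-1", (0,), (+1,)),
    ScenarioSpec("1-2", (+1,), (+1,)),
    ScenarioSpec("1-3", (-1,), (+1,)),
    ScenarioSpec("4-1", (0, 0, 0, 0), (+1, +1, +1, +1)),
    ScenarioSpec("4-2", (+1, +1, +1, +1), (+1, +1, +1, +1)),
    ScenarioSpec("4-3", (-1, -1, -1, -1), (+1, +1, +1, +1)),
    ScenarioSpec("4-4", (+1, +1, -1, -1), (+1, +1, +1, +1)),
    ScenarioSpec("4-5", (0, 0, 0, 0), (+1, +1, -1, -1)),
    ScenarioSpec("4-6", (+1, +1, -1, -1), (+1, +1, -1, -1)),
    ScenarioSpec("4-7", (-1, -1, +1, +1), (+1, +1, -1, -1)),
    ScenarioSpec("4-8", (+1, -1, +1, -1), (+1, +1, -1, -1)),
]}

EFFECT_RANGES = {
    ("gaussian", "small"): (0.08, 0.12),
    ("gaussian", "medium"): (0.13, 0.17),
    ("gaussian", "large"): (0.18, 0.22),
    ("binomial", "small"): (np.log(1.05), np.log(1.15)),
    ("binomial", "medium"): (np.log(1.25), np.log(1.35)),
    ("binomial", "large"): (np.log(1.45), np.log(1.55)),
}


@dataclass(frozen=True)
class EffectSizeLevel:
    level: str
    family: str

    @property
    def range(self) -> tuple[float, float]:
        try:
            return EFFECT_RANGES[(self.family, self.level)]
        except KeyError:
            raise ValueError(f"unknown effect level {self.level!r} / family {self.family!r}")


def draw_effect_sizes(level: EffectSizeLevel, signs, seed) -> np.ndarray:
    """|beta| ~ Uniform(level range) with the given sign; sign 0 -> beta 0."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = np.asarray(signs, dtype=float)
    lo, hi = level.range
    mags = rng.uniform(lo, hi, size=len(signs))
    return np.where(signs == 0, 0.0, signs * mags)


# ---------------------------------------------------------------------------
# genotype and phenotype generation
# ---------------------------------------------------------------------------

def simulate_genotypes(n: int, L: int, maf_range=(0.05, 0.5), ld_rho: float = 0.5,
                       seed: int | np.random.Generator = 0,
                       chrom: str = "1", spacing: int = 1_000) -> GenotypeMatrix:
    """LD-structured SNP genotypes via a thresholded AR(1) Gaussian copula.

    Two haplotypes per sample are drawn from a multivariate normal with AR(1)
    correlation ``ld_rho`` along the SNP axis and thresholded at each SNP's
    normal MAF quantile (MAF ~ Uniform(maf_range)); the minor-allele count is
    the haplotype sum.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if not abs(ld_rho) < 1:
        raise ValueError("ld_rho must lie strictly inside (-1, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=L)
    thresh = stats.norm.ppf(maf)
    counts = np.zeros((n, L))
    for _hap in range(2):
        z = np.empty((n, L))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, L - 1)) if L > 1 else None
        scale = np.sqrt(1.0 - ld_rho ** 2)
        for j in range(1, L):
            z[:, j] = ld_rho * z[:, j - 1] + scale * innov[:, j - 1]
        counts += z < thresh[None, :]
    snps = pd.DataFrame({
        "id": [f"snp{j + 1}" for j in range(L)],
        "chrom": chrom,
        "pos": np.arange(1, L + 1) * spacing,
        "minor_allele": "A",
        "major_allele": "B",
    })
    samples = [f"s{i + 1}" for i in range(n)]
    return GenotypeMatrix(samples, snps, counts)


def default_effect_indices(L: int, d: int) -> np.ndarray:
    """Place the d causal SNPs evenly through the window interior, so that
    they sit in LD with flanking null SNPs on both sides."""
    if d > L:
        raise ValueError(f"cannot place {d} causal SNPs in a {L}-SNP window")
    # i * L // (d + 1) for i = 1..d: d distinct interior-leaning positions
    return (np.arange(1, d + 1) * L) // (d + 1)


def simulate_phenotype(G, scenario: ScenarioSpec | str, level: EffectSizeLevel | str,
                       family: str = "gaussian", seed: int | np.random.Generator = 0,
                       effect_indices=None):
    """Simulate (Y, E) for one replicate under a power scenario.

    ``G`` is a GenotypeMatrix or a plain count matrix.  E ~ Bernoulli(0.5);
    effect sizes are drawn per replicate from the level's uniform range.
    Passing a scenario with all-zero effects (or label "null") gives the
    null model used for type-I error studies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = G.counts if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    n, L = counts.shape
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if isinstance(level, str):
        level = EffectSizeLevel(level, family)
    d = scenario.d
    if d > L:
        raise ValueError(f"scenario needs {d} SNPs but the window has {L}")
    idx = default_effect_indices(L, d) if effect_indices is None else np.asarray(effect_indices)
    beta_g = draw_effect_sizes(level, scenario.main_signs, rng)
    beta_ge = draw_effect_sizes(level, scenario.inter_signs, rng)
    E = rng.binomial(1, 0.5, size=n).astype(float)
    Gd = counts[:, idx]
    lin = Gd @ beta_g + (Gd * E[:, None]) @ beta_ge
    if family == "gaussian":
        Y = lin + rng.standard_normal(n)
    elif family == "binomial":
        prob = 1.0 / (1.0 + np.exp(-(LOGISTIC_INTERCEPT + lin)))
        Y = rng.binomial(1, prob).astype(float)
    else:
        raise ValueError(f"unknown family {family!r}")
    return Y, E


def simulate_null_phenotype(n: int, family: str, rng) -> tuple[np.ndarray, np.ndarray]:
    """Null-model replicate: no genetic or interaction effects."""
    E = rng.binomial(1, 0.5, size=n).astype(float)
    if family == "gaussian":
        Y = rng.standard_normal(n)
    else:
        prev = 1.0 / (1.0 + np.exp(-LOGISTIC_INTERCEPT))
        Y = rng.binomial(1, prev, size=n).astype(float)
    return Y, E


# ---------------------------------------------------------------------------
# test registry
# ---------------------------------------------------------------------------

def _run_adabf(Y, G, E, X, family, seed, resampling):
    cfg = resampling or ResamplingConfig()
    cfg = ResamplingConfig(cfg.b_min, cfg.b_max, cfg.stop_multiplier, seed)
    return adabf_test(Y, G, E, X, family, cfg=cfg).p_value


def _run_sberia_main(Y, G, E, X, family, seed, resampling):
    filt = main_effect_filter(Y, G, X, family)
    return sberia_test(Y, G, E, X, family, filt)


def _run_sberia_snpe(Y, G, E, X, family, seed, resampling):
    filt = snp_e_filter(E, G, X)
    return sberia_test(Y, G, E, X, family, filt)


def _run_vc_fixed(Y, G, E, X, family, seed, resampling):
    return vc_score_test(Y, G, E, X, family, main_effect_mode="fixed").p_value


def _run_vc_ridge(Y, G, E, X, family, seed, resampling):
    return vc_score_test(Y, G, E, X, family, main_effect_mode="ridge").p_value


TEST_REGISTRY = {
    "adabf": _run_adabf,
    "sberia_main": _run_sberia_main,
    "sberia_snpe": _run_sberia_snpe,
    "vc_fixed": _run_vc_fixed,
    "vc_ridge": _run_vc_ridge,
}


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Per-test empirical rejection rates with 95% binomial bands."""

    kind: str  # "type1" or "power"
    tests: list[str]
    family: str
    n_reps: int
    levels: tuple
    pvalues: dict[str, np.ndarray]
    seed: int
    meta: dict = field(default_factory=dict)

    def rejection_rate(self, test: str, alpha: float) -> float:
        p = self.pvalues[test]
        return float(np.mean(p <= alpha))

    def band(self, test: str, alpha: float) -> tuple[float, float, float]:
        """(rate, lo, hi): normal-approximation 95% binomial band."""
        rate = self.rejection_rate(test, alpha)
        half = 1.96 * np.sqrt(max(rate * (1 - rate), 1e-300) / self.n_reps)
        return rate, max(rate - half, 0.0), min(rate + half, 1.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tests:
            for a in self.levels:
                rate, lo, hi = self.band(t, a)
                rows.append({"test": t, "family": self.family, "level": a,
                             "rate": rate, "ci_lo": lo, "ci_hi": hi,
                             "n_reps": self.n_reps})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _rep_seeds(seed: int, n_reps: int) -> np.ndarray:
    ss = np.random.SeedSequence(int(seed))
    return np.array([int(c.generate_state(1)[0]) & 0x7FFFFFFF for c in ss.spawn(n_reps)])


def _check_tests(tests) -> list[str]:
    tests = list(tests)
    unknown = [t for t in tests if t not in TEST_REGISTRY]
    if unknown:
        raise ValueError(f"unknown tests {unknown}; available: {sorted(TEST_REGISTRY)}")
    return tests


def run_type1_experiment(tests, n: int = 1000, L: int = 20, n_reps: int = 5000,
                         levels=(0.05, 0.01, 0.001), seed: int = 0,
                         family: str = "gaussian", ld_rho: float = 0.5,
                         maf_range=(0.05, 0.5),
                         resampling: ResamplingConfig | None = None,
                         progress: bool = False) -> ExperimentResult:
    """Empirical type-I error of the chosen tests under the null model.

    One fixed genotype matrix; ``n_reps`` independent null (Y, E) replicates;
    rejection rates reported at each nominal level with binomial bands.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    tests = _check_tests(tests)
    gm = simulate_genotypes(n, L, maf_range, ld_rho, seed=np.random.default_rng(seed))
    G = gm.counts
    seeds = _rep_seeds(seed + 1, n_reps)
    pvals = {t: np.empty(n_reps) for t in tests}
    for r in range(n_reps):
        rng = np.random.default_rng(seeds[r])
        Y, E = simulate_null_phenotype(n, family, rng)
        for t in tests:
            pvals[t][r] = TEST_REGISTRY[t](Y, G, E, None, family, int(seeds[r]), resampling)
        if progress and (r + 1) % 500 == 0:
            logger.info("type-I experiment: %d / %d replicates", r + 1, n_reps)
    return ExperimentResult("type1", tests, family, n_reps, tuple(levels), pvals, seed,
                            meta=dict(n=n, L=L, ld_rho=ld_rho, maf_range=tuple(maf_range)))


def run_power_experiment(tests, scenario, level, n: int = 1000, L: int = 20,
                         n_reps: int = 500, alpha: float = 0.001, seed: int = 0,
                         family: str = "gaussian", ld_rho: float = 0.5,
                         maf_range=(0.05, 0.5),
                         resampling: ResamplingConfig | None = None,
                         progress: bool = False) -> ExperimentResult:
    """Empirical power of the chosen tests under one scenario and effect level."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    tests = _check_tests(tests)
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    gm = simulate_genotypes(n, L, maf_range, ld_rho, seed=np.random.default_rng(seed))
    G = gm.counts
    seeds = _rep_seeds(seed + 1, n_reps)
    pvals = {t: np.empty(n_reps) for t in tests}
    for r in range(n_reps):
        rng = np.random.default_rng(seeds[r])
        Y, E = simulate_phenotype(G, scenario, level, family, rng)
        for t in tests:
            pvals[t][r] = TEST_REGISTRY[t](Y, G, E, None, family, int(seeds[r]), resampling)
        if progress and (r + 1) % 100 == 0:
            logger.info("power experiment %s/%s: %d / %d replicates",
                        scenario.label, level, r + 1, n_reps)
    res = ExperimentResult("power", tests, family, n_reps, (alpha,), pvals, seed,
                           meta=dict(n=n, L=L, scenario=scenario.label, level=str(level),
                                     ld_rho=ld_rho))
    return res
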