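"""Two-stage set-based gene-environment interaction test (SBERIA).

Stage 1 screens the SNPs of a gene window with a filter that is asymptotically
independent of the interaction test: either the SNP main-effect association
with the trait (fit g[E(Y)] = g0 + gG * G_l + gX' X per SNP) or, for binary
exposures in case-control settings, the SNP-exposure association
(logit(E) = d0 + dG * G_l + dX' X).  Each SNP receives weight +1 or -1 (the
filter estimate's sign) when its filter p-value is below the threshold (0.10
by default) and a very small weight (0.0001) otherwise.

Stage 2 collapses the window into a single signed burden covariate
E * (G w_hat) and tests its coefficient in

    g[E(Y)] = a0 + aG' G + aE * E + aGE * E * (G' w_hat) + aX' X ,

a one-degree-of-freedom Wald test of H0: aGE = 0.  The asymptotic
independence of the two stages preserves the type-I error rate without any
data splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .glm_engine import (
    as_exposure,
    batch_glm,
    glm_fit,
    scale_exposure,
    standardize_trait,
    wald_pvalue,
    _covariate_array,
)

logger = logging.getLogger("gxeset")

DEFAULT_P_THRESHOLD = 0.10
DEFAULT_SMALL_WEIGHT = 0.0001


@dataclass
class FilterResult:
    """Per-SNP screening outcome and the burden weights it implies."""

    signs: np.ndarray
    pvalues: np.ndarray
    weights: np.ndarray
    strategy: str
    p_threshold: float = DEFAULT_P_THRESHOLD
    small_weight: float = DEFAULT_SMALL_WEIGHT
    degenerate: np.ndarray = field(default=None)


def _weights_from_filter(signs, pvalues, ok, p_threshold, small_weight):
    w = np.full(len(signs), small_weight)
    hit = ok & (pvalues < p_threshold)
    w[hit] = signs[hit]
    return w


def _single_covariate_filter(response, G, X, family, strategy,
                             p_threshold, small_weight) -> FilterResult:
    """Common core: per-SNP GLM of ``response`` on [1, G_l, X]."""
    from scipy import stats

    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, L = G.shape
    Xa = _covariate_array(X, n)
    c = Xa.shape[1]
    T = np.empty((L, n, 2 + c))
    T[:, :, 0] = 1.0
    T[:, :, 1] = G.T
    if c:
        T[:, :, 2:] = Xa[None, :, :]
    betas, covs, ok = batch_glm(np.asarray(response, float), T, family)
    ok = ok & (np.ptp(G, axis=0) > 0)
    est = betas[:, 1]
    se = np.sqrt(covs[:, 1, 1])
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(est / se))
    p = np.where(ok, p, 1.0)
    signs = np.where(ok, np.sign(est), 0.0)
    signs[signs == 0] = 1.0  # an exactly-zero estimate cannot pass the filter anyway
    weights = _weights_from_filter(signs, p, ok, p_threshold, small_weight)
    if (~ok).any():
        logger.debug("%d degenerate SNPs assigned the small filter weight", int((~ok).sum()))
    return FilterResult(signs, p, weights, strategy, p_threshold, small_weight,
                        degenerate=~ok)


def main_effect_filter(Y, G, X=None, family: str = "gaussian",
                       p_threshold: float = DEFAULT_P_THRESHOLD,
                       small_weight: float = DEFAULT_SMALL_WEIGHT) -> FilterResult:
    """Screen SNPs by their main-effect association with the trait.

    This is the filter of choice when the exposure is randomized (a
    SNP-exposure filter carries no signal there).
    """
    return _single_covariate_filter(np.asarray(Y, float), G, X, family,
                                    "main_effect", p_threshold, small_weight)


def snp_e_filter(E, G, X=None,
                 p_threshold: float = DEFAULT_P_THRESHOLD,
                 small_weight: float = DEFAULT_SMALL_WEIGHT) -> FilterResult:
    """Screen SNPs by their association with a binary exposure (logistic fit)."""
    ev = as_exposure(E)
    if ev.kind != "binary":
        raise ValueError("the SNP-E association filter requires a binary exposure")
    return _single_covariate_filter(ev.values, G, X, "binomial",
                                    "snp_e_association", p_threshold, small_weight)


def sberia_test(Y, G, E, X=None, family: str = "gaussian",
                filt: FilterResult | None = None) -> float:
    """Stage-2 weighted burden interaction test; returns the two-sided Wald p.

    The design contains the intercept, all L SNP main effects, E, the scalar
    burden covariate E * (G w_hat) and the covariates.  If the main-effect
    block is collinear it is ridge-stabilized with a tiny penalty
    (1e-6 * mean diagonal) on the G columns only.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, L = G.shape
    ev = scale_exposure(as_exposure(E))
    if family == "gaussian":
        Y = standardize_trait(Y)
    if filt is None:
        filt = main_effect_filter(Y, G, X, family)
    if len(filt.weights) != L:
        raise ValueError("filter was computed on a different SNP window")
    burden = ev.values * (G @ filt.weights)
    Xa = _covariate_array(X, n)
    D = np.column_stack([np.ones(n), G, ev.values, burden, Xa])
    burden_col = 1 + L + 1
    penalty = None
    # ridge-stabilize the main-effect block if the design is ill-conditioned
    gram = D.T @ D
    if np.linalg.matrix_rank(gram) < D.shape[1] or L >= n:
        penalty = np.zeros(D.shape[1])
        penalty[1:1 + L] = 1e-6 * np.trace(gram) / D.shape[1]
        logger.warning("collinear SNP main-effect block; ridge-stabilizing G columns")
    fit = glm_fit(Y, D, family, penalty=penalty)
    if not fit["converged"]:
        logger.warning("stage-2 GLM did not converge; p-value may be unreliable")
    beta = fit["beta"][burden_col]
    se = float(np.sqrt(fit["cov"][burden_col, burden_col]))
    return wald_pvalue(float(beta), se)
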