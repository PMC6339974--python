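"""Variance-component score test for SNP-by-exposure interaction.

The interaction coefficients of the L SNPs in a window are treated as random
effects with common variance tau2 in

    g[E(Y)] = d0 + dG' G + dE * E + dGE' S + dX' X ,   S = [E*G_1 ... E*G_L],

and H0: dGE = 0 reduces to the one-sided H0: tau2 = 0.  The score statistic
is the kernel quadratic form Q = || S' (Y - mu0) ||^2 evaluated at the null
fit (working residuals for the binomial family).  Under H0, Q is distributed
as a mixture of independent 1-df chi-squares whose weights are the
eigenvalues of the projected covariance of S'(Y - mu0); the p-value comes
from Liu's four-moment match by default, or from Imhof's exact numerical
inversion of the characteristic function.

SNP main effects under the null can be fixed (ordinary GLM fit) or
ridge-penalized with the penalty chosen by generalized cross-validation, the
two conventions used by the fixed-effect and ridge-based variants of this
test family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .glm_engine import (
    as_exposure,
    glm_fit,
    scale_exposure,
    standardize_trait,
    _covariate_array,
)

logger = logging.getLogger("gxeset")

RIDGE_GRID_POINTS = 25
RIDGE_GRID_RANGE = (1e-4, 1e4)  # multiplied by n


@dataclass
class InteractionDesign:
    """The n x L interaction design S = [E*G_1 ... E*G_L] plus the null design."""

    S: np.ndarray
    null_design: np.ndarray
    family: str


@dataclass
class VCTestResult:
    q_statistic: float
    p_value: float
    main_effect_mode: str
    ridge_lambda: float | None = None
    eigenvalues: np.ndarray | None = None


# ---------------------------------------------------------------------------
# mixture-of-chi-square tail probabilities
# ---------------------------------------------------------------------------

def liu_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Tail probability P(sum lambda_j chi2_1 > q) by Liu's moment matching."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    c1, c2, c3, c4 = (np.sum(lam ** k) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        delta = 0.0
        df = c2 ** 3 / c3 ** 2
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x, sigma_x = df + delta, np.sqrt(2 * (df + 2 * delta))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    t = max(t, 0.0)
    if delta > 0:
        return float(stats.ncx2.sf(t, df, delta))
    return float(stats.chi2.sf(t, df))


def imhof_pvalue(q: float, lambdas: np.ndarray, tol: float = 1e-9) -> float:
    """Exact tail probability by Imhof's numerical inversion."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, _ = integrate.quad(integrand, 0, np.inf, epsabs=tol, limit=2000)
    return float(min(max(0.5 + val / np.pi, 0.0), 1.0))


# ---------------------------------------------------------------------------
# the score test
# ---------------------------------------------------------------------------

def _gcv_ridge_lambda(Y, D, w, n_pen_first: int, n_pen_count: int) -> float:
    """Pick the ridge penalty on the SNP block by generalized cross-validation.

    Works on the weighted working regression at the current IRLS weights:
    GCV(lam) = n * RSS_w / (n - tr H_lam)^2 over a log grid spanning
    RIDGE_GRID_RANGE * n.
    """
    n, p = D.shape
    sw = np.sqrt(w)
    Dw = D * sw[:, None]
    yw = Y * sw
    gram = Dw.T @ Dw
    Dty = Dw.T @ yw
    best_lam, best_gcv = None, np.inf
    for lam in np.geomspace(RIDGE_GRID_RANGE[0] * n, RIDGE_GRID_RANGE[1] * n,
                            RIDGE_GRID_POINTS):
        pen = np.zeros(p)
        pen[n_pen_first:n_pen_first + n_pen_count] = lam
        try:
            A = np.linalg.solve(gram + np.diag(pen), np.column_stack([Dty, gram]))
        except np.linalg.LinAlgError:
            continue
        beta = A[:, 0]
        trH = float(np.trace(A[:, 1:]))
        resid = yw - Dw @ beta
        denom = max(n - trH, 1.0)
        gcv = n * float(resid @ resid) / denom ** 2
        if gcv < best_gcv:
            best_gcv, best_lam = gcv, lam
    if best_lam is None:
        best_lam = 1e-4 * n
        logger.warning("ridge GCV failed; falling back to lambda = 1e-4 * n")
    return float(best_lam)


def vc_score_test(Y, G, E, X=None, family: str = "gaussian",
                  main_effect_mode: str = "fixed",
                  method: str = "liu") -> VCTestResult:
    """Score test of H0: tau2 = 0 for the SNP-by-E variance component.

    ``main_effect_mode`` is ``"fixed"`` (SNP main effects as ordinary fixed
    effects in the null fit) or ``"ridge"`` (ridge-penalized with GCV-chosen
    penalty).  ``method`` selects the mixture-tail computation.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, L = G.shape
    if L == 0:
        raise ValueError("empty SNP window")
    ev = scale_exposure(as_exposure(E))
    if family == "gaussian":
        Y = standardize_trait(Y)
    Xa = _covariate_array(X, n)
    D = np.column_stack([np.ones(n), G, ev.values, Xa])
    S = G * ev.values[:, None]

    ridge_lambda = None
    penalty = None
    if main_effect_mode == "ridge":
        w0 = np.ones(n)
        if family == "binomial":
            w0 = glm_fit(Y, np.column_stack([np.ones(n), ev.values, Xa]), "binomial")["w"]
        ridge_lambda = _gcv_ridge_lambda(Y, D, w0, 1, L)
        penalty = np.zeros(D.shape[1])
        penalty[1:1 + L] = ridge_lambda
    elif main_effect_mode != "fixed":
        raise ValueError(f"unknown main_effect_mode {main_effect_mode!r}")

    fit = glm_fit(Y, D, family, penalty=penalty)
    resid = Y - fit["mu"]
    score = S.T @ resid
    q = float(score @ score)

    # covariance of S'(Y - mu0): sandwich around the (possibly penalized) hat.
    # With working weights w (ones for gaussian), C0 = (D'WD + P)^-1 and
    # B = S'WD:  M = scale * [S'WS - 2 B C0 B' + B C0 (D'WD) C0 B'],
    # scale = sigma2 for gaussian (Var(Y) = sigma2 I), 1 for binomial
    # (Var(Y) = W).  Unpenalized, this collapses to the usual projection
    # S'(W - WD(D'WD)^-1 D'W)S.
    w = np.ones(n) if family == "gaussian" else fit["w"]
    scale = fit["sigma2"] if family == "gaussian" else 1.0
    pen0 = np.zeros(D.shape[1]) if penalty is None else penalty
    if family == "binomial":
        # leverage correction: fitted mu(1-mu) under-estimates the variance by
        # roughly (1 - h_i) with many fitted main effects -- the binomial
        # analogue of the gaussian n - p denominator (HC2-style)
        Dw0 = D * w[:, None]
        Cw = np.linalg.inv(D.T @ Dw0 + np.diag(pen0))
        h = np.einsum("np,pq,nq->n", D, Cw, Dw0, optimize=True)
        w = w / np.clip(1.0 - h, 0.5, None)
    SwS = S.T @ (S * w[:, None])
    B = S.T @ (D * w[:, None])
    DwD = D.T @ (D * w[:, None])
    pen = np.zeros(D.shape[1]) if penalty is None else penalty
    C0 = np.linalg.inv(DwD + np.diag(pen))
    BC = B @ C0
    M = scale * (SwS - BC @ B.T - B @ BC.T + BC @ DwD @ BC.T)
    M = 0.5 * (M + M.T)
    lam = np.linalg.eigvalsh(M)
    lam = lam[lam > 1e-12 * max(lam.max(), 1e-300)]
    if lam.size == 0:
        raise ValueError("degenerate interaction design: no positive eigenvalues")
    if method == "liu":
        p = liu_pvalue(q, lam)
    elif method == "imhof":
        p = imhof_pvalue(q, lam)
    else:
        raise ValueError(f"unknown method {method!r}")
    return VCTestResult(q, p, main_effect_mode, ridge_lambda, lam)
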