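"""Per-SNP generalized linear model machinery shared by every gene-based test.

Each set-based gene-environment interaction (G-by-E) test starts from the same
single-SNP model

    g[E(Y)] = b0 + bG * G_l + bE * E + bGE * G_l * E + bX' X ,

fitted with an identity link for continuous traits and a logit link for binary
traits.  The quantity of interest is the interaction MLE ``bGE_hat`` together
with its estimated variance; Wald inference uses the standard normal reference.

The fitting core is written as batched linear algebra (one closed-form weighted
least-squares / IRLS pass over all L SNPs of a gene window at once) because the
simulation framework evaluates hundreds of thousands of these small fits; the
single-SNP entry point :func:`fit_interaction_glm` wraps the same code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger("gxeset")

# IRLS controls for the binomial family (coefficient-change tolerance / cap)
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100

FAMILIES = ("gaussian", "binomial")


class DegenerateInputError(ValueError):
    """Raised for inputs that make a model undefined (constant exposure etc.)."""


# ---------------------------------------------------------------------------
# exposure scaling and trait standardization
# ---------------------------------------------------------------------------

@dataclass
class ExposureVector:
    """A per-sample environmental exposure.

    ``kind`` is ``"binary"`` or ``"continuous"``; after scaling every value
    lies in [0, 1] (binary exposures are exactly {0, 1}).
    """

    values: np.ndarray
    kind: str = "continuous"
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown exposure kind {self.kind!r}")


def as_exposure(E) -> ExposureVector:
    """Coerce an array-like into an :class:`ExposureVector`, sniffing binarity."""
    if isinstance(E, ExposureVector):
        return E
    arr = np.asarray(E, dtype=float)
    uniq = np.unique(arr)
    kind = "binary" if uniq.size <= 2 and np.isin(uniq, (0.0, 1.0)).all() else "continuous"
    return ExposureVector(arr, kind=kind, scaled=(kind == "binary"))


def scale_exposure(E) -> ExposureVector:
    """Scale an exposure to [0, 1]: E' = (E - Emin) / (Emax - Emin).

    A dichotomous exposure already coded {0, 1} passes through unchanged.
    Scaling puts G_l * E on the same 0..2 range as the allele count G_l, so
    that one interaction-effect prior is sensible for any exposure.
    """
    ev = as_exposure(E)
    vals = ev.values
    lo, hi = np.min(vals), np.max(vals)
    if hi == lo:
        raise DegenerateInputError("exposure is constant; cannot scale to [0, 1]")
    if ev.kind == "binary":
        return ExposureVector(vals, kind="binary", scaled=True)
    return ExposureVector((vals - lo) / (hi - lo), kind="continuous", scaled=True)


def standardize_trait(Y) -> np.ndarray:
    """Standardize a continuous trait to sample mean 0 and sd 1 (n-1 denominator)."""
    arr = np.asarray(Y, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("trait has zero variance; cannot standardize")
    return (arr - arr.mean()) / sd


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

@dataclass
class CovariateSet:
    """Confounder covariates X (age, sex, BMI, principal components, ...)."""

    matrix: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.ndim != 2:
            raise ValueError("covariate matrix must be 2-D (n samples x c columns)")
        if not self.names:
            self.names = [f"x{j + 1}" for j in range(self.matrix.shape[1])]
        if np.any(np.ptp(self.matrix, axis=0) == 0):
            j = int(np.flatnonzero(np.ptp(self.matrix, axis=0) == 0)[0])
            raise ValueError(
                f"covariate column {self.names[j]!r} is constant; the intercept "
                "is added automatically"
            )
        full = np.column_stack([np.ones(len(self.matrix)), self.matrix])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise ValueError("covariate matrix is rank deficient after adding intercept")


def _covariate_array(X, n: int) -> np.ndarray:
    if X is None:
        return np.empty((n, 0))
    if isinstance(X, CovariateSet):
        return X.matrix
    return np.atleast_2d(np.asarray(X, dtype=float)).reshape(n, -1)


# ---------------------------------------------------------------------------
# fitting cores
# ---------------------------------------------------------------------------

def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glm_fit(Y: np.ndarray, D: np.ndarray, family: str, penalty: np.ndarray | None = None):
    """Fit a single GLM ``g[E(Y)] = D beta`` and return a result dict.

    ``penalty`` is an optional per-coefficient ridge diagonal (added to D'WD
    when solving; the reported covariance is the sandwich-free inverse of the
    penalized information, adequate for the score constructions that use it).
    Returns dict with beta, cov, mu, w (working weights), converged, df_resid.
    """
    Y = np.asarray(Y, dtype=float)
    D = np.asarray(D, dtype=float)
    n, p = D.shape
    pen = np.zeros(p) if penalty is None else np.asarray(penalty, dtype=float)
    if family == "gaussian":
        XtX = D.T @ D + np.diag(pen)
        beta = np.linalg.solve(XtX, D.T @ Y)
        mu = D @ beta
        resid = Y - mu
        df = n - p if penalty is None else n - np.trace(np.linalg.solve(XtX, D.T @ D))
        sigma2 = float(resid @ resid) / max(df, 1.0)
        cov = sigma2 * np.linalg.inv(XtX)
        return dict(beta=beta, cov=cov, mu=mu, w=np.ones(n), converged=True,
                    df_resid=df, sigma2=sigma2)
    if family != "binomial":
        raise ValueError(f"unknown family {family!r}")
    beta = np.zeros(p)
    ybar = min(max(Y.mean(), 1e-6), 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))
    converged = False
    for _ in range(IRLS_MAX_ITER):
        eta = D @ beta
        mu = _sigmoid(eta)
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (Y - mu) / w
        Dw = D * w[:, None]
        XtWX = D.T @ Dw + np.diag(pen)
        new = np.linalg.solve(XtWX, Dw.T @ z)
        step = np.max(np.abs(new - beta))
        beta = new
        if step < IRLS_TOL:
            converged = True
            break
    eta = D @ beta
    mu = _sigmoid(eta)
    w = np.maximum(mu * (1 - mu), 1e-12)
    XtWX = D.T @ (D * w[:, None]) + np.diag(pen)
    cov = np.linalg.inv(XtWX)
    return dict(beta=beta, cov=cov, mu=mu, w=w, converged=converged,
                df_resid=n - p, sigma2=1.0)


def batch_glm(Y: np.ndarray, designs: np.ndarray, family: str):
    """Fit the same-shape GLM for a batch of designs.

    ``designs`` has shape (L, n, p); returns (beta (L, p), cov (L, p, p),
    converged (L,)).  Singular designs (e.g. a monomorphic SNP) are flagged
    non-converged with NaN coefficients rather than raising.
    """
    Y = np.asarray(Y, dtype=float)
    T = np.asarray(designs, dtype=float)
    L, n, p = T.shape
    betas = np.full((L, p), np.nan)
    covs = np.full((L, p, p), np.nan)
    ok = np.zeros(L, dtype=bool)

    def _safe_solve(A, b):
        """Batched solve of A[i] x = b[i]; returns solution and validity mask."""
        sol = np.full_like(b, np.nan)
        good = np.ones(A.shape[0], dtype=bool)
        try:
            sol = np.linalg.solve(A, b[..., None])[..., 0]
            good = np.isfinite(sol).all(axis=-1)
        except np.linalg.LinAlgError:
            for i in range(A.shape[0]):
                try:
                    sol[i] = np.linalg.solve(A[i], b[i])
                    good[i] = np.isfinite(sol[i]).all()
                except np.linalg.LinAlgError:
                    good[i] = False
        return sol, good

    if family == "gaussian":
        XtX = np.einsum("lnp,lnq->lpq", T, T, optimize=True)
        XtY = np.einsum("lnp,n->lp", T, Y, optimize=True)
        # guard near-singular batches: perturb diagnosis via solve failure
        beta, good = _safe_solve(XtX, XtY)
        mu = np.einsum("lnp,lp->ln", T, beta, optimize=True)
        resid = Y[None, :] - mu
        rss = np.einsum("ln,ln->l", resid, resid, optimize=True)
        sigma2 = rss / max(n - p, 1)
        with np.errstate(all="ignore"):
            try:
                inv = np.linalg.inv(XtX)
            except np.linalg.LinAlgError:
                inv = np.full_like(XtX, np.nan)
                for i in np.flatnonzero(good):
                    try:
                        inv[i] = np.linalg.inv(XtX[i])
                    except np.linalg.LinAlgError:
                        good[i] = False
            cov = sigma2[:, None, None] * inv
        # a numerically singular XtX can pass solve but give absurd variances
        diag = np.einsum("lpp->lp", cov)
        good &= np.isfinite(diag).all(axis=1) & (diag > 0).all(axis=1)
        betas[good], covs[good], ok[good] = beta[good], cov[good], True
        return betas, covs, ok

    if family != "binomial":
        raise ValueError(f"unknown family {family!r}")

    beta = np.zeros((L, p))
    ybar = min(max(Y.mean(), 1e-6), 1 - 1e-6)
    beta[:, 0] = np.log(ybar / (1 - ybar))
    active = np.ones(L, dtype=bool)
    conv = np.zeros(L, dtype=bool)
    for _ in range(IRLS_MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ti = T[idx]
        eta = np.einsum("lnp,lp->ln", Ti, beta[idx], optimize=True)
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        z = eta + (Y[None, :] - mu) / w
        Tw = Ti * w[:, :, None]
        XtWX = np.einsum("lnp,lnq->lpq", Tw, Ti, optimize=True)
        XtWz = np.einsum("lnp,ln->lp", Tw, z, optimize=True)
        new, good = _safe_solve(XtWX, XtWz)
        bad = idx[~good]
        active[bad] = False  # singular: leave non-converged
        goodidx = idx[good]
        step = np.max(np.abs(new[good] - beta[goodidx]), axis=1)
        beta[goodidx] = new[good]
        done = goodidx[step < IRLS_TOL]
        conv[done] = True
        active[done] = False
        # runaway coefficients indicate separation; flag and stop iterating
        sep = goodidx[np.max(np.abs(new[good]), axis=1) > 1e3]
        conv[sep] = False
        active[sep] = False
    idx = np.flatnonzero(conv)
    if idx.size:
        Ti = T[idx]
        eta = np.einsum("lnp,lp->ln", Ti, beta[idx], optimize=True)
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        XtWX = np.einsum("lnp,lnq->lpq", Ti * w[:, :, None], Ti, optimize=True)
        try:
            inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            inv = np.full_like(XtWX, np.nan)
            for j, i in enumerate(idx):
                try:
                    inv[j] = np.linalg.inv(XtWX[j])
                except np.linalg.LinAlgError:
                    conv[i] = False
        diag = np.einsum("lpp->lp", inv)
        keep = np.isfinite(diag).all(axis=1) & (diag > 0).all(axis=1)
        conv[idx[~keep]] = False
        idx = idx[keep]
        betas[idx] = beta[idx]
        covs[idx] = inv[keep]
        ok[idx] = True
    return betas, covs, ok


# ---------------------------------------------------------------------------
# interaction fits
# ---------------------------------------------------------------------------

@dataclass
class InteractionEstimate:
    """MLE of the G-by-E coefficient for one SNP with Wald inference."""

    beta_hat: float
    v_hat: float
    se: float
    wald: float
    p: float
    converged: bool = True


def interaction_designs(G: np.ndarray, E: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Stack the per-SNP designs [1, G_l, E, G_l*E, X] into an (L, n, p) tensor."""
    n, L = G.shape
    c = X.shape[1]
    T = np.empty((L, n, 4 + c))
    T[:, :, 0] = 1.0
    T[:, :, 1] = G.T
    T[:, :, 2] = E[None, :]
    T[:, :, 3] = (G * E[:, None]).T
    if c:
        T[:, :, 4:] = X[None, :, :]
    return T


def batch_interaction_fits(Y, G, E, X, family: str):
    """Interaction-coefficient fits for every SNP column of ``G``.

    Returns (beta_hat (L,), v_hat (L,), converged (L,)).  Degenerate SNPs
    (constant columns) are flagged non-converged.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    E = np.asarray(E, dtype=float)
    Xa = _covariate_array(X, len(Y))
    T = interaction_designs(G, E, Xa)
    betas, covs, ok = batch_glm(Y, T, family)
    ok = ok & (np.ptp(G, axis=0) > 0)
    beta_hat = np.where(ok, betas[:, 3], np.nan)
    v_hat = np.where(ok, covs[:, 3, 3], np.nan)
    return beta_hat, v_hat, ok


def fit_interaction_glm(Y, g_l, E, X=None, family: str = "gaussian") -> InteractionEstimate:
    """Fit the single-SNP interaction GLM and return the G-by-E estimate.

    The design is [intercept, G, E, G*E, covariates]; the returned p-value is
    the two-sided normal Wald p for H0: bGE = 0.
    """
    g = np.asarray(g_l, dtype=float)
    if np.ptp(g) == 0:
        raise DegenerateInputError("SNP genotype column is constant")
    E = as_exposure(E).values
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family == "binomial":
        yy = np.asarray(Y, dtype=float)
        if not np.isin(np.unique(yy), (0.0, 1.0)).all():
            raise ValueError("binomial family requires Y in {0, 1}")
    beta, v, ok = batch_interaction_fits(np.asarray(Y, float), g[:, None], E, X, family)
    if not ok[0]:
        # collinearity vs plain non-convergence: identify the offending column
        Xa = _covariate_array(X, len(g))
        D = interaction_designs(g[:, None], E, Xa)[0]
        if np.linalg.matrix_rank(D) < D.shape[1]:
            names = ["intercept", "G", "E", "G:E"] + [f"x{j+1}" for j in range(Xa.shape[1])]
            for j in range(D.shape[1]):
                others = np.delete(D, j, axis=1)
                if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(D):
                    raise ValueError(f"collinear design: column {names[j]!r} is redundant")
        return InteractionEstimate(np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)
    se = float(np.sqrt(v[0]))
    wald = float(beta[0]) / se
    return InteractionEstimate(float(beta[0]), float(v[0]), se, wald,
                               wald_pvalue(float(beta[0]), se), converged=True)


def wald_pvalue(beta: float, se: float) -> float:
    """Two-sided normal p-value, p = 2 * Phi(-|beta / se|)."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * stats.norm.sf(abs(beta / se)))
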