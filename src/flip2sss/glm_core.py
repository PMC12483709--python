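"""Generalized linear model fitting by IRLS, with Firth bias-reduced logistic regression.

Supports the three canonical family/link pairs needed by the score machinery:
gaussian/identity, binomial/logit and poisson/log.  The fits expose the
quantities the sign-flip score test consumes: fitted means, IRLS weights and
working residuals.  Rank-deficient designs are handled by pivoted-QR column
dropping so that tiny per-cluster fits never raise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "GlmSpec",
    "GlmFit",
    "fit_glm",
    "fit_firth_logistic",
    "score_components",
    "log_likelihood",
    "firth_penalized_loglik",
]

FAMILIES = ("gaussian", "binomial", "poisson")
#: canonical link for each family
CANONICAL_LINKS = {"gaussian": "identity", "binomial": "logit", "poisson": "log"}
#: |eta| beyond which a binomial ML fit is considered to be diverging
SEPARATION_ETA = 15.0
#: relative pivot tolerance for aliased-column detection
ALIAS_RTOL = 1e-10


@dataclass
class GlmSpec:
    """A GLM fitting problem: family, design matrix and response.

    Only canonical links are supported, so ``link`` is implied by ``family``.
    ``offset`` enters the linear predictor additively and defaults to zero.
    """

    family: str
    design: np.ndarray
    response: np.ndarray
    offset: np.ndarray | None = None
    max_iter: int = 100
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; use one of {FAMILIES}")
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        self.response = np.asarray(self.response, dtype=float).ravel()
        n = self.response.shape[0]
        if self.design.shape[0] != n:
            raise ValueError("design and response have incompatible shapes")
        if self.offset is None:
            self.offset = np.zeros(n)
        else:
            self.offset = np.asarray(self.offset, dtype=float).ravel()
            if self.offset.shape[0] != n:
                raise ValueError("offset length must match response")
        if self.family == "binomial" and not np.all(np.isin(self.response, (0.0, 1.0))):
            raise ValueError("binomial response must be coded 0/1")
        if self.family == "poisson" and (
            np.any(self.response < 0) or np.any(self.response != np.round(self.response))
        ):
            raise ValueError("poisson response must be non-negative integers")

    @property
    def link(self) -> str:
        return CANONICAL_LINKS[self.family]


@dataclass
class GlmFit:
    """Result of an IRLS fit.

    ``coefficients`` has one entry per design column; aliased (dropped) columns
    carry NaN and are listed in ``dropped``.  ``irls_weights`` is the diagonal
    of W = (dmu/deta)^2 / V(mu), which for canonical links equals V(mu).
    """

    coefficients: np.ndarray
    fitted_mean: np.ndarray
    irls_weights: np.ndarray
    linear_predictor: np.ndarray
    converged: bool
    n_iter: int
    separation_flag: bool = False
    dispersion_estimate: float = 1.0
    dropped: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    method: str = "ml"


def _variance(family: str, mu: np.ndarray) -> np.ndarray:
    if family == "gaussian":
        return np.ones_like(mu)
    if family == "binomial":
        return mu * (1.0 - mu)
    return mu  # poisson


def _inverse_link(family: str, eta: np.ndarray) -> np.ndarray:
    if family == "gaussian":
        return eta
    if family == "binomial":
        return expit(eta)
    return np.exp(np.clip(eta, -700, 700))


def _link(family: str, mu: np.ndarray) -> np.ndarray:
    if family == "gaussian":
        return mu
    if family == "binomial":
        return np.log(mu) - np.log1p(-mu)
    return np.log(mu)


def _initial_mu(family: str, y: np.ndarray) -> np.ndarray:
    # safe starts: keep binomial strictly inside (0,1), poisson positive
    if family == "binomial":
        return (y + 0.5) / 2.0
    if family == "poisson":
        return y + 0.5
    return y.copy()


def detect_aliased(design: np.ndarray, rtol: float = ALIAS_RTOL) -> tuple[np.ndarray, np.ndarray]:
    """Return (kept, dropped) column indices of ``design``.

    Sequential (order-preferring) rank detection: a column is dropped when its
    residual after projection on the previously kept columns falls below
    ``rtol`` times its own norm.  Earlier columns win ties, so an intercept is
    never sacrificed for a constant covariate — the convention the stage-2
    masking relies on.
    """
    n, q = design.shape
    if q == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    kept: list[int] = []
    dropped: list[int] = []
    basis: list[np.ndarray] = []
    for j in range(q):
        v = np.array(design[:, j], dtype=float)
        nrm0 = np.linalg.norm(v)
        if nrm0 == 0.0:
            dropped.append(j)
            continue
        for _ in range(2):  # modified Gram-Schmidt with one re-orthogonalization
            for u in basis:
                v -= (u @ v) * u
        nrm = np.linalg.norm(v)
        if nrm > rtol * nrm0:
            kept.append(j)
            basis.append(v / nrm)
        else:
            dropped.append(j)
    return np.asarray(kept, dtype=int), np.asarray(dropped, dtype=int)


def log_likelihood(spec: GlmSpec, beta: np.ndarray) -> float:
    """Log-likelihood at ``beta`` (unit dispersion for the gaussian family).

    Dropped-column sentinels (NaN) in ``beta`` are treated as zero.
    """
    b = np.nan_to_num(np.asarray(beta, dtype=float))
    eta = spec.design @ b + spec.offset
    y = spec.response
    if spec.family == "gaussian":
        return float(-0.5 * np.sum((y - eta) ** 2))
    if spec.family == "binomial":
        # y*eta - log(1+exp(eta)), stable via logaddexp
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    from scipy.special import gammaln

    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def _irls(spec: GlmSpec, X: np.ndarray, firth: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, int, bool]:
    """Run (possibly Firth-adjusted) IRLS on a full-rank design ``X``."""
    y, offset, fam = spec.response, spec.offset, spec.family
    n, q = X.shape
    mu = _initial_mu(fam, y)
    eta = _link(fam, mu)
    beta = np.zeros(q)
    max_iter = spec.max_iter
    converged = False
    separated = False
    it = 0
    prev_step = None
    for it in range(1, max_iter + 1):
        w = _variance(fam, mu)
        if fam != "gaussian":
            w = np.maximum(w, 1e-12)
        Xw = X * w[:, None]
        M = X.T @ Xw
        adj = y - mu
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            Minv = np.linalg.pinv(M)
        if firth:
            # hat diagonal of the weighted design; Firth's modified score adds
            # h_i * (1/2 - mu_i) to each working residual
            h = w * np.einsum("ij,jk,ik->i", X, Minv, X)
            adj = adj + h * (0.5 - mu)
        # working-response form: z = eta - offset + adj/w, solve the WLS normal
        # equations X'WX beta = X'W(eta - offset) + X'adj
        beta_new = Minv @ (Xw.T @ (eta - offset) + X.T @ adj)
        # dampen wild steps and the two-cycle oscillation Fisher scoring shows
        # on near-saturated Firth fits (step direction reversing each iteration)
        step = beta_new - beta
        if firth:
            if prev_step is not None and float(step @ prev_step) < 0.0:
                step = 0.5 * step
            smax = float(np.abs(step).max()) if q else 0.0
            if smax > 5.0:
                step = step * (5.0 / smax)
                smax = 5.0
            prev_step = step
            beta_new = beta + step
        else:
            smax = float(np.abs(step).max()) if q else 0.0
        eta = X @ beta_new + offset
        mu = _inverse_link(fam, eta)
        if fam == "binomial":
            np.clip(mu, 1e-12, 1.0 - 1e-12, out=mu)
        beta = beta_new
        if fam == "binomial" and not firth and float(np.abs(eta).max()) > SEPARATION_ETA:
            separated = True
            break  # monotone likelihood: stop rather than chase infinity
        if smax < spec.tol:
            converged = True
            break
        if fam == "gaussian":
            converged = True  # identity link: one weighted LS solve is exact
            break
    return beta, mu, eta, converged, it, separated


def batched_logistic(
    Xp: np.ndarray,
    yp: np.ndarray,
    real: np.ndarray,
    *,
    firth: bool,
    max_iter: int,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit many small logistic (optionally Firth) models in one vectorized IRLS.

    ``Xp`` is (N, m, q) with clusters padded to a common length m by all-zero
    rows, ``yp`` (N, m) the responses and ``real`` (N, m) the padding mask.
    Zero design rows contribute nothing to any normal-equation product, so
    padding is inert.  Every cluster design must have full column rank q.
    Returns (beta (N,q), converged (N,), n_iter (N,), separated (N,)); the
    iteration, damping and stopping rules match the scalar :func:`fit_glm`.
    """
    N, m, q = Xp.shape
    y = np.where(real, yp, 0.0)
    mu = np.where(real, (y + 0.5) / 2.0, 0.5)
    eta = np.log(mu) - np.log1p(-mu)
    beta = np.zeros((N, q))
    prev_step = np.zeros((N, q))
    have_prev = False
    active = np.ones(N, dtype=bool)
    converged = np.zeros(N, dtype=bool)
    separated = np.zeros(N, dtype=bool)
    n_iter = np.zeros(N, dtype=int)
    eye = np.eye(q)
    for it in range(1, max_iter + 1):
        if not active.any():
            break
        w = np.where(real, np.maximum(mu * (1.0 - mu), 1e-12), 0.0)
        Xw = Xp * w[..., None]
        M = np.einsum("nij,nik->njk", Xw, Xp)
        M[~active] = eye  # frozen clusters: keep the batched inverse well posed
        Minv = np.linalg.inv(M)
        adj = y - mu
        if firth:
            h = np.einsum("nij,njk,nik->ni", Xp, Minv, Xw)
            adj = adj + h * (0.5 - mu)
        adj = np.where(real, adj, 0.0)
        rhs = np.einsum("nij,ni->nj", Xp, w * eta + adj)
        beta_new = np.einsum("njk,nk->nj", Minv, rhs)
        step = beta_new - beta
        if firth:
            if have_prev:
                flip = np.einsum("nj,nj->n", step, prev_step) < 0.0
                step[flip] *= 0.5
            smax = np.abs(step).max(axis=1)
            big = smax > 5.0
            if big.any():
                step[big] *= (5.0 / smax[big])[:, None]
                smax = np.minimum(smax, 5.0)
            prev_step = step
            have_prev = True
        else:
            smax = np.abs(step).max(axis=1)
        beta = np.where(active[:, None], beta + step, beta)
        eta = np.einsum("nij,nj->ni", Xp, beta)
        mu = expit(eta)
        np.clip(mu, 1e-12, 1.0 - 1e-12, out=mu)
        n_iter[active] = it
        newsep = np.zeros(N, dtype=bool)
        if not firth:
            etamax = np.where(real, np.abs(eta), 0.0).max(axis=1)
            newsep = active & (etamax > SEPARATION_ETA)
            separated |= newsep
        newconv = active & ~newsep & (smax < tol)
        converged |= newconv
        active &= ~(newsep | newconv)
    return beta, converged, n_iter, separated


def fit_glm(spec: GlmSpec, *, firth: bool = False) -> GlmFit:
    """Maximum-likelihood GLM fit by IRLS (or Firth-penalized if ``firth``).

    Aliased design columns are detected by pivoted QR and dropped; their
    coefficients are reported as NaN.  For binomial ML fits a separation flag
    is raised (and iteration stopped) once the linear predictor exceeds
    ``SEPARATION_ETA`` in absolute value.
    """
    kept, dropped = detect_aliased(spec.design)
    n, q = spec.design.shape
    X = spec.design[:, kept]
    if X.shape[1] == 0:
        mu = _inverse_link(spec.family, spec.offset)
        if spec.family == "binomial":
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return GlmFit(
            coefficients=np.full(q, np.nan),
            fitted_mean=mu,
            irls_weights=_variance(spec.family, mu),
            linear_predictor=spec.offset.copy(),
            converged=True,
            n_iter=0,
            dropped=dropped,
            method="firth" if firth else "ml",
        )
    beta_k, mu, eta, converged, n_iter, separated = _irls(spec, X, firth)
    if firth and spec.family == "binomial":
        # report whether plain ML would have separated
        _, _, _, _, _, sep_ml = _irls(spec, X, firth=False)
        separated = sep_ml
    coefficients = np.full(q, np.nan)
    coefficients[kept] = beta_k
    w = _variance(spec.family, mu)
    dispersion = 1.0
    if spec.family == "gaussian":
        resid_df = max(n - kept.size, 1)
        dispersion = float(np.sum((spec.response - mu) ** 2) / resid_df)
    return GlmFit(
        coefficients=coefficients,
        fitted_mean=mu,
        irls_weights=w,
        linear_predictor=eta,
        converged=converged,
        n_iter=n_iter,
        separation_flag=separated,
        dispersion_estimate=dispersion,
        dropped=dropped,
        method="firth" if firth else "ml",
    )


def fit_firth_logistic(spec: GlmSpec) -> GlmFit:
    """Firth bias-reduced logistic regression.

    Solves the modified score equations X'(y - mu + h*(1/2 - mu)) = 0, where h
    is the hat diagonal of the IRLS-weighted design — equivalently maximizes
    the Jeffreys-prior penalized log-likelihood.  Estimates stay finite under
    complete separation; ``separation_flag`` still reports whether plain ML
    would diverge.
    """
    if spec.family != "binomial":
        raise ValueError("Firth correction is implemented for binomial/logit only")
    if spec.max_iter == 100:  # bump the default: Firth converges slower near separation
        spec = GlmSpec(
            family=spec.family,
            design=spec.design,
            response=spec.response,
            offset=spec.offset,
            max_iter=200,
            tol=spec.tol,
        )
    return fit_glm(spec, firth=True)


def firth_penalized_loglik(spec: GlmSpec, beta: np.ndarray) -> float:
    """Jeffreys-penalized binomial log-likelihood l(beta) + 0.5*logdet(X'WX)."""
    b = np.nan_to_num(np.asarray(beta, dtype=float))
    kept, _ = detect_aliased(spec.design)
    X = spec.design[:, kept]
    eta = spec.design @ b + spec.offset
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-300, None)
    sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    if sign <= 0:
        return -np.inf
    return log_likelihood(spec, b) + 0.5 * logdet


def score_components(fit: GlmFit, spec: GlmSpec) -> tuple[np.ndarray, np.ndarray]:
    """Raw residuals ``y - mu`` and IRLS weight diagonal of a fit."""
    resid = spec.response - fit.fitted_mean
    return resid, fit.irls_weights.copy()


def check_canonical_score(fit: GlmFit, spec: GlmSpec, rtol_n: float | None = None) -> float:
    """Max |X'(y - mu)| over estimable columns; near zero at a canonical-link MLE."""
    kept = np.setdiff1d(np.arange(spec.design.shape[1]), fit.dropped)
    if kept.size == 0:
        return 0.0
    score = spec.design[:, kept].T @ (spec.response - fit.fitted_mean)
    val = float(np.max(np.abs(score)))
    if rtol_n is not None and val > rtol_n * spec.response.size:
        warnings.warn("score equations not satisfied to tolerance", stacklevel=2)
    return val
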