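"""SNP-BLUP association testing on (tag)SNP predictors.

The model is y = X beta + e with y and the columns of X centered within
family and scaled to unit variance, beta random with common variance
sigma2_beta and e ~ N(0, sigma2_e I).  The ridge estimate

    beta_hat = (X'X + lambda I)^{-1} X'y,   lambda = sigma2_e / sigma2_beta

is the BLUP of beta; lambda is estimated by restricted maximum likelihood
(a 1-D profile search on the eigendecomposition of X'X, which shares its
stationary point with AI-REML).  Effects are screened with a t-like
statistic T_k = beta_hat_k / SD(beta_hat_k) against standard-normal
quantiles, and QTL detection is summarized as an ROC over the type-I
level alpha with a cM window around each true QTL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize_scalar
from scipy.stats import norm

LAMBDA_BOUNDS = (1e-6, 1e9)


@dataclass
class RidgeFit:
    beta_hat: np.ndarray
    lam: float
    sigma2_e: float
    sd_beta: np.ndarray
    T: np.ndarray | None = None


def ridge_solve(
    X: np.ndarray, y: np.ndarray, lam: float, sd_method: str = "pev"
) -> RidgeFit:
    """Solve (X'X + lambda I) beta = X'y by a symmetric (Cholesky) solve.

    The residual variance uses the effective model dimension
    df = trace(X (X'X + lambda I)^{-1} X'); standard deviations of the
    estimates come from the prediction-error form
    sd_k = sqrt(sigma2_e [(X'X + lambda I)^{-1}]_kk) (``sd_method="pev"``,
    the form mixed-model software reports) or from the sandwich
    sigma2_e [(C^{-1} X'X C^{-1}]_kk (``sd_method="sandwich"``, exact
    sampling variance of beta_hat for fixed lambda under pure noise).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, tau = X.shape
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    XtX = X.T @ X
    C = XtX + lam * np.eye(tau)
    try:
        cho = sla.cho_factor(C)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises LinAlgError
        raise np.linalg.LinAlgError(
            "normal equations singular; use lambda > 0 for a rank-deficient design"
        ) from exc
    if lam == 0 and np.linalg.matrix_rank(XtX) < tau:
        raise np.linalg.LinAlgError(
            "design is rank deficient at lambda = 0; choose lambda > 0"
        )
    beta = sla.cho_solve(cho, X.T @ y)
    Cinv = sla.cho_solve(cho, np.eye(tau))
    df = tau - lam * float(np.trace(Cinv))
    resid = y - X @ beta
    denom = max(n - df, 1.0)
    sigma2_e = float(resid @ resid) / denom
    if sd_method == "pev":
        var = sigma2_e * np.diag(Cinv)
    elif sd_method == "sandwich":
        var = sigma2_e * np.diag(Cinv @ XtX @ Cinv)
    else:
        raise ValueError(f"unknown sd_method {sd_method!r}")
    sd = np.sqrt(np.maximum(var, 0.0))
    return RidgeFit(beta_hat=beta, lam=float(lam), sigma2_e=sigma2_e, sd_beta=sd)


def _reml_neg2logl(log_lam: float, s: np.ndarray, yty: float, u2: np.ndarray, n: int) -> float:
    lam = np.exp(log_lam)
    w = s / lam + 1.0
    quad = float(np.sum(u2 / w)) + (yty - float(np.sum(u2)))
    sigma2 = quad / n
    if sigma2 <= 0 or not np.isfinite(sigma2):
        return np.inf
    return float(np.sum(np.log(w))) + n * np.log(sigma2)


def estimate_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """REML estimate of the shrinkage lambda = sigma2_e / sigma2_beta.

    Profiles the restricted likelihood of y ~ N(0, sigma2_beta XX' +
    sigma2_e I) over log lambda on the eigendecomposition of X'X (with no
    fixed effects beyond the within-family centering already applied, the
    restricted and full likelihoods coincide).  The search is a bounded
    1-D minimization with tolerance 1e-6 in log lambda; pure-noise
    responses drive lambda to the upper search bound.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    yty = float(y @ y)
    if yty <= 0 or not np.isfinite(yty):
        raise ValueError("degenerate response: REML likelihood undefined")
    s, Q = np.linalg.eigh(X.T @ X)
    s = np.maximum(s, 0.0)
    # scores of y on the left singular vectors of X
    Xty = X.T @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        u2 = np.where(s > 1e-10, (Q.T @ Xty) ** 2 / np.where(s > 1e-10, s, 1.0), 0.0)
    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    res = minimize_scalar(
        _reml_neg2logl,
        bounds=(lo, hi),
        args=(s, yty, u2, n),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not np.isfinite(res.fun):
        raise ValueError("non-finite REML objective")
    return float(np.exp(res.x))


def reml_neg2logl(X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """-2 profile REML log-likelihood at a given lambda (for diagnostics)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    s = np.maximum(np.linalg.eigh(X.T @ X)[0], 0.0)
    Q = np.linalg.eigh(X.T @ X)[1]
    Xty = X.T @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        u2 = np.where(s > 1e-10, (Q.T @ Xty) ** 2 / np.where(s > 1e-10, s, 1.0), 0.0)
    return _reml_neg2logl(np.log(lam), s, float(y @ y), u2, y.size)


def fit_snp_blup(
    X: np.ndarray, y: np.ndarray, lam: float | None = None, sd_method: str = "pev"
) -> RidgeFit:
    """Estimate lambda by REML (unless given) and fit the ridge model,
    attaching the t-like statistics T_k = beta_hat_k / sd_k."""
    if lam is None:
        lam = estimate_lambda(X, y)
    fit = ridge_solve(X, y, lam, sd_method=sd_method)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(fit.sd_beta > 0, fit.beta_hat / fit.sd_beta, 0.0)
    fit.T = T
    return fit


def test_effects(fit: RidgeFit, alpha: float) -> np.ndarray:
    """Two-sided significance flags: T_k >= q_{1-alpha/2} or
    T_k < q_{alpha/2} with standard-normal quantiles."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if fit.T is None:
        raise ValueError("fit carries no test statistics")
    q_hi = norm.ppf(1 - alpha / 2)
    q_lo = norm.ppf(alpha / 2)
    return (fit.T >= q_hi) | (fit.T < q_lo)


def roc_curve(
    T: np.ndarray,
    tag_positions: np.ndarray,
    qtl_positions: np.ndarray,
    window: float = 0.05,
    alphas: np.ndarray | None = None,
) -> np.ndarray:
    """Sensitivity and specificity of the t-like screen over a grid of
    type-I levels.

    A tested marker is "in-window" if it lies within ``window`` cM of any
    QTL.  Per level alpha, sensitivity is the fraction of QTLs with at
    least one significant in-window marker; specificity is one minus the
    fraction of significant markers among those outside all windows.
    Returns a structured array with fields alpha, sensitivity,
    specificity, sorted by alpha.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    T = np.asarray(T, dtype=float)
    tag_positions = np.asarray(tag_positions, dtype=float)
    qtl_positions = np.atleast_1d(np.asarray(qtl_positions, dtype=float))
    if alphas is None:
        alphas = np.linspace(1e-3, 1.0, 200)
    alphas = np.sort(np.asarray(alphas, dtype=float))

    dist = np.abs(tag_positions[:, None] - qtl_positions[None, :])
    in_window = dist <= window  # (markers, qtls)
    outside = ~in_window.any(axis=1)
    if not outside.any():
        raise ValueError("specificity undefined: no tested marker outside QTL windows")

    out = np.zeros(alphas.size, dtype=[("alpha", float), ("sensitivity", float), ("specificity", float)])
    for i, a in enumerate(alphas):
        q_hi = norm.ppf(1 - a / 2)
        q_lo = norm.ppf(a / 2)
        sig = (T >= q_hi) | (T < q_lo)
        detected = (sig[:, None] & in_window).any(axis=0)
        sens = detected.mean()
        fpr = sig[outside].mean()
        out[i] = (a, sens, 1.0 - fpr)
    return out


def roc_area(roc: np.ndarray) -> float:
    """Area under the ROC curve (trapezoid over FPR, with (0,0) and (1,1)
    endpoints added)."""
    fpr = 1.0 - roc["specificity"]
    tpr = roc["sensitivity"]
    order = np.argsort(fpr, kind="stable")
    fpr = np.concatenate([[0.0], fpr[order], [1.0]])
    tpr = np.concatenate([[0.0], tpr[order], [1.0]])
    return float(np.trapezoid(tpr, fpr))
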