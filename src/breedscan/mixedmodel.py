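"""Single-variance-component linear mixed model fitted by REML.

Model: y = X b + u + e with u ~ N(0, sg2 * K) and e ~ N(0, se2 * I).
The REML likelihood is profiled on the ratio lambda = sg2 / se2 using the
eigendecomposition of K, so the optimisation is a one-dimensional search
(golden-section / Brent, tolerance 1e-8 on log-lambda). This is the EMMA
formulation; association scans reuse the null-model ratio for every marker
(the EMMAX approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


@dataclass
class MixedModelFit:
    """REML fit of y = Xb + u + e with Var(u) = sg2*K, Var(e) = se2*I."""

    beta: np.ndarray
    sg2: float
    se2: float
    ratio: float  # lambda = sg2 / se2
    reml_loglik: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    y_rot: np.ndarray
    X_rot: np.ndarray

    @property
    def delta(self) -> float:
        """se2 / sg2 (inverse signal ratio); inf when sg2 = 0."""
        return np.inf if self.sg2 == 0 else self.se2 / self.sg2


def _reml_neg_loglik(log_lam: float, y_rot: np.ndarray, X_rot: np.ndarray, s: np.ndarray):
    lam = np.exp(log_lam)
    w = lam * s + 1.0
    n, p = X_rot.shape
    sw = np.sqrt(w)
    Xw = X_rot / sw[:, None]
    yw = y_rot / sw
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    try:
        beta = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    df = n - p
    se2 = rss / df
    sign, logdet_xtx = np.linalg.slogdet(XtX)
    ll = -0.5 * (
        df * np.log(2 * np.pi * se2)
        + df
        + np.sum(np.log(w))
        + logdet_xtx
    )
    return -ll, beta, se2


def reml_fit(y: np.ndarray, X: np.ndarray, K: np.ndarray, ridge: float = 1e-8) -> MixedModelFit:
    """Fit the one-component mixed model by REML.

    K must be symmetric PSD (a small ridge is added before decomposition).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n = len(y)
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: y is constant")
    K = np.asarray(K, dtype=float)
    s, U = np.linalg.eigh(K + ridge * np.eye(n))
    if s.min() < -1e-6:
        raise np.linalg.LinAlgError("kinship matrix not positive semidefinite")
    s = np.clip(s, 0.0, None)
    y_rot = U.T @ y
    X_rot = U.T @ X

    def obj(ll):
        return _reml_neg_loglik(ll, y_rot, X_rot, s)[0]

    res = optimize.minimize_scalar(
        obj, bounds=_LOG_LAMBDA_BOUNDS, method="bounded", options={"xatol": 1e-8}
    )
    # guard against local optima at the boundary
    candidates = [res.x, _LOG_LAMBDA_BOUNDS[0], _LOG_LAMBDA_BOUNDS[1]]
    best = min(candidates, key=obj)
    nll, beta, se2 = _reml_neg_loglik(best, y_rot, X_rot, s)
    lam = float(np.exp(best))
    if best <= _LOG_LAMBDA_BOUNDS[0] + 1e-6:
        lam = 0.0  # effectively no genetic variance
    return MixedModelFit(
        beta=beta,
        sg2=lam * se2,
        se2=se2,
        ratio=lam,
        reml_loglik=-nll,
        eigvals=s,
        eigvecs=U,
        y_rot=y_rot,
        X_rot=X_rot,
    )


def gls_scan(fit: MixedModelFit, markers_rot: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker GLS tests with the null variance ratio held fixed.

    markers_rot: rotated marker matrix (U.T @ M), one column per marker.
    Returns (beta, se, two-sided p) per marker; Wald-type t test on n-p-1 df.
    """
    lam = fit.ratio
    w = lam * fit.eigvals + 1.0
    sw = np.sqrt(w)
    Xw = fit.X_rot / sw[:, None]
    yw = fit.y_rot / sw
    Mw = markers_rot / sw[:, None]
    n, p = Xw.shape
    # residualize y and markers against the null fixed effects
    Q, _ = np.linalg.qr(Xw)
    y_res = yw - Q @ (Q.T @ yw)
    M_res = Mw - Q @ (Q.T @ Mw)
    xtx = np.einsum("ij,ij->j", M_res, M_res)
    xty = M_res.T @ y_res
    ok = xtx > 1e-12
    beta = np.full(markers_rot.shape[1], np.nan)
    se = np.full_like(beta, np.nan)
    pval = np.ones_like(beta)
    beta[ok] = xty[ok] / xtx[ok]
    rss0 = float(y_res @ y_res)
    rss = rss0 - xty[ok] ** 2 / xtx[ok]
    rss = np.clip(rss, 0.0, None)
    df = n - p - 1
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2 / xtx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / se[ok]
    pv = 2.0 * stats.t.sf(np.abs(tstat), df)
    pval[ok] = np.clip(pv, np.finfo(float).tiny, 1.0)
    return beta, se, pval
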