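"""Negative-binomial GLM fitting with a log link and multiplicative offsets.

The RNA model is NB2: y_b ~ NB(mean mu_b, size r) with
log mu_b = x_b' theta + log o_b, where o_b is the latent construct abundance
times the RNA size factor.  theta is maximised by Newton iterations (the
log-likelihood is concave in theta for fixed r); the dispersion r is profiled
by bounded scalar minimisation of the negative profile log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, xlogy

_LOG_R_BOUNDS = (np.log(1e-2), np.log(1e6))
_ETA_CLIP = 40.0


def nb_loglik(y: np.ndarray, mu: np.ndarray, r: float) -> float:
    return float(np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + xlogy(y, mu / (r + mu))))


@dataclass
class NBFit:
    theta: np.ndarray
    dispersion: float
    loglik: float
    converged: bool


def _newton(y, log_offset, X, r, theta0, tol=1e-10, max_iter=60):
    theta = theta0.copy()
    eta = np.clip(X @ theta + log_offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = nb_loglik(y, mu, r)
    converged = False
    for _ in range(max_iter):
        s = y - mu * (y + r) / (r + mu)
        g = X.T @ s
        w = (y + r) * mu * r / (r + mu) ** 2
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(len(theta)), g)
        except np.linalg.LinAlgError:
            break
        # step halving to guarantee ascent
        for _ in range(30):
            cand = theta + step
            eta_c = np.clip(X @ cand + log_offset, -_ETA_CLIP, _ETA_CLIP)
            mu_c = np.exp(eta_c)
            ll_c = nb_loglik(y, mu_c, r)
            if ll_c >= ll - 1e-12:
                break
            step = step / 2
        moved = np.max(np.abs(cand - theta))
        theta, mu, dll, ll = cand, mu_c, ll_c - ll, ll_c
        if moved < tol or abs(dll) < 1e-12:
            converged = True
            break
    return theta, ll, converged


def _init_theta(y, log_offset, X):
    z = np.log((y + 0.5)) - log_offset
    theta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    return np.clip(theta0, -30.0, 30.0)


def fit_nb_glm(y, log_offset, X, dispersion: float | None = None,
               *, xatol: float = 5e-3) -> NBFit:
    """Fit theta (and, if not given, the profiled dispersion)."""
    y = np.asarray(y, dtype=float)
    log_offset = np.asarray(log_offset, dtype=float)
    X = np.asarray(X, dtype=float)
    theta0 = _init_theta(y, log_offset, X)

    if dispersion is not None:
        theta, ll, conv = _newton(y, log_offset, X, dispersion, theta0)
        return NBFit(theta, dispersion, ll, conv)

    warm = {"theta": theta0}

    def neg_profile(log_r):
        theta, ll, _ = _newton(y, log_offset, X, np.exp(log_r), warm["theta"])
        warm["theta"] = theta
        return -ll

    res = minimize_scalar(neg_profile, bounds=_LOG_R_BOUNDS, method="bounded",
                          options={"xatol": xatol})
    r = float(np.exp(res.x))
    theta, ll, conv = _newton(y, log_offset, X, r, warm["theta"])
    return NBFit(theta, r, ll, conv and res.success)
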