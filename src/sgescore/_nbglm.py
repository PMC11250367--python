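"""Vectorized negative-binomial GLM core.

All fits in an SGE screen share one small design matrix (time, or a
two-level day factor), so the IRLS updates, Wald information and the
Cox-Reid adjusted profile likelihood are computed simultaneously for a
whole block of variants with plain ndarray algebra.  Shapes throughout:
``y`` is (V, S) counts, ``X`` is (S, P), ``offset`` is (V, S) or (S,),
``alpha`` is (V,) NB2 dispersions (var = mu + alpha * mu^2).  The linear
predictor is on the natural-log scale; callers convert slopes to log2.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

ALPHA_FLOOR = 1e-8
_ETA_CLIP = 50.0


def _as2d(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return y[None, :] if y.ndim == 1 else y


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-observation NB2 log-likelihood; Poisson limit below the floor."""
    y = _as2d(y)
    mu = np.maximum(_as2d(mu), 1e-300)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))[:, None]
    pois = y * np.log(mu) - mu - gammaln(y + 1.0)
    a = np.maximum(alpha, ALPHA_FLOOR)
    inv = 1.0 / a
    nb = (
        gammaln(y + inv)
        - gammaln(inv)
        - gammaln(y + 1.0)
        + y * np.log(a * mu / (1.0 + a * mu))
        - inv * np.log1p(a * mu)
    )
    return np.where(alpha < ALPHA_FLOOR, pois, nb)


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Summed NB deviance per variant (2 * [l_saturated - l_model])."""
    y = _as2d(y)
    mu = np.maximum(_as2d(mu), 1e-300)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))[:, None]
    ylog = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    a = np.maximum(alpha, ALPHA_FLOOR)
    nb = ylog - (y + 1.0 / a) * np.log((1.0 + a * y) / (1.0 + a * mu))
    pois = ylog - (y - mu)
    per_obs = np.where(alpha < ALPHA_FLOOR, pois, nb)
    return 2.0 * per_obs.sum(axis=1)


def _wls_solve(X: np.ndarray, w: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Weighted LS for every variant at once: solve (X'WX) b = X'Wz."""
    A = np.einsum("vs,sp,sq->vpq", w, X, X)
    b = np.einsum("vs,vs,sp->vp", w, z, X)
    # ridge a hair on ill-conditioned systems rather than erroring mid-block
    eye = np.eye(X.shape[1])
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.linalg.solve(A + 1e-10 * eye, b[..., None])[..., 0]


def irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Fit log-link NB GLMs by iteratively reweighted least squares.

    Returns ``(beta, se, mu, deviance, converged, n_iter)`` where ``beta``
    and ``se`` are (V, P) on the natural-log scale; ``se`` comes from the
    observed Fisher information.
    """
    y = _as2d(y)
    X = np.asarray(X, dtype=float)
    V, S = y.shape
    P = X.shape[1]
    offset = np.broadcast_to(_as2d(offset), (V, S)).astype(float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (V,)).copy()

    # log-linear start on lightly regularized counts
    z0 = np.log(y + 0.5) - offset
    beta = _wls_solve(X, np.ones_like(y), z0)

    dev = np.full(V, np.inf)
    converged = np.zeros(V, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(offset + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset) + (y - mu) / mu
        beta_new = _wls_solve(X, w, z)
        eta_new = np.clip(offset + beta_new @ X.T, -_ETA_CLIP, _ETA_CLIP)
        dev_new = nb_deviance(y, np.exp(eta_new), alpha)
        # deviance is quadratic near the optimum, so require the
        # coefficients themselves to settle as well
        step_ok = (np.abs(dev_new - dev) < tol * (1.0 + np.abs(dev_new))) & (
            np.max(np.abs(beta_new - beta), axis=1) < 1e-10
        )
        upd = ~converged
        beta[upd] = beta_new[upd]
        dev[upd] = dev_new[upd]
        converged = converged | (step_ok & upd)
        if converged.all():
            break

    eta = np.clip(offset + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    a = alpha[:, None]
    w_obs = mu * (1.0 + a * y) / (1.0 + a * mu) ** 2
    info = np.einsum("vs,sp,sq->vpq", w_obs, X, X)
    eye = np.eye(P)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(info + 1e-10 * eye)
    se = np.sqrt(np.maximum(np.einsum("vpp->vp", cov), 0.0))
    return beta, se, mu, dev, converged, it


def cr_profile_loglik(
    alpha: np.ndarray, y: np.ndarray, mu: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood of alpha at fixed means."""
    y = _as2d(y)
    mu = _as2d(mu)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    ll = nb_loglik(y, mu, alpha).sum(axis=1)
    w = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("vs,sp,sq->vpq", w, X, X)
    sign, logdet = np.linalg.slogdet(A)
    return ll - 0.5 * logdet


def _mom_alpha(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion from Pearson-style residuals."""
    y = _as2d(y)
    mu = _as2d(mu)
    num = ((y - mu) ** 2 - mu).sum(axis=1)
    den = np.maximum((mu**2).sum(axis=1), 1e-300)
    return np.clip(num / den, ALPHA_FLOOR, 100.0)


def estimate_alpha_cr(
    y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray,
    *,
    alpha_max: float = 50.0,
    grid_size: int = 25,
    refine_iter: int = 45,
    prior_log_mean: np.ndarray | None = None,
    prior_log_sd: float = 0.5,
) -> np.ndarray:
    """Maximize the CR adjusted profile likelihood over the dispersion.

    A method-of-moments estimate seeds a log-spaced bracket; a coarse
    grid locates the mode and golden-section refines it, vectorized over
    variants.  Under-dispersed variants return the floor (1e-8).  When
    ``prior_log_mean`` is given the objective is penalized by a normal
    prior on log(alpha) (MAP estimation toward a dispersion trend).
    """
    y = _as2d(y)
    mu = _as2d(mu)
    V = y.shape[0]

    if prior_log_mean is None:
        def objective(alpha):
            return cr_profile_loglik(alpha, y, mu, X)
    else:
        pm = np.asarray(prior_log_mean, dtype=float)

        def objective(alpha):
            pen = (np.log(alpha) - pm) ** 2 / (2.0 * prior_log_sd**2)
            return cr_profile_loglik(alpha, y, mu, X) - pen

    mom = _mom_alpha(y, mu)
    lo = np.log(ALPHA_FLOOR)
    hi = np.log(np.clip(10.0 * np.maximum(mom, 1e-4), 1.0, alpha_max))

    grid = np.linspace(0.0, 1.0, grid_size)
    vals = np.empty((grid_size, V))
    for k, g in enumerate(grid):
        vals[k] = objective(np.exp(lo + g * (hi - lo)))
    best = np.argmax(vals, axis=0)
    step = (hi - lo) / (grid_size - 1)
    a = lo + np.maximum(best - 1, 0) * step
    b = lo + np.minimum(best + 1, grid_size - 1) * step

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(refine_iter):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = objective(np.exp(c))
        fd = objective(np.exp(d))
        shrink_right = fc > fd  # maximum lies in [a, d]
        b = np.where(shrink_right, d, b)
        a = np.where(shrink_right, a, c)
    alpha = np.exp((a + b) / 2.0)
    at_floor = objective(np.full(V, ALPHA_FLOOR))
    at_opt = objective(alpha)
    alpha = np.where(at_floor >= at_opt, ALPHA_FLOOR, alpha)
    return np.maximum(alpha, ALPHA_FLOOR)
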