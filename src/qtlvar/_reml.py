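"""Restricted-likelihood numerics for one- and two-ratio variance models.

The restricted log-likelihood maximized here is

    L(theta) = -1/2 [ (n-p) ln(2 pi) + ln|V| + ln|X' V^-1 X| + r' V^-1 r ]

with r = y - X beta_hat and beta_hat the GLS solution at theta.  The
Gaussian constant is included so values are on the same scale as standard
mixed-model software.  The residual variance is profiled out analytically;
the remaining variance ratio(s) lambda = sigma_g^2 / sigma^2 are optimized
on the log scale, which enforces positivity, with explicit comparisons
against the boundary fits (component removed) so zero estimates are exact.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize

LOG2PI = float(np.log(2.0 * np.pi))

#: log-ratio search window; e^±25 spans every practically distinguishable ratio
_LOGLAM_LO, _LOGLAM_HI = -25.0, 25.0


class ConvergenceError(RuntimeError):
    """REML iteration failed; carries the evaluation trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


def check_design(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient (collinear columns)")
    return X


def ols_restricted_fit(y, X) -> dict:
    """Single-component limit V = I sigma^2 (closed form)."""
    y = np.asarray(y, dtype=float).ravel()
    X = check_design(X)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    rss = float(r @ r)
    sigma2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)
    loglik = -0.5 * ((n - p) * (LOG2PI + np.log(sigma2)) + logdet_xtx + (n - p))
    beta_cov = sigma2 * np.linalg.inv(X.T @ X)
    return {
        "beta": beta,
        "beta_cov": beta_cov,
        "sigma_g2": 0.0,
        "sigma2": sigma2,
        "lam": 0.0,
        "loglik": float(loglik),
        "boundary": True,
        "n_iter": 1,
        "converged": True,
    }


def reml_one_random(y, X, G, *, eig=None, identifiability_tol=1e-8, grid_size=41) -> dict:
    """REML for V = G sigma_g^2 + I sigma^2.

    A spectral decomposition of G makes each likelihood evaluation O(n p^2)
    after the O(n^3) setup; pass ``eig=(d, U)`` to reuse a decomposition
    across fits sharing G.  The profiled restricted likelihood in the log
    variance ratio is maximized by a coarse grid followed by bounded Brent
    refinement, and compared against the lambda = 0 boundary (ordinary least
    squares) so that zero variance components are reported exactly.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = check_design(X)
    n, p = X.shape
    if eig is None:
        G = np.asarray(G, dtype=float)
        d, U = np.linalg.eigh(0.5 * (G + G.T))
    else:
        d, U = eig
    d = np.clip(d, 0.0, None)
    if d[-1] - d[0] < identifiability_tol * max(d[-1], 1.0):
        raise ValueError(
            "random-effect covariance is proportional to the identity; "
            "its variance component is confounded with the residual variance"
        )
    yt = U.T @ y
    Xt = U.T @ X

    def profile(loglam):
        lam = np.exp(loglam)
        v = d * lam + 1.0
        w = 1.0 / v
        XtWX = Xt.T @ (Xt * w[:, None])
        c, low = linalg.cho_factor(XtWX)
        beta = linalg.cho_solve((c, low), Xt.T @ (w * yt))
        r = yt - Xt @ beta
        q = float(np.sum(r * r * w))
        sigma2 = q / (n - p)
        logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(c))))
        ll = -0.5 * (
            (n - p) * (LOG2PI + np.log(sigma2))
            + float(np.sum(np.log(v)))
            + logdet_xvx
            + (n - p)
        )
        return ll, beta, sigma2, XtWX

    lgrid = np.linspace(_LOGLAM_LO, _LOGLAM_HI, grid_size)
    lls = np.array([profile(l)[0] for l in lgrid])
    i = int(np.argmax(lls))
    lo = lgrid[max(i - 1, 0)]
    hi = lgrid[min(i + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda l: -profile(l)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-11},
    )
    loglam = float(res.x)
    ll, beta, sigma2, XtWX = profile(loglam)
    lam = float(np.exp(loglam))

    ols = ols_restricted_fit(y, X)
    if ols["loglik"] >= ll or lam * d[-1] < 1e-10:
        out = dict(ols)
        out["n_iter"] = grid_size + int(res.nfev) + 1
        return out
    beta_cov = sigma2 * np.linalg.inv(XtWX)
    return {
        "beta": beta,
        "beta_cov": beta_cov,
        "sigma_g2": lam * sigma2,
        "sigma2": sigma2,
        "lam": lam,
        "loglik": float(ll),
        "boundary": False,
        "n_iter": grid_size + int(res.nfev) + 1,
        "converged": bool(res.success),
    }


def reml_two_random(y, X, G1, G2, *, starts=None, eig2=None, maxiter=2000) -> dict:
    """REML for V = G1 sigma_1^2 + G2 sigma_2^2 + I sigma^2.

    The two log variance ratios are optimized with Nelder-Mead (restarted once
    from its own solution for polish); the three boundary models (either or
    both components removed) are fitted exactly and the overall restricted-
    likelihood maximizer is returned.  ``boundary`` flags which of
    (sigma_1^2, sigma_2^2) is pinned at zero.

    Intended for direct solves at moderate n (a few thousand at most).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = check_design(X)
    n, p = X.shape
    G1 = np.asarray(G1, dtype=float)
    G2 = np.asarray(G2, dtype=float)
    I = np.eye(n)

    def profile(v):
        l1 = np.exp(np.clip(v[0], _LOGLAM_LO - 5, _LOGLAM_HI + 5))
        l2 = np.exp(np.clip(v[1], _LOGLAM_LO - 5, _LOGLAM_HI + 5))
        H = G1 * l1 + G2 * l2 + I
        try:
            c, low = linalg.cho_factor(H)
        except linalg.LinAlgError:
            return None
        logdet_h = 2.0 * float(np.sum(np.log(np.diag(c))))
        Hinv_X = linalg.cho_solve((c, low), X)
        XtHX = X.T @ Hinv_X
        try:
            cx, lowx = linalg.cho_factor(XtHX)
        except linalg.LinAlgError:
            return None
        beta = linalg.cho_solve((cx, lowx), Hinv_X.T @ y)
        r = y - X @ beta
        q = float(r @ linalg.cho_solve((c, low), r))
        sigma2 = q / (n - p)
        logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(cx))))
        ll = -0.5 * (
            (n - p) * (LOG2PI + np.log(sigma2)) + logdet_h + logdet_xvx + (n - p)
        )
        return ll, beta, sigma2, XtHX

    def neg(v):
        out = profile(v)
        return np.inf if out is None else -out[0]

    start_list = [np.log([0.1, 0.1])]
    if starts is not None:
        start_list = [np.asarray(s, dtype=float) for s in starts] + start_list

    best = None
    nfev = 0
    for s0 in start_list:
        res = optimize.minimize(
            neg, s0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": maxiter},
        )
        # polish: restart the simplex from the solution
        res = optimize.minimize(
            neg, res.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": maxiter},
        )
        nfev += int(res.nfev)
        if np.isfinite(res.fun) and (best is None or -res.fun > best[0]):
            best = (-res.fun, res.x)
    if best is None:
        raise ConvergenceError("two-ratio REML failed from all starts")

    candidates = []
    ll_int, beta, sigma2, XtHX = profile(best[1])
    l1, l2 = np.exp(best[1])
    candidates.append(
        {
            "loglik": ll_int,
            "sigma_g1": l1 * sigma2,
            "sigma_g2": l2 * sigma2,
            "sigma2": sigma2,
            "beta": beta,
            "beta_cov": sigma2 * np.linalg.inv(XtHX),
            "boundary": (False, False),
        }
    )
    # boundary fits: exact maximizers of the reduced models
    try:
        b1 = reml_one_random(y, X, G2, eig=eig2)
        candidates.append(
            {
                "loglik": b1["loglik"],
                "sigma_g1": 0.0,
                "sigma_g2": b1["sigma_g2"],
                "sigma2": b1["sigma2"],
                "beta": b1["beta"],
                "beta_cov": b1["beta_cov"],
                "boundary": (True, b1["boundary"]),
            }
        )
    except ValueError:
        pass
    try:
        b2 = reml_one_random(y, X, G1)
        candidates.append(
            {
                "loglik": b2["loglik"],
                "sigma_g1": b2["sigma_g2"],
                "sigma_g2": 0.0,
                "sigma2": b2["sigma2"],
                "beta": b2["beta"],
                "beta_cov": b2["beta_cov"],
                "boundary": (b2["boundary"], True),
            }
        )
    except ValueError:
        pass
    out = max(candidates, key=lambda c: c["loglik"])
    out["n_iter"] = nfev
    out["converged"] = True
    return out


def reml_information(V, X, V_derivs) -> np.ndarray:
    """Expected (Fisher) information for variance components.

    I[i, j] = 1/2 tr(P dV/dtheta_i P dV/dtheta_j) with
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1, evaluated at the estimates on
    the original variance scale.
    """
    V = np.asarray(V, dtype=float)
    X = check_design(X)
    Vinv = np.linalg.inv(V)
    VX = Vinv @ X
    P = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
    PV = [P @ np.asarray(Vi, dtype=float) for Vi in V_derivs]
    k = len(PV)
    info = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            info[i, j] = info[j, i] = 0.5 * float(np.sum(PV[i] * PV[j].T))
    return info


def restricted_loglik(y, X, V) -> float:
    """Direct evaluation of the restricted log-likelihood at a given V."""
    y = np.asarray(y, dtype=float).ravel()
    X = check_design(X)
    n, p = X.shape
    c, low = linalg.cho_factor(np.asarray(V, dtype=float))
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv_X = linalg.cho_solve((c, low), X)
    XtVX = X.T @ Vinv_X
    beta = np.linalg.solve(XtVX, Vinv_X.T @ y)
    r = y - X @ beta
    q = float(r @ linalg.cho_solve((c, low), r))
    _, logdet_xvx = np.linalg.slogdet(XtVX)
    return -0.5 * ((n - p) * LOG2PI + logdet_v + logdet_xvx + q)
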