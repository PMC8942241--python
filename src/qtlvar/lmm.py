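"""Fixed- and random-effect QTL mixed models fitted by REML.

Two treatments of a single tested locus in the mixed model
y = X beta + z alpha + xi + eps, with polygenic background
xi ~ N(0, A sigma_xi^2) and residual eps ~ N(0, I sigma^2):

``FixedQTLModel``
    The standardized marker code z enters the fixed design.  REML estimates
    (sigma_xi^2, sigma^2); the QTL variance is then the moment estimate
    alpha_hat^2 - s_alpha^2, which corrects the upward bias of the naive
    squared effect.

``RandomQTLModel``
    alpha ~ N(0, sigma_alpha^2) is a variance component of
    V = z z' sigma_alpha^2 + A sigma_xi^2 + I sigma^2, estimated by REML
    together with an asymptotic covariance matrix from the inverse expected
    information, which feeds the delta-method standard error of the QTL
    heritability.

Both are scikit-learn estimators: ``fit(X, y, covariates=...)`` takes the
marker code column as X; fitted quantities carry trailing underscores.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from . import _reml, estimators as _est
from .genodata import KinshipMatrix, standardize_genotypes

__all__ = [
    "FixedQTLModel",
    "RandomQTLModel",
    "reml_fit_fixed_qtl",
    "reml_fit_random_qtl",
    "reml_fit_null",
    "wald_test",
    "likelihood_ratio_test",
    "bonferroni_wald_threshold",
]


def _marker_column(X) -> np.ndarray:
    z = np.asarray(X, dtype=float)
    if z.ndim == 2:
        if z.shape[1] != 1:
            raise ValueError(f"expected a single marker column, got shape {z.shape}")
        z = z[:, 0]
    return z.ravel()


def _build_design(n: int, covariates) -> np.ndarray:
    parts = [np.ones((n, 1))]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError(f"covariates have {C.shape[0]} rows, expected {n}")
        parts.append(C)
    return np.hstack(parts)


def _kinship_values(kinship) -> np.ndarray | None:
    if kinship is None:
        return None
    if isinstance(kinship, KinshipMatrix):
        return kinship.values
    return KinshipMatrix(np.asarray(kinship, dtype=float)).values


def wald_test(alpha_hat: float, s_alpha: float) -> tuple[float, float]:
    """Wald statistic W = (alpha_hat / s)^2 with a chi-square(1) p-value."""
    if s_alpha <= 0:
        raise ValueError(f"standard error must be positive, got {s_alpha}")
    W = (alpha_hat / s_alpha) ** 2
    return float(W), float(stats.chi2.sf(W, df=1))


def likelihood_ratio_test(loglik_null: float, loglik_alt: float) -> float:
    """LRT = -2 (L0 - L1), floored at zero for nested fits."""
    if loglik_alt < loglik_null - 1e-6:
        raise ValueError(
            f"alternative log-likelihood {loglik_alt} below null {loglik_null}; fits are not nested"
        )
    return max(-2.0 * (loglik_null - loglik_alt), 0.0)


def bonferroni_wald_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Chi-square(1) quantile at 1 - alpha/n_tests (Bonferroni-corrected Wald threshold)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return float(stats.chi2.ppf(1.0 - alpha / n_tests, df=1))


class FixedQTLModel(BaseEstimator):
    """Mixed model with the tested locus as a fixed effect.

    Parameters
    ----------
    kinship : KinshipMatrix, ndarray or None
        Additive relationship matrix A for the polygenic component.  When
        absent the model degenerates to ordinary least squares (interval-
        mapping mode, single residual variance).
    standardize : bool
        Standardize the marker codes before fitting (idempotent; default
        True).  The moment/adjusted-R2 identities presume standardized codes.
    marker_name : str
        Label used in error messages and reports.

    Attributes (after ``fit``)
    --------------------------
    beta_ : ndarray            fixed effects (intercept, covariates, alpha)
    alpha_, s_alpha_ : float   marker effect and its standard error
    sigma_xi2_ : float | None  polygenic variance (None without kinship)
    sigma2_ : float            residual variance
    loglik_ : float            restricted log-likelihood
    wald_, p_value_ : float
    qtl_variance_raw_ : float  moment estimate alpha^2 - s^2, untruncated
    qtl_variance_ : float      max(alpha^2 - s^2, 0)
    h2_ : float                corrected heritability (truncated variance)
    h2_naive_ : float          naive heritability from the squared effect
    """

    def __init__(self, kinship=None, standardize: bool = True, marker_name: str = "marker"):
        self.kinship = kinship
        self.standardize = standardize
        self.marker_name = marker_name

    def fit(self, X, y, covariates=None):
        z = _marker_column(X)
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if z.size != n:
            raise ValueError(f"marker length {z.size} != trait length {n}")
        if self.standardize:
            z = standardize_genotypes(z, name=self.marker_name)
        design = np.hstack([_build_design(n, covariates), z[:, None]])
        A = _kinship_values(self.kinship)
        if A is None:
            fit = _reml.ols_restricted_fit(y, design)
            self.sigma_xi2_ = None
        else:
            fit = _reml.reml_one_random(y, design, A)
            self.sigma_xi2_ = fit["sigma_g2"]
        self.n_, self.z_ = n, z
        self.beta_ = fit["beta"]
        self.beta_cov_ = fit["beta_cov"]
        self.alpha_ = float(fit["beta"][-1])
        self.s_alpha_ = float(np.sqrt(fit["beta_cov"][-1, -1]))
        self.sigma2_ = float(fit["sigma2"])
        self.loglik_ = float(fit["loglik"])
        self.n_iter_ = fit["n_iter"]
        self.converged_ = fit["converged"]
        self.boundary_ = fit["boundary"]
        self.wald_, self.p_value_ = wald_test(self.alpha_, self.s_alpha_)
        self.qtl_variance_raw_ = _est.moment_qtl_variance(self.alpha_, self.s_alpha_, truncate=False)
        self.qtl_variance_ = max(self.qtl_variance_raw_, 0.0)
        xi = self.sigma_xi2_ or 0.0
        self.h2_ = _est.qtl_heritability(self.qtl_variance_, xi, self.sigma2_)
        self.h2_naive_ = _est.qtl_heritability(self.alpha_ ** 2, xi, self.sigma2_)
        # the fixed model carries no sampling covariance for the moment
        # estimate, so no delta-method SE is available here
        self.h2_se_ = None
        return self

    def predict(self, X, covariates=None):
        z = _marker_column(X)
        if self.standardize:
            z = standardize_genotypes(z, name=self.marker_name)
        design = np.hstack([_build_design(z.size, covariates), z[:, None]])
        return design @ self.beta_


class RandomQTLModel(BaseEstimator):
    """Mixed model with the tested locus as a random effect (QTL variance REML).

    The marker is excluded from the fixed design; its contribution enters the
    covariance as z z' sigma_alpha^2.  Without kinship this is the
    two-component model V = z z' sigma_alpha^2 + I sigma^2; with kinship a
    three-component model whose two variance ratios are maximized jointly,
    warm-started from the companion fixed-model fit.

    Attributes (after ``fit``)
    --------------------------
    sigma_alpha2_, sigma_xi2_, sigma2_ : float   REML variance components
    theta_ : ndarray          components in estimation order
    theta_cov_ : ndarray      inverse expected information at theta_
                              (rows/columns of boundary components are NaN
                              when the information is not invertible there)
    loglik_ : float
    h2_ : float               sigma_alpha^2 / total
    h2_se_ : float            delta-method standard error of h2_
    boundary_ : bool          sigma_alpha^2 pinned at zero
    alpha_gls_, s_alpha_gls_ : float
        GLS effect estimate and standard error of the marker computed at the
        fitted nuisance components.  At an interior REML optimum the score
        equation makes sigma_alpha2_ = alpha_gls_^2 - s_alpha_gls_^2 exactly,
        the sufficient-statistic form of the moment/REML equivalence.
    """

    def __init__(self, kinship=None, standardize: bool = True, marker_name: str = "marker"):
        self.kinship = kinship
        self.standardize = standardize
        self.marker_name = marker_name

    def fit(self, X, y, covariates=None):
        z = _marker_column(X)
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if z.size != n:
            raise ValueError(f"marker length {z.size} != trait length {n}")
        if self.standardize:
            z = standardize_genotypes(z, name=self.marker_name)
        design = _build_design(n, covariates)
        A = _kinship_values(self.kinship)
        Gz = np.outer(z, z)
        if A is None:
            fit = _reml.reml_one_random(y, design, Gz)
            self.sigma_alpha2_ = float(fit["sigma_g2"])
            self.sigma_xi2_ = None
            self.sigma2_ = float(fit["sigma2"])
            self.boundary_ = bool(fit["boundary"])
            self.theta_ = np.array([self.sigma_alpha2_, self.sigma2_])
            derivs = [Gz, np.eye(n)]
            V = Gz * self.sigma_alpha2_ + np.eye(n) * self.sigma2_
            pinned = [self.boundary_, False]
        else:
            warm = self._warm_start(z, y, design, A)
            dA, UA = np.linalg.eigh(A)
            fit = _reml.reml_two_random(y, design, Gz, A, starts=warm, eig2=(dA, UA))
            self.sigma_alpha2_ = float(fit["sigma_g1"])
            self.sigma_xi2_ = float(fit["sigma_g2"])
            self.sigma2_ = float(fit["sigma2"])
            b1, b2 = fit["boundary"]
            self.boundary_ = bool(b1)
            self.theta_ = np.array([self.sigma_alpha2_, self.sigma_xi2_, self.sigma2_])
            derivs = [Gz, A, np.eye(n)]
            V = Gz * self.sigma_alpha2_ + A * self.sigma_xi2_ + np.eye(n) * self.sigma2_
            pinned = [bool(b1), bool(b2), False]
        self.n_, self.z_ = n, z
        self.beta_ = fit["beta"]
        self.loglik_ = float(fit["loglik"])
        self.n_iter_ = fit["n_iter"]
        self.converged_ = fit.get("converged", True)
        self.theta_cov_ = self._theta_cov(V, design, derivs, pinned)
        self.alpha_gls_, self.s_alpha_gls_ = self._gls_at_nuisance(z, y, design, A)
        total = float(self.theta_.sum())
        self.h2_ = _est.qtl_heritability(
            self.sigma_alpha2_, self.sigma_xi2_ or 0.0, self.sigma2_
        )
        if np.all(np.isfinite(self.theta_cov_)) and total > 0:
            self.h2_se_ = _est.delta_se_heritability(self.theta_, self.theta_cov_)
        else:
            self.h2_se_ = float("nan")
        return self

    @staticmethod
    def _theta_cov(V, X, derivs, pinned):
        info = _reml.reml_information(V, X, derivs)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full_like(info, np.nan)
            return cov
        # a boundary solution can leave the expected information indefinite
        # for the pinned component; report those entries as unavailable
        bad = [i for i, (pin, var) in enumerate(zip(pinned, np.diag(cov))) if var < 0 or (pin and var < 0)]
        if np.any(np.diag(cov) < 0):
            bad = list(np.where(np.diag(cov) < 0)[0])
        for i in bad:
            cov[i, :] = np.nan
            cov[:, i] = np.nan
        return cov

    def _gls_at_nuisance(self, z, y, X, A):
        """GLS marker effect and SE at the fitted nuisance components.

        V0 excludes the QTL term; P0 projects out the fixed design under V0.
        alpha_gls = z'P0 y / z'P0 z, s_gls^2 = 1 / z'P0 z.
        """
        n = y.size
        V0 = np.eye(n) * self.sigma2_
        if A is not None:
            V0 = V0 + A * self.sigma_xi2_
        V0inv = np.linalg.inv(V0)
        VX = V0inv @ X
        P0 = V0inv - VX @ np.linalg.solve(X.T @ VX, VX.T)
        c = float(z @ P0 @ z)
        u = float(z @ P0 @ y)
        return u / c, float(np.sqrt(1.0 / c))

    def _warm_start(self, z, y, design, A):
        """Seed the two-ratio search from the fixed-model fit."""
        try:
            fixed = _reml.reml_one_random(y, np.hstack([design, z[:, None]]), A)
        except (ValueError, _reml.ConvergenceError):
            return None
        s2 = fixed["sigma2"]
        alpha = float(fixed["beta"][-1])
        s_alpha2 = float(fixed["beta_cov"][-1, -1])
        lam_a = max(alpha * alpha - s_alpha2, 1e-6 * s2) / s2
        lam_xi = max(fixed["sigma_g2"], 1e-6 * s2) / s2
        return [np.log([lam_a, lam_xi])]


def reml_fit_fixed_qtl(y, marker, covariates=None, kinship=None, **kwargs) -> FixedQTLModel:
    """Fit the fixed-QTL mixed model; returns the fitted estimator."""
    return FixedQTLModel(kinship=kinship, **kwargs).fit(np.asarray(marker), y, covariates=covariates)


def reml_fit_random_qtl(y, marker, covariates=None, kinship=None, **kwargs) -> RandomQTLModel:
    """Fit the random-QTL mixed model; returns the fitted estimator."""
    return RandomQTLModel(kinship=kinship, **kwargs).fit(np.asarray(marker), y, covariates=covariates)


def reml_fit_null(y, covariates=None, kinship=None) -> tuple[dict, float]:
    """Null model without the tested locus: y = X beta + xi + eps.

    Returns ``(components, restricted_loglik)`` with components keyed
    'sigma_xi2' (None when kinship is absent) and 'sigma2'.  The
    log-likelihood is on the same scale as the fitted QTL models, so
    ``likelihood_ratio_test`` applies directly.
    """
    y = np.asarray(y, dtype=float).ravel()
    design = _build_design(y.size, covariates)
    A = _kinship_values(kinship)
    if A is None:
        fit = _reml.ols_restricted_fit(y, design)
        return {"sigma_xi2": None, "sigma2": fit["sigma2"]}, fit["loglik"]
    fit = _reml.reml_one_random(y, design, A)
    return {"sigma_xi2": fit["sigma_g2"], "sigma2": fit["sigma2"]}, fit["loglik"]
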