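"""QTL variance and heritability estimators.

The central quantity is the moment estimator of the QTL variance,

    sigma_alpha^2 = alpha_hat^2 - s_alpha^2,

the squared fixed-model effect estimate minus its squared standard error.
Because E[alpha_hat^2] = alpha^2 + s_alpha^2, subtracting the squared
standard error removes the upward bias of the naive squared estimator;
truncated at zero it coincides with the random-model REML estimate.  The
companion functions cover the heritability ratio and its delta-method
standard error, the pseudo/adjusted R-squared connections, the multi-level
generalization of the moment estimator, and the partition of multi-locus
genetic variance under linkage disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "HeritabilityResult",
    "R2Family",
    "moment_qtl_variance",
    "naive_qtl_variance",
    "qtl_heritability",
    "delta_se_heritability",
    "pseudo_r2",
    "r2_family",
    "moment_variance_multilevel",
    "ld_partitioned_variance",
]


@dataclass
class HeritabilityResult:
    """A heritability estimate with its provenance."""

    h2: float
    se: float | None
    method: str  # moment-fixed | reml-random | naive-squared | adjusted-R2 | pseudo-R2 | R2

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"heritability must be in [0, 1], got {self.h2}")
        if self.se is not None and self.se < 0:
            raise ValueError(f"standard error must be non-negative, got {self.se}")


def moment_qtl_variance(alpha_hat: float, s_alpha: float, truncate: bool = True) -> float:
    """Moment estimate of the QTL variance: alpha_hat^2 - s_alpha^2.

    ``truncate=True`` returns the positive part (the REML-equivalent
    estimate); ``truncate=False`` keeps negative values, which is the form
    whose mean is unbiased for the true variance.
    """
    if s_alpha < 0:
        raise ValueError("s_alpha must be non-negative")
    v = alpha_hat * alpha_hat - s_alpha * s_alpha
    return max(v, 0.0) if truncate else v


def naive_qtl_variance(alpha_hat: float, sigma_z2: float = 1.0) -> float:
    """Naive (upward-biased) QTL variance: sigma_Z^2 * alpha_hat^2.

    With standardized genotype codes (sigma_Z^2 = 1) this is just the squared
    effect estimate; pass ``sigma_z2`` (e.g. 2pq) for unstandardized codes.
    """
    return sigma_z2 * alpha_hat * alpha_hat


def qtl_heritability(sigma_qtl2: float, sigma_xi2: float, sigma2: float) -> float:
    """Proportion of phenotypic variance due to the locus.

    The QTL variance is clipped at zero before use; the denominator must be
    positive.
    """
    v = max(sigma_qtl2, 0.0)
    denom = v + sigma_xi2 + sigma2
    if denom <= 0:
        raise ValueError("total variance must be positive")
    return v / denom


def delta_se_heritability(theta_hat, theta_cov) -> float:
    """Delta-method standard error of h2 = theta[0] / sum(theta).

    With X = L_X' theta (L_X selecting the QTL component) and
    Y = L_Y' theta (L_Y summing all components),

        var(h2) ~= (var(X) Y^2 - 2 cov(X, Y) X Y + var(Y) X^2) / Y^4.

    Works for any number of components >= 2 (two without a polygene, three
    with one).
    """
    theta = np.asarray(theta_hat, dtype=float).ravel()
    C = np.asarray(theta_cov, dtype=float)
    k = theta.size
    if C.shape != (k, k):
        raise ValueError(f"covariance must be {k} x {k}, got {C.shape}")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("covariance matrix must be symmetric")
    L_X = np.zeros(k)
    L_X[0] = 1.0
    L_Y = np.ones(k)
    X = float(L_X @ theta)
    Y = float(L_Y @ theta)
    if Y <= 0:
        raise ValueError("total variance must be positive")
    var_X = float(L_X @ C @ L_X)
    cov_XY = float(L_X @ C @ L_Y)
    var_Y = float(L_Y @ C @ L_Y)
    var_h2 = (var_X * Y * Y - 2.0 * cov_XY * X * Y + var_Y * X * X) / Y ** 4
    if var_h2 < -1e-15:
        raise ValueError(
            f"delta approximation gave negative variance ({var_h2:.3e}); invalid covariance input"
        )
    return float(np.sqrt(max(var_h2, 0.0)))


def pseudo_r2(lrt: float, n: int) -> float:
    """Likelihood-based goodness of fit 1 - exp(-LRT/n)."""
    if lrt < 0:
        raise ValueError("LRT must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(1.0 - np.exp(-lrt / n))


class R2Family(NamedTuple):
    r2: float
    adjusted_r2: float
    corrected_h2: float


def r2_family(alpha_hat: float, sigma2_hat: float, n: int) -> R2Family:
    """R-squared, adjusted R-squared and corrected heritability for a
    single standardized marker with no polygene.

    Under that model s_alpha^2 = sigma^2/(n-1), so

        R2     = (n-1) a^2 / [(n-1) a^2 + (n-2) s2]
        R2_adj = 1 - (1 - R2)(n-1)/(n-2)
        h2     = (a^2 - s2/(n-1)) / (a^2 - s2/(n-1) + s2)

    and R2_adj equals the corrected heritability identically; both can be
    negative when the effect is indistinguishable from noise, mirroring the
    usual behavior of the adjusted R-squared.
    """
    if n <= 2:
        raise ValueError("need n >= 3")
    a2 = alpha_hat * alpha_hat
    s2 = sigma2_hat
    r2 = (n - 1) * a2 / ((n - 1) * a2 + (n - 2) * s2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    m = a2 - s2 / (n - 1)
    h2 = m / (m + s2)
    if abs(adj - h2) > 1e-12:
        raise AssertionError(
            f"adjusted R2 ({adj!r}) and corrected h2 ({h2!r}) diverged; numerical fault"
        )
    if s2 > 0 and not r2 > h2:
        raise AssertionError("R2 must strictly exceed the corrected h2 when sigma2 > 0")
    return R2Family(float(r2), float(adj), float(h2))


def moment_variance_multilevel(alpha_hat_vector, alpha_cov) -> float:
    """Randomized-fixed-model variance estimate for a k-level random effect.

    (1/k) [ sum_k alpha_hat_k^2 - tr(var(alpha_hat | alpha)) ]; reduces to
    the scalar moment estimate at k = 1.  Useful e.g. for the four epistatic
    effect levels of a locus pair.
    """
    a = np.asarray(alpha_hat_vector, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(alpha_cov, dtype=float))
    k = a.size
    if C.shape != (k, k):
        raise ValueError(f"error covariance must be {k} x {k}, got {C.shape}")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("error covariance must be symmetric")
    return float((a @ a - np.trace(C)) / k)


def ld_partitioned_variance(effects, z_cov, model: str = "fixed") -> tuple[np.ndarray, float]:
    """Per-locus genetic variances for multiple loci in linkage disequilibrium.

    fixed
        locus k contributes sigma_Zk^2 alpha_k^2 plus its LD cross terms
        sum_{k' != k} sigma_ZkZk' alpha_k alpha_k'; the per-locus terms sum to
        the full quadratic form alpha' cov(Z) alpha.  Cross terms can be
        negative under antagonistic LD and are reported as-is.
    random
        with standardized genotype codes each locus contributes alpha_k^2 and
        the total is their plain sum, LD or not.
    """
    a = np.asarray(effects, dtype=float).ravel()
    if model == "random":
        per = a * a
        return per, float(per.sum())
    if model != "fixed":
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    C = np.atleast_2d(np.asarray(z_cov, dtype=float))
    if C.shape != (a.size, a.size):
        raise ValueError(f"genotype covariance must be {a.size} x {a.size}, got {C.shape}")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("genotype covariance must be symmetric")
    per = a * (C @ a)
    return per, float(per.sum())
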