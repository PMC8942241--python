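import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from qtlvar import _reml, simulate_f2_single_marker, simulate_fullsib_polygenic
from qtlvar.genodata import fullsib_numerator_matrix
from qtlvar.lmm import (
    FixedQTLModel,
    RandomQTLModel,
    bonferroni_wald_threshold,
    likelihood_ratio_test,
    reml_fit_fixed_qtl,
    reml_fit_null,
    reml_fit_random_qtl,
    wald_test,
)


class TestFixedModelOLSLimit:
    """Without kinship the fixed-QTL model must reduce to ordinary least squares."""

    def test_matches_closed_form(self, rng):
        n = 40
        z = rng.choice([1.0, 0.0, -1.0], n)
        z = (z - z.mean()) / z.std(ddof=1)
        y = 3.0 + 0.8 * z + rng.normal(0, 2.0, n)
        fit = reml_fit_fixed_qtl(y, z)
        # independent closed-form OLS oracle
        X = np.column_stack([np.ones(n), z])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 2)
        s_alpha = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert fit.alpha_ == pytest.approx(beta[1], abs=1e-10)
        assert fit.s_alpha_ == pytest.approx(s_alpha, abs=1e-10)
        assert fit.sigma2_ == pytest.approx(sigma2, abs=1e-10)
        assert fit.sigma_xi2_ is None
        # with standardized z, s^2 = sigma^2/(n-1)
        assert fit.s_alpha_**2 == pytest.approx(fit.sigma2_ / (n - 1), abs=1e-10)

    def test_wald_consistency_invariant(self, rng):
        y, geno = simulate_f2_single_marker(50, 0.1, rng=rng)
        fit = reml_fit_fixed_qtl(y, geno.standardized)
        assert fit.wald_ == pytest.approx((fit.alpha_ / fit.s_alpha_) ** 2, abs=1e-10)

    def test_collinear_covariate_rejected(self, rng):
        y, geno = simulate_f2_single_marker(30, 0.1, rng=rng)
        with pytest.raises(ValueError, match="rank deficient"):
            reml_fit_fixed_qtl(y, geno.standardized, covariates=geno.standardized)


class TestFixedModelPolygenic:
    def test_recovers_true_components(self):
        # full-sib data at n = 250, truth (sigma_xi2, sigma2) = (10, 10)
        reps, xi_hat, s2_hat = 60, [], []
        A = fullsib_numerator_matrix(50, 5)
        for r in range(reps):
            y, geno, _ = simulate_fullsib_polygenic(50, 5, 0.1, seed=[77, r], kinship=A)
            f = FixedQTLModel(kinship=A).fit(geno.standardized, y)
            xi_hat.append(f.sigma_xi2_)
            s2_hat.append(f.sigma2_)
        for est, truth in ((xi_hat, 10.0), (s2_hat, 10.0)):
            mc_se = np.std(est, ddof=1) / np.sqrt(reps)
            assert abs(np.mean(est) - truth) < 3 * mc_se

    def test_against_lme4(self, tmp_path, fullsib_data):
        """Compound-symmetry kinship is a random family intercept: lme4 oracle."""
        y, geno, K = fullsib_data
        fit = FixedQTLModel(kinship=K).fit(geno.standardized, y)
        df = pd.DataFrame(
            {"y": y, "z": geno.standardized, "fam": np.repeat(np.arange(10), 5)}
        )
        csv = tmp_path / "fs.csv"
        df.to_csv(csv, index=False)
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript not on PATH"
        out = subprocess.run(
            [
                rscript,
                "-e",
                "suppressMessages(library(lme4));"
                f"d <- read.csv('{csv}'); d$fam <- factor(d$fam);"
                "m <- lmer(y ~ z + (1|fam), data=d, REML=TRUE);"
                "vc <- as.data.frame(VarCorr(m));"
                "cat(fixef(m)['z'], sqrt(vcov(m)['z','z']), 2*vc$vcov[1],"
                "    vc$vcov[2]-vc$vcov[1], as.numeric(logLik(m)), sep=',')",
            ],
            capture_output=True,
            text=True,
            check=True,
        )
        alpha, s, xi, s2, ll = map(float, out.stdout.strip().split(","))
        assert fit.alpha_ == pytest.approx(alpha, rel=1e-5)
        assert fit.s_alpha_ == pytest.approx(s, rel=1e-5)
        assert fit.sigma_xi2_ == pytest.approx(xi, rel=1e-4, abs=1e-6)
        assert fit.sigma2_ == pytest.approx(s2, rel=1e-4)
        assert fit.loglik_ == pytest.approx(ll, abs=1e-5)

    def test_non_identifiable_kinship_rejected(self, rng):
        # singleton families make A = I: polygenic and residual confounded
        y, geno, K = simulate_fullsib_polygenic(30, 1, 0.1, rng=rng)
        with pytest.raises(ValueError, match="confounded"):
            FixedQTLModel(kinship=K).fit(geno.standardized, y)


class TestRandomModel:
    def test_moment_equivalence_without_polygene(self):
        """F2 single-marker data: REML variance = truncated moment estimate."""
        agree = 0
        reps = 40
        for r in range(reps):
            y, geno = simulate_f2_single_marker(50, 0.1, seed=[13, r])
            f = reml_fit_fixed_qtl(y, geno.standardized)
            m = reml_fit_random_qtl(y, geno.standardized)
            if abs(f.qtl_variance_ - m.sigma_alpha2_) <= 1e-4:
                agree += 1
        assert agree >= 0.95 * reps

    def test_sufficient_statistic_identity_with_polygene(self):
        """At the REML optimum sigma_alpha^2 = alpha_gls^2 - s_gls^2 exactly."""
        checked = 0
        for r in range(15):
            y, geno, K = simulate_fullsib_polygenic(10, 5, 0.15, seed=[21, r])
            m = reml_fit_random_qtl(y, geno.standardized, kinship=K)
            if m.boundary_:
                continue
            moment = max(m.alpha_gls_**2 - m.s_alpha_gls_**2, 0.0)
            assert m.sigma_alpha2_ == pytest.approx(moment, abs=1e-4)
            checked += 1
        assert checked >= 5

    def test_boundary_solution_flagged(self, rng):
        y, geno = simulate_f2_single_marker(60, 0.0, seed=5)
        m = reml_fit_random_qtl(y, geno.standardized)
        assert m.sigma_alpha2_ == 0.0
        assert m.boundary_

    def test_loglik_is_local_maximum(self, fullsib_data):
        y, geno, K = fullsib_data
        m = reml_fit_random_qtl(y, geno.standardized, kinship=K)
        z, A = geno.standardized, K.values
        n = len(y)
        X = np.ones((n, 1))

        def ll(theta):
            V = np.outer(z, z) * theta[0] + A * theta[1] + np.eye(n) * theta[2]
            return _reml.restricted_loglik(y, X, V)

        base = ll(m.theta_)
        assert base == pytest.approx(m.loglik_, abs=1e-6)
        for i in range(3):
            for sign in (+1, -1):
                pert = m.theta_.copy()
                pert[i] += sign * 1e-3
                if pert[i] < 0:
                    continue
                assert ll(pert) <= base + 1e-9

    def test_information_matches_finite_difference_hessian(self, fullsib_data):
        """Inverse covariance vs a numerical Hessian of the restricted likelihood."""
        y, geno, K = fullsib_data
        m = reml_fit_random_qtl(y, geno.standardized, kinship=K)
        assert not m.boundary_
        z, A = geno.standardized, K.values
        n = len(y)
        X = np.ones((n, 1))

        def ll(theta):
            V = np.outer(z, z) * theta[0] + A * theta[1] + np.eye(n) * theta[2]
            return _reml.restricted_loglik(y, X, V)

        h = 1e-4 * np.maximum(np.abs(m.theta_), 0.05)
        H = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                ei, ej = np.eye(3)[i] * h[i], np.eye(3)[j] * h[j]
                H[i, j] = (
                    ll(m.theta_ + ei + ej)
                    - ll(m.theta_ + ei - ej)
                    - ll(m.theta_ - ei + ej)
                    + ll(m.theta_ - ei - ej)
                ) / (4 * h[i] * h[j])
        cov_fd = np.linalg.inv(-H)
        # expected vs observed information: agree within 5% relative on the SEs
        np.testing.assert_allclose(
            np.sqrt(np.diag(m.theta_cov_)), np.sqrt(np.diag(cov_fd)), rtol=0.05
        )

    def test_delta_se_available_for_interior_fit(self, fullsib_data):
        y, geno, K = fullsib_data
        m = reml_fit_random_qtl(y, geno.standardized, kinship=K)
        assert m.h2_se_ > 0
        assert 0 <= m.h2_ <= 1

    def test_sklearn_params_round_trip(self):
        m = RandomQTLModel(standardize=False, marker_name="bin7")
        params = m.get_params()
        assert params["standardize"] is False
        m2 = RandomQTLModel().set_params(**params)
        assert m2.marker_name == "bin7"


class TestNullAndTests:
    def test_null_is_ols_limit_on_noise(self, rng):
        y = rng.normal(2.0, 1.5, 80)
        comps, ll = reml_fit_null(y)
        resid = y - y.mean()
        assert comps["sigma2"] == pytest.approx(resid @ resid / 79, abs=1e-10)
        assert comps["sigma_xi2"] is None

    def test_null_never_beats_alternative(self, rng):
        for r in range(5):
            y, geno = simulate_f2_single_marker(40, 0.1, seed=[31, r])
            _, ll0 = reml_fit_null(y)
            fit = reml_fit_fixed_qtl(y, geno.standardized)
            lrt = likelihood_ratio_test(ll0, fit.loglik_)
            assert lrt >= 0

    def test_lrt_rice_arithmetic(self):
        assert likelihood_ratio_test(-464.4, -455.05) == pytest.approx(18.7, abs=1e-9)
        assert likelihood_ratio_test(-10.0, -10.0) == 0.0

    def test_wald_examples(self):
        W, p = wald_test(0.5278, 0.1122)
        assert W == pytest.approx((0.5278 / 0.1122) ** 2, abs=1e-10)
        W0, p0 = wald_test(0.0, 0.1)
        assert (W0, p0) == (0.0, 1.0)
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)

    def test_bonferroni_threshold_mouse_design(self):
        assert bonferroni_wald_threshold(193, 0.05) == pytest.approx(13.34533, abs=1e-5)
        assert bonferroni_wald_threshold(1, 1.0) == 0.0

    def test_bonferroni_against_root_finding_oracle(self):
        # independent inversion of the chi-square CDF
        target = 1 - 0.05
        root = optimize.brentq(lambda x: stats.chi2.cdf(x, 1) - target, 0, 100)
        assert bonferroni_wald_threshold(1, 0.05) == pytest.approx(root, abs=1e-8)
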