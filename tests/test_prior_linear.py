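"""Prior-penalized ridge and logistic fits against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from comet.prior_linear import (GAMMAS, LOGISTIC_CS, RIDGE_LAMBDAS,
                                DesignMatrix, PriorCoefficients,
                                build_design, cv_select, fit_prior_logistic,
                                fit_prior_ridge, prior_from_pretraining)


def design(X, y, groups=None):
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return DesignMatrix(X=X, y=y,
                        feature_names=[f"f{j}" for j in range(X.shape[1])],
                        groups=(np.arange(len(y)).astype(str)
                                if groups is None else np.asarray(groups)))


class TestRidgeClosedForm:
    def test_printed_one_feature_cases(self):
        """The hand-derivable fits on X=[[1],[2]], y=(1,2), lam=1, gamma=1:
        beta = (5+1)^-1 (5+0) = 5/6 for beta0=0 and (5+1)^-1 (5+1) = 1 for
        beta0=1."""
        D = design([[1.0], [2.0]], [1.0, 2.0])
        b0, _ = fit_prior_ridge(D, np.array([0.0]), 1.0, 1.0,
                                fit_intercept=False)
        assert b0[0] == pytest.approx(5 / 6, abs=1e-12)
        b1, _ = fit_prior_ridge(D, np.array([1.0]), 1.0, 1.0,
                                fit_intercept=False)
        assert b1[0] == pytest.approx(1.0, abs=1e-12)

    def test_gamma_zero_equals_standard_ridge(self, rng):
        X = rng.standard_normal((15, 4))
        y = rng.standard_normal(15)
        D = design(X, y)
        b_any, _ = fit_prior_ridge(D, rng.standard_normal(4), 10.0, 0.0)
        b_zero, _ = fit_prior_ridge(D, np.zeros(4), 10.0, 0.0)
        assert np.allclose(b_any, b_zero)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_iterative_minimizer(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(5, 21), rng.integers(1, 8)
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        beta0 = rng.standard_normal(p)
        lam = float(rng.choice(RIDGE_LAMBDAS))
        gamma = float(rng.choice(GAMMAS))
        D = design(X, y)

        def objective(b):
            return (np.sum((D.y - X @ b) ** 2)
                    + lam * np.sum((b - gamma * beta0) ** 2))

        beta, _ = fit_prior_ridge(D, beta0, lam, gamma, fit_intercept=False)
        res = minimize(objective, np.zeros(p), method="BFGS",
                       options={"gtol": 1e-10})
        denom = max(1.0, np.linalg.norm(res.x))
        assert np.linalg.norm(beta - res.x) / denom <= 1e-6

    def test_prior_pull_monotone_in_lambda(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        beta0 = rng.standard_normal(3)
        D = design(X, y)
        dists = [np.linalg.norm(fit_prior_ridge(D, beta0, lam, 1.0)[0] - beta0)
                 for lam in RIDGE_LAMBDAS]
        assert all(a >= b - 1e-10 for a, b in zip(dists, dists[1:]))

    def test_nonfinite_inputs_rejected(self):
        D = design([[1.0], [np.nan]], [0.0, 1.0])
        with pytest.raises(ValueError):
            fit_prior_ridge(D, np.zeros(1), 1.0, 0.0)


class TestLogistic:
    def make(self, seed=0, n=40, p=3):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        beta_true = rng.standard_normal(p)
        y = (rng.random(n) < expit(X @ beta_true)).astype(float)
        return design(X, y), rng.standard_normal(p)

    @pytest.mark.parametrize("seed", range(5))
    def test_converged_fit_has_tiny_penalized_gradient(self, seed):
        D, beta0 = self.make(seed)
        C, gamma = 1e-2, 0.5
        beta, icept, conv = fit_prior_logistic(D, beta0, C, gamma)
        assert conv
        mu = expit(D.X @ beta + icept)
        g = D.X.T @ (mu - D.y) + (beta - gamma * beta0) / C
        assert np.sqrt(np.sum(g**2) + np.sum(mu - D.y) ** 2) < 1e-6

    def test_gradient_matches_numerical_oracle(self):
        """The analytic penalized gradient at the optimum agrees with a
        central-difference gradient of the objective."""
        D, beta0 = self.make(3)
        C, gamma = 1e-3, 1.0
        beta, icept, conv = fit_prior_logistic(D, beta0, C, gamma)
        assert conv

        def objective(b):
            eta = D.X @ b + icept
            nll = np.sum(np.logaddexp(0, eta) - D.y * eta)
            return nll + 0.5 / C * np.sum((b - gamma * beta0) ** 2)

        eps = 1e-6
        num = np.array([
            (objective(beta + eps * e) - objective(beta - eps * e)) / (2 * eps)
            for e in np.eye(len(beta))])
        assert np.abs(num).max() < 1e-3

    def test_strong_penalty_pulls_to_scaled_prior(self):
        D, beta0 = self.make(1)
        gamma = 0.75
        dists = [np.linalg.norm(
            fit_prior_logistic(D, beta0, C, gamma)[0] - gamma * beta0)
            for C in sorted(LOGISTIC_CS, reverse=True)]
        assert all(a >= b - 1e-8 for a, b in zip(dists, dists[1:]))
        assert dists[-1] < 1e-4  # C = 1e-8 pins beta at gamma*beta0

    def test_sign_follows_association(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        beta, _, _ = fit_prior_logistic(design(X, y), np.zeros(1), 1e-2, 0.0)
        assert beta[0] > 0


class TestDesignAndCV:
    def test_variance_filter_and_standardization(self, tiny_bundle):
        bundle, _ = tiny_bundle
        D = build_design(bundle.omics, bundle.analyte_names)
        assert np.allclose(D.X.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(D.X.std(axis=0), 1, atol=1e-10)
        assert all(n.startswith(("ehr:", "omics:")) for n in D.feature_names)

    def test_rare_codes_filtered_by_raw_variance(self):
        from comet.cohort_io import PatientRecord
        recs = []
        for i in range(100):
            codes = ["common"] if i % 2 else ["common", "alsocommon"]
            if i == 0:
                codes.append("rare")  # occurrence prob 1% -> var ~0.0099
            recs.append(PatientRecord(
                patient_id=f"p{i}", windowed_events=[(0, codes)],
                outcome=0.0, cohort="pretraining"))
        D = build_design(recs, analyte_names=[])
        assert "ehr:rare" not in D.feature_names
        assert "ehr:alsocommon" in D.feature_names

    def test_single_point_grid_and_grouped_folds(self, rng):
        X = rng.standard_normal((30, 3))
        y = X @ np.array([1.0, -1.0, 0.5]) + 0.1 * rng.standard_normal(30)
        groups = np.repeat([f"p{i}" for i in range(15)], 2)
        D = design(X, y, groups)
        prior = PriorCoefficients(values=np.zeros(3),
                                  from_pretraining=np.zeros(3, bool))
        out = cv_select(D, prior, "regression", lambdas=(1.0,), gammas=(0.0,))
        assert out["strength"] == 1.0 and out["gamma"] == 0.0
        assert np.isfinite(out["predictions"]).all()

    def test_prior_from_pretraining_zero_fills_unseen_features(self,
                                                               tiny_bundle):
        bundle, _ = tiny_bundle
        D = build_design(bundle.omics, bundle.analyte_names)
        prior = prior_from_pretraining(bundle.pretraining, D.feature_names,
                                       "regression")
        omics_cols = [i for i, f in enumerate(D.feature_names)
                      if f.startswith("omics:")]
        assert np.all(prior.values[omics_cols] == 0)
        assert not prior.from_pretraining[omics_cols].any()

    def test_informative_prior_helps_at_small_n(self):
        """With beta0 equal to the true coefficients and little data, the
        prior-pulled fit beats the gamma = 0 fit out of sample."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p, n = 12, 14
            beta_true = rng.standard_normal(p)
            X = rng.standard_normal((n, p))
            y = X @ beta_true + 0.3 * rng.standard_normal(n)
            Xte = rng.standard_normal((200, p))
            yte = Xte @ beta_true + 0.3 * rng.standard_normal(200)
            D = design(X, y - y.mean())
            b_prior, _ = fit_prior_ridge(D, beta_true, 25.0, 1.0)
            b_plain, _ = fit_prior_ridge(D, beta_true, 25.0, 0.0)
            rmse = lambda b: np.sqrt(np.mean((Xte @ b - (yte - y.mean()))**2))
            wins += rmse(b_prior) < rmse(b_plain)
        assert wins >= 4
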