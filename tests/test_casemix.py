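"""Outcome model, standardization, factor effects, and the multilevel ICC."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit

from actbench import (
    GeneratorConfig,
    adjusted_hospital_rates,
    factor_effect,
    fit_outcome_model,
    generate_cohort,
    indirect_standardize,
    multilevel_icc,
    null_config,
)
from actbench.casemix import _glmm_nll_grad, fit_random_intercept_logit
from actbench.errors import ModelError, SeparationError

from conftest import counts_cohort, make_hospitals, make_patients


class TestFitOutcomeModel:
    def test_null_effects_recovered_near_zero(self):
        # no covariate effects: every non-intercept coefficient within 3 SE of 0
        cfg = null_config(seed=21, n_patients=20_000, n_hospitals=20,
                          hospital_size_profile="uniform",
                          small_hospitals=0, small_patients=0)
        cohort, _ = generate_cohort(cfg)
        model = fit_outcome_model(cohort)
        frame = model.summary_frame().drop(index="const")
        z = frame["coef"] / frame["se"]
        assert (z.abs() < 3).all(), frame[z.abs() >= 3]

    def test_known_gradients_recovered(self, study_cohort):
        cohort, truth = study_cohort
        model = fit_outcome_model(cohort)
        frame = model.summary_frame()
        for cov, effects in truth.covariate_log_odds.items():
            for level, beta in effects.items():
                if beta == 0.0:
                    continue
                row = frame.loc[f"{cov}[{level}]"]
                assert abs(row["coef"] - beta) < 4 * row["se"]

    def test_perfect_separation_raises(self):
        rows = [{"grade": "unstated", "treated": 1} for _ in range(5)]
        rows += [{"grade": "well-moderate", "treated": t} for t in (0, 1) * 10]
        cohort = counts_cohort([("A", 1, 1)])  # placeholder, rebuilt below
        patients = make_patients(rows)
        from actbench import Cohort

        cohort = Cohort(patients, make_hospitals(["H1"]))
        with pytest.raises(SeparationError) as err:
            fit_outcome_model(cohort, covariates=["grade"])
        assert err.value.covariate == "grade"

    def test_constant_outcome_raises(self):
        cohort = counts_cohort([("A", 10, 10)])
        with pytest.raises(ModelError):
            fit_outcome_model(cohort, covariates=[])

    def test_intercept_only_model_predicts_pooled_rate(self):
        cohort = counts_cohort([("A", 40, 30), ("B", 60, 30)])
        model = fit_outcome_model(cohort, covariates=[])
        p = model.predict(cohort.patients)
        assert p == pytest.approx(np.full(100, 0.6), abs=1e-6)


class TestAdjustedRates:
    def test_indirect_standardization_arithmetic(self):
        assert indirect_standardize(0.80, 0.73, 0.66) == pytest.approx(0.7233, abs=5e-4)

    def test_intercept_only_adjusted_equals_observed(self):
        cohort = counts_cohort([("A", 50, 40), ("B", 50, 25), ("C", 40, 20)])
        model = fit_outcome_model(cohort, covariates=[])
        adj = adjusted_hospital_rates(cohort, model, bootstrap_reps=0)
        t = adj.table
        assert t["adjusted"].to_numpy() == pytest.approx(
            t["observed"].to_numpy(), abs=1e-6
        )

    def test_null_effects_adjusted_close_to_observed(self):
        cfg = null_config(seed=23, n_patients=3000, n_hospitals=30,
                          hospital_size_profile="uniform",
                          small_hospitals=0, small_patients=0)
        cohort, _ = generate_cohort(cfg)
        model = fit_outcome_model(cohort)
        adj = adjusted_hospital_rates(cohort, model, bootstrap_reps=400, seed=1)
        se = adj.draws.std(axis=1, ddof=1)
        diff = (adj.table["adjusted"] - adj.table["observed"]).abs().to_numpy()
        assert (diff <= 3 * np.maximum(se, 1e-3)).all()

    def test_adjustment_shrinks_toward_pooled_under_case_mix_confounding(self):
        # strong age effect + hospitals of small size => observed rates carry
        # case-mix noise the adjustment removes
        cohort, _ = generate_cohort(GeneratorConfig(seed=29))
        model = fit_outcome_model(cohort)
        adj = adjusted_hospital_rates(cohort, model, bootstrap_reps=0)
        t = adj.table[adj.table["n"] >= 10]
        mad_obs = (t["observed"] - adj.pooled_rate).abs().mean()
        mad_adj = (t["adjusted"] - adj.pooled_rate).abs().mean()
        assert mad_adj < mad_obs

    def test_bootstrap_ci_brackets_estimate(self, study_cohort):
        cohort, _ = study_cohort
        model = fit_outcome_model(cohort)
        adj = adjusted_hospital_rates(cohort, model, bootstrap_reps=300, seed=2)
        t = adj.table
        assert ((t["ci_low"] <= t["adjusted"]) & (t["adjusted"] <= t["ci_high"])).all()


class TestFactorEffect:
    def test_hand_computed_unadjusted_rr(self):
        cohort = counts_cohort(
            [("A", 50, 30), ("B", 100, 40)], flags={"teaching": [1, 0]}
        )
        eff = factor_effect(cohort, "teaching", covariates=[], bootstrap_reps=0)
        assert eff.unadjusted_rr == pytest.approx(1.5, abs=1e-9)
        assert eff.unadjusted_rates == {0: 0.4, 1: 0.6}

    def test_identical_rates_give_rr_one(self):
        cohort = counts_cohort(
            [("A", 50, 30), ("B", 100, 60)], flags={"teaching": [1, 0]}
        )
        eff = factor_effect(cohort, "teaching", covariates=[], bootstrap_reps=0)
        assert eff.unadjusted_rr == pytest.approx(1.0, abs=1e-9)

    def test_no_covariates_adjusted_equals_unadjusted(self):
        cohort = counts_cohort(
            [("A", 60, 45), ("B", 90, 45)], flags={"cancer_centre": [1, 0]}
        )
        eff = factor_effect(cohort, "cancer_centre", covariates=[], bootstrap_reps=0)
        assert eff.adjusted_rr == pytest.approx(eff.unadjusted_rr, abs=1e-6)
        assert eff.adjusted_rates[1] == pytest.approx(eff.unadjusted_rates[1], abs=1e-6)

    def test_constant_factor_raises(self):
        cohort = counts_cohort([("A", 10, 5), ("B", 10, 5)])
        with pytest.raises(ModelError, match="constant"):
            factor_effect(cohort, "teaching")

    def test_rr_ci_brackets_point(self, study_cohort):
        cohort, _ = study_cohort
        eff = factor_effect(cohort, "teaching", bootstrap_reps=300, seed=3)
        assert eff.unadjusted_rr_ci[0] < eff.unadjusted_rr < eff.unadjusted_rr_ci[1]
        assert eff.adjusted_rr_ci[0] < eff.adjusted_rr < eff.adjusted_rr_ci[1]


class TestRandomInterceptLogit:
    @staticmethod
    def _toy():
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        y = rng.integers(0, 2, size=12).astype(float)
        groups = np.repeat([0, 1, 2], 4)
        return X, y, groups

    def _quad_loglik(self, X, y, groups, beta, sigma):
        """Independent oracle: marginal log-likelihood by adaptive quadrature."""
        total = 0.0
        for g in np.unique(groups):
            Xg, yg = X[groups == g], y[groups == g]

            def integrand(u):
                eta = Xg @ beta + u
                p = expit(eta)
                like = np.prod(p**yg * (1 - p) ** (1 - yg))
                return like * np.exp(-0.5 * u**2 / sigma**2) / (
                    sigma * np.sqrt(2 * np.pi)
                )

            val, _ = quad(integrand, -10 * sigma, 10 * sigma, limit=200)
            total += np.log(val)
        return total

    @pytest.mark.parametrize("sigma", [0.3, 1.0, 2.0])
    def test_quadrature_matches_numerical_integration(self, sigma):
        X, y, groups = self._toy()
        beta = np.array([0.4, -0.7])
        order = np.argsort(groups)
        starts = np.array([0, 4, 8])
        xg, w = np.polynomial.hermite.hermgauss(60)
        z = np.sqrt(2.0) * xg
        logw = np.log(w) - 0.5 * np.log(np.pi)
        theta = np.concatenate([beta, [np.log(sigma)]])
        nll, _ = _glmm_nll_grad(theta, X[order], y[order], starts, z, logw)
        assert -nll == pytest.approx(self._quad_loglik(X, y, groups, beta, sigma),
                                     rel=1e-6)

    def test_analytic_gradient_matches_finite_differences(self):
        X, y, groups = self._toy()
        starts = np.array([0, 4, 8])
        xg, w = np.polynomial.hermite.hermgauss(25)
        z, logw = np.sqrt(2.0) * xg, np.log(w) - 0.5 * np.log(np.pi)
        theta = np.array([0.2, -0.5, np.log(0.8)])
        _, grad = _glmm_nll_grad(theta, X, y, starts, z, logw)
        eps = 1e-6
        for j in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            fd = (
                _glmm_nll_grad(tp, X, y, starts, z, logw)[0]
                - _glmm_nll_grad(tm, X, y, starts, z, logw)[0]
            ) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_icc_null_near_zero(self, study_cohort):
        cohort, _ = study_cohort  # generated with hospital_sd = 0
        res = multilevel_icc(cohort)
        assert res.converged
        assert res.icc < 0.02

    def test_icc_half_at_latent_variance(self):
        # sigma_u^2 = pi^2/3 puts half the latent variance between hospitals
        sd = np.sqrt(np.pi**2 / 3)
        cfg = null_config(seed=31, n_patients=9000, n_hospitals=150,
                          hospital_size_profile="uniform", hospital_sd=sd,
                          small_hospitals=0, small_patients=0)
        cohort, _ = generate_cohort(cfg)
        res = multilevel_icc(cohort, covariates=[])
        assert res.icc == pytest.approx(0.5, abs=0.08)

    def test_sigma2_recovery_with_wald_ci(self):
        cfg = GeneratorConfig(seed=37, hospital_sd=0.5)
        cohort, _ = generate_cohort(cfg)
        res = multilevel_icc(cohort)
        lo, hi = res.sigma2_ci
        assert np.isfinite(lo) and np.isfinite(hi)
        assert lo < 0.25 < hi
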