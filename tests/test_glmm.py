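import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from agiwear.glmm import (agq_loglik, build_design, fit_glmm, laplace_loglik,
                          run_feature_screen)


def simulate_glmm(rng, n_groups=10, n_per=15, beta=(-0.5, 0.5), sigma=1.0):
    groups = np.repeat(np.arange(n_groups), n_per)
    n = groups.size
    z = rng.normal(0, 1, n)
    X = np.column_stack([np.ones(n), z])
    u = rng.normal(0, sigma, n_groups)
    y = (rng.random(n) < expit(X @ np.asarray(beta) + u[groups])).astype(float)
    return X, y, groups


class TestMarginalLoglik:
    def test_sigma_zero_equals_plain_logistic(self, rng):
        X, y, groups = simulate_glmm(rng)
        res = sm.Logit(y, X).fit(disp=0)
        ll = laplace_loglik(res.params, 0.0, X, y, groups, 10)
        assert ll == pytest.approx(res.llf, abs=1e-10)

    def test_single_patient_two_obs_matches_quadrature(self):
        X = np.array([[1.0, 0.5], [1.0, -1.0]])
        y = np.array([1.0, 0.0])
        groups = np.array([0, 0])
        beta = np.array([0.3, -0.4])
        la = laplace_loglik(beta, 1.0, X, y, groups, 1)
        gh = agq_loglik(beta, 1.0, X, y, groups, 1)
        assert la == pytest.approx(gh, abs=1e-3)

    def test_oracle_equivalence_small_instances(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(30):
            n_g = int(rng.integers(2, 6))
            n_per = int(rng.integers(4, 11))
            X, y, groups = simulate_glmm(
                rng, n_g, n_per, beta=rng.uniform(-2, 2, 2),
                sigma=float(rng.uniform(0.2, 2.0)))
            if len(np.unique(y)) < 2:
                continue
            sigma = float(rng.uniform(0.2, 2.0))
            beta = rng.uniform(-2, 2, 2)
            d = abs(laplace_loglik(beta, sigma, X, y, groups, n_g)
                    - agq_loglik(beta, sigma, X, y, groups, n_g))
            worst = max(worst, d)
        assert worst < 1e-2

    def test_nonfinite_parameters_rejected(self, rng):
        X, y, groups = simulate_glmm(rng)
        with pytest.raises(ValueError):
            laplace_loglik(np.array([np.nan, 0.0]), 1.0, X, y, groups, 10)


class TestFit:
    def test_local_optimality(self, rng):
        X, y, groups = simulate_glmm(rng, n_groups=15, n_per=20)
        fit = fit_glmm(X, y, groups)
        ll_hat = laplace_loglik(fit.beta, fit.sigma_u, X, y, groups, 15)
        for delta in ([0.05, 0], [0, 0.05], [-0.05, 0.02]):
            ll_pert = laplace_loglik(fit.beta + delta, fit.sigma_u, X, y,
                                     groups, 15)
            assert ll_hat >= ll_pert - 1e-9

    def test_sigma_zero_limit_matches_glm_coefficients(self, rng):
        X, y, groups = simulate_glmm(rng, sigma=0.0)
        fit = fit_glmm(X, y, groups, sigma_bounds=(0.0, 1e-9))
        res = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.beta, res.params, atol=1e-4)

    def test_single_class_outcome_rejected(self, rng):
        X, y, groups = simulate_glmm(rng)
        with pytest.raises(ValueError, match="single class"):
            fit_glmm(X, np.zeros_like(y), groups)

    def test_single_patient_rejected(self, rng):
        X, y, _ = simulate_glmm(rng, n_groups=1, n_per=30)
        with pytest.raises(ValueError, match="2 patients"):
            fit_glmm(X, y, np.zeros(30, dtype=int))

    def test_complete_separation_flagged(self):
        rng = np.random.default_rng(5)
        n = 80
        groups = np.repeat(np.arange(4), 20)
        z = rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), z])
        y = (z > 0).astype(float)  # perfectly separable
        fit = fit_glmm(X, y, groups)
        assert not fit.converged
        assert fit.flag == "separation"


class TestFeatureScreen:
    def _analysis(self, rng, n_patients=6, n_surveys=30):
        rows = []
        for p in range(n_patients):
            pid = f"P{p:02d}"
            for s in range(n_surveys):
                sid = f"{pid}-{s}"
                tg = int(rng.integers(1, 5))
                out = int(rng.random() < 0.3)
                for series, modality in (("acc_magnitude", "acc"),
                                         ("hr", "hr"), ("eda_tonic", "eda")):
                    for feat in ("median", "sd"):
                        rows.append({
                            "survey_id": sid, "patient_id": pid,
                            "modality": modality, "series": series,
                            "feature": feat, "z": rng.normal(),
                            "time_group": tg, "agitated": out,
                            "motor_agitated": out, "verbal_agitated": 0,
                            "ambient_mean": rng.normal(),
                            "acc_sd": rng.normal(),
                        })
        return pd.DataFrame(rows)

    def test_counts_and_confounder_mapping(self, rng):
        fits = run_feature_screen(self._analysis(rng))
        # 3 series x 2 features x 3 outcomes
        assert len(fits) == 18
        assert (fits.loc[fits["series"] == "hr", "confounder"] == "acc_sd").all()
        assert (fits.loc[fits["series"] == "eda_tonic", "confounder"]
                == "ambient_mean").all()
        assert (fits.loc[fits["series"] == "acc_magnitude", "confounder"]
                == "").all()

    def test_degenerate_outcome_flagged_not_fitted(self, rng):
        fits = run_feature_screen(self._analysis(rng))
        verbal = fits[fits["outcome"] == "verbal_agitated"]
        assert (verbal["flag"] == "degenerate_data").all()
        assert verbal["beta"].isna().all()

    def test_output_deterministically_sorted(self, rng):
        a = self._analysis(rng)
        fits = run_feature_screen(a)
        resorted = fits.sort_values(["modality", "series", "feature",
                                     "outcome"], ignore_index=True)
        assert fits.equals(resorted)

    def test_design_matrix_treatment_coding(self):
        rows = pd.DataFrame({"z": [0.1, 0.2, 0.3, 0.4],
                             "time_group": [1, 2, 3, 4]})
        X, terms = build_design(rows)
        assert terms == ["intercept", "feature", "time_group[2]",
                         "time_group[3]", "time_group[4]"]
        # block 1 is the reference: its row has no time-group indicator
        assert np.array_equal(X[0, 2:], [0, 0, 0])
        assert np.array_equal(X[3, 2:], [0, 0, 1])
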