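"""Mixed cumulative-probit estimation: oracles, recovery, model comparison."""

import numpy as np
import pandas as pd
import pytest

from metastair.ordinal import (
    CumulativeProbitMixed,
    compare_aic,
    fit_cumulative_probit,
    subject_coefficient_test,
)
from metastair.simulate import ObserverParams, simulate_confidence_dataset


def _null_params(**kw):
    base = dict(meta_noise_im=0.0, meta_noise_wm=0.0)
    base.update(kw)
    return ObserverParams(**base)


@pytest.fixture(scope="module")
def model1_fit():
    rng = np.random.default_rng(31)
    data = simulate_confidence_dataset(
        40, 200, params=_null_params(sigma_u=0.5), rng=rng
    )
    return data, fit_cumulative_probit(data, model="model1", n_quad=15)


class TestPooledOracle:
    def test_sigma_zero_matches_pooled_ml(self):
        """With no subject heterogeneity the mixed fit must agree with an
        independent pooled cumulative-probit ML fit (statsmodels)."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(21)
        data = simulate_confidence_dataset(
            30, 150, params=_null_params(sigma_u=0.0), rng=rng
        )
        fit = fit_cumulative_probit(data, model="model1")
        X = pd.DataFrame(
            {
                "IM": (data["condition"] == "IM").astype(float),
                "nItems": data["n_items"].astype(float),
                "accuracy": data["correct"].astype(float),
            }
        )
        oracle = OrderedModel(
            data["confidence"].astype(int), X, distr="probit"
        ).fit(method="bfgs", disp=False)
        for name in ("IM", "nItems", "accuracy"):
            assert fit.params[name] == pytest.approx(
                oracle.params[name], abs=1e-3
            )
        # the variance estimate collapses towards zero; the finite-sample
        # MLE can sit at a tiny positive value, so the marginal likelihood
        # may exceed the pooled one by a sliver but never fall below it
        assert fit.re_sd < 0.1
        assert -1e-6 <= fit.llf - oracle.llf < 0.05

    def test_predicted_probabilities_sum_to_one(self, model1_fit):
        data, fit = model1_fit
        m = CumulativeProbitMixed(
            data["confidence"].astype(int),
            np.column_stack(
                [
                    (data["condition"] == "IM").astype(float),
                    data["n_items"],
                    data["correct"],
                ]
            ),
            data["subject_id"],
        )
        probs = m.predict_proba(fit.packed_params)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(probs >= 0)

    def test_quadrature_node_count_converged(self, model1_fit):
        data, fit = model1_fit
        m = CumulativeProbitMixed(
            data["confidence"].astype(int),
            np.column_stack(
                [
                    (data["condition"] == "IM").astype(float),
                    data["n_items"],
                    data["correct"],
                ]
            ),
            data["subject_id"],
            n_quad=20,
        )
        l20 = m.loglike(fit.packed_params)
        l50 = m.loglike(fit.packed_params, n_quad=50)
        assert abs(l20 - l50) / m.nobs < 1e-4

    def test_threshold_shift_is_absorbed(self, model1_fit):
        """Shifting all thresholds and adding the same constant to the
        latent mean leaves the likelihood unchanged (identifiability)."""
        data, fit = model1_fit
        m = CumulativeProbitMixed(
            data["confidence"].astype(int),
            np.column_stack(
                [
                    (data["condition"] == "IM").astype(float),
                    data["n_items"],
                    np.ones(len(data)),  # constant column absorbs the shift
                ]
            ),
            data["subject_id"],
        )
        p = fit.packed_params.copy()
        base = m.loglike(p)
        shifted = p.copy()
        shifted[2] += 0.7  # constant-column coefficient
        shifted[3] += 0.7  # tau_1 (others follow via log-diffs)
        assert m.loglike(shifted) == pytest.approx(base, abs=1e-6)


class TestRecovery:
    def test_wald_type_i_error(self):
        """beta_IM = 0 generator: Wald rejections near the nominal rate."""
        rng = np.random.default_rng(41)
        params = _null_params(beta_im=0.0, sigma_u=0.4)
        rejections = 0
        reps = 40
        for _ in range(reps):
            data = simulate_confidence_dataset(30, 100, params=params, rng=rng)
            fit = fit_cumulative_probit(data, model="model1", n_quad=7)
            rejections += fit.pvalues["IM"] < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate < 0.05 + 3 * se

    def test_sigma_near_zero_recovered(self):
        rng = np.random.default_rng(51)
        data = simulate_confidence_dataset(
            20, 120, params=_null_params(sigma_u=0.0), rng=rng
        )
        fit = fit_cumulative_probit(data, model="model1")
        assert fit.re_sd < 0.1  # at or near the sigma = 0 boundary


class TestModelComparison:
    def test_aic_of_fit_vs_itself_is_zero(self, model1_fit):
        _, fit = model1_fit
        cmp = compare_aic(fit, fit)
        assert cmp.delta == 0.0

    def test_mismatched_nobs_rejected(self, model1_fit):
        _, fit = model1_fit
        rng = np.random.default_rng(3)
        other = fit_cumulative_probit(
            simulate_confidence_dataset(5, 40, params=_null_params(), rng=rng),
            model="model1",
        )
        with pytest.raises(ValueError):
            compare_aic(fit, other)

    def test_random_slope_generator_prefers_model3(self):
        """Heterogeneous subject slopes: the full-random-effects model wins
        the AIC comparison in (essentially) every replicate."""
        rng = np.random.default_rng(61)
        params = _null_params(sigma_u=0.5)
        wins = 0
        reps = 3
        for _ in range(reps):
            data = simulate_confidence_dataset(
                24,
                120,
                params=params,
                random_slope_sd={"accuracy": 0.6, "IM": 0.4},
                rng=rng,
            )
            f2 = fit_cumulative_probit(data, model="model2")
            f3 = fit_cumulative_probit(data, model="model3")
            wins += compare_aic(f2, f3, "m2", "m3").preferred == "m3"
        assert wins == reps

    def test_intercept_only_generator_prefers_smaller_model(self):
        rng = np.random.default_rng(71)
        data = simulate_confidence_dataset(
            24, 120, params=_null_params(sigma_u=0.5), rng=rng
        )
        f2 = fit_cumulative_probit(data, model="model2")
        f3 = fit_cumulative_probit(data, model="model3")
        assert compare_aic(f2, f3, "m2", "m3").preferred == "m2"


@pytest.fixture(scope="module")
def model3_fit():
    rng = np.random.default_rng(81)
    data = simulate_confidence_dataset(
        20,
        100,
        params=_null_params(sigma_u=0.5),
        random_slope_sd={"IM": 0.3, "accuracy": 0.3},
        rng=rng,
    )
    return fit_cumulative_probit(data, model="model3")


class TestSubjectCoefficientTest:

    def test_df_is_subjects_minus_one(self, model3_fit):
        res = subject_coefficient_test(model3_fit, "IM")
        assert res.df == 19

    def test_strong_mean_slope_detected(self, model3_fit):
        # accuracy has a large positive mean coefficient
        res = subject_coefficient_test(model3_fit, "accuracy")
        assert res.significant
        assert res.mean_difference > 0.5

    def test_term_without_random_component_rejected(self, model1_fit):
        _, fit = model1_fit
        with pytest.raises(ValueError):
            subject_coefficient_test(fit, "nItems")


class TestCorrelatedPredictors:
    def test_high_im_nitems_correlation_still_covered(self):
        """Point-biserial correlation 0.77 between condition and set size:
        the Wald CI still covers the true coefficients (robustness check,
        small-scale; the full-design coverage sweep is in the acceptance
        suite)."""
        rng = np.random.default_rng(91)
        params = _null_params(
            beta_im=-0.1, beta_nitems=-0.12, beta_accuracy=1.3, sigma_u=0.5
        )
        true = {"IM": -0.1, "nItems": -0.12, "accuracy": 1.3}
        covered = {k: 0 for k in true}
        reps = 10
        for _ in range(reps):
            data = simulate_confidence_dataset(
                50, 200, params=params, rho_im_nitems=0.77, rng=rng
            )
            fit = fit_cumulative_probit(data, model="model1", n_quad=7)
            ci = fit.conf_int()
            for k, v in true.items():
                covered[k] += ci.loc[k, "lower"] <= v <= ci.loc[k, "upper"]
        for k, c in covered.items():
            assert c >= 8, f"{k}: {c}/{reps} covered"
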