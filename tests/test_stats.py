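"""Paired t, effect-size convention, TOST, partial eta squared, set-size controls."""

import numpy as np
import pytest

from metastair.preprocess import preprocess
from metastair.roc import subject_summaries
from metastair.stats import (
    cohens_d_from_t,
    paired_t,
    partial_eta_sq,
    setsize_variability_analysis,
    tost_paired,
)


class TestPairedT:
    def test_identical_samples_degenerate(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_sign_follows_mean_difference(self, rng):
        x = rng.normal(0.5, 1.0, 40)
        y = rng.normal(0.0, 1.0, 40)
        res = paired_t(x, y)
        assert np.sign(res.statistic) == np.sign(res.mean_difference)

    def test_matches_textbook_formula(self, rng):
        from scipy.stats import t as tdist

        x = rng.normal(0.2, 1.0, 25)
        y = rng.normal(0.0, 1.2, 25)
        res = paired_t(x, y)
        d = x - y
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_manual = 2 * tdist.sf(abs(t_manual), len(d) - 1)
        assert res.statistic == pytest.approx(t_manual, abs=1e-10)
        assert res.p_value == pytest.approx(p_manual, abs=1e-10)
        assert res.df == len(d) - 1

    def test_type_i_error_calibrated(self):
        # vectorized null simulation: rejection rate ~ alpha
        rng = np.random.default_rng(99)
        reps, n, alpha = 10_000, 20, 0.05
        d = rng.normal(0.0, 1.0, size=(reps, n))
        t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
        from scipy.stats import t as tdist

        rate = (2 * tdist.sf(np.abs(t), n - 1) < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 2.5 * se


class TestCohensD:
    @pytest.mark.parametrize(
        "t,n,expected",
        [(4.68, 101, 0.47), (-3.22, 101, 0.32), (0.0, 50, 0.0)],
    )
    def test_study_convention(self, t, n, expected):
        assert round(cohens_d_from_t(t, n), 2) == expected

    def test_rejects_zero_n(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 0)


class TestTost:
    def test_tiny_effect_inside_bounds_is_equivalent(self, rng):
        x = rng.normal(0.0, 0.001, 200)
        y = x + rng.normal(0.0, 0.001, 200)
        res = tost_paired(x, y, -0.325, 0.325, standardized=True, alpha=0.025)
        assert res.p_value < 0.001
        assert res.significant

    def test_symmetric_bounds_order_invariant(self, rng):
        x = rng.normal(0.1, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        a = tost_paired(x, y, -0.4, 0.4)
        b = tost_paired(y, x, -0.4, 0.4)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_p_is_max_of_one_sided(self, rng):
        from scipy.stats import t as tdist

        x = rng.normal(0.05, 1.0, 40)
        y = rng.normal(0.0, 1.0, 40)
        res = tost_paired(x, y, -0.3, 0.3, standardized=True)
        d = x - y
        n = len(d)
        sd = d.std(ddof=1)
        se = sd / np.sqrt(n)
        p_lo = tdist.sf((d.mean() + 0.3 * sd) / se, n - 1)
        p_hi = tdist.cdf((d.mean() - 0.3 * sd) / se, n - 1)
        assert res.p_value == pytest.approx(max(p_lo, p_hi), abs=1e-12)

    def test_size_at_equivalence_boundary(self):
        # true standardized difference pinned at the upper bound: long-run
        # equivalence-claim rate approaches alpha (vectorized simulation)
        rng = np.random.default_rng(7)
        reps, n, b, alpha = 10_000, 100, 0.325, 0.05
        from scipy.stats import t as tdist

        d = rng.normal(b, 1.0, size=(reps, n))
        sd = d.std(axis=1, ddof=1)
        se = sd / np.sqrt(n)
        p_lo = tdist.sf((d.mean(axis=1) + b * sd) / se, n - 1)
        p_hi = tdist.cdf((d.mean(axis=1) - b * sd) / se, n - 1)
        rate = (np.maximum(p_lo, p_hi) < alpha).mean()
        se_rate = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 2.5 * se_rate

    def test_infinite_bounds_always_equivalent_tight_never(self, rng):
        x = rng.normal(0.3, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        wide = tost_paired(x, y, -100.0, 100.0, standardized=True)
        tight = tost_paired(x, y, -1e-9, 1e-9, standardized=True)
        assert wide.significant
        assert not tight.significant

    def test_bad_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            tost_paired([1, 2, 3], [3, 2, 1], 0.3, -0.3)


class TestPartialEtaSq:
    def test_simple_values(self):
        assert partial_eta_sq(1.0, 1, 1) == 0.5
        assert partial_eta_sq(0.0, 3, 50) == 0.0

    def test_formula_oracle(self, rng):
        for _ in range(50):
            F = float(rng.uniform(0, 30))
            dfe = int(rng.integers(1, 10))
            dfr = int(rng.integers(2, 200))
            assert partial_eta_sq(F, dfe, dfr) == pytest.approx(
                F * dfe / (F * dfe + dfr), abs=1e-12
            )

    def test_negative_f_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_sq(-1.0, 1, 10)


class TestSetSizeVariability:
    @pytest.fixture()
    def analysis(self, small_cohort):
        kept, _ = preprocess(small_cohort)
        summaries = subject_summaries(kept)
        return setsize_variability_analysis(summaries, kept), summaries

    def test_components_present(self, analysis):
        res, _ = analysis
        assert res["sd_comparison"].kind == "paired_t"
        assert set(res["regression"]) == {"sd_items_z", "WM", "WM_x_sd"}
        assert res["modal_t"].alpha == 0.025
        assert res["modal_tost"].alpha == 0.025

    def test_wm_term_matches_two_group_fit_at_mean_sd(self, analysis):
        # at z-normalized sd = 0, the WM coefficient equals the fitted
        # condition gap; cross-check against an explicit normal-equations fit
        res, summaries = analysis
        import numpy.linalg as la

        z = (summaries["sd_items"] - summaries["sd_items"].mean()) / summaries[
            "sd_items"
        ].std(ddof=1)
        wm = (summaries["condition"] == "WM").astype(float).to_numpy()
        X = np.column_stack([np.ones(len(summaries)), z, wm, wm * z])
        beta = la.lstsq(X, summaries["auroc2"].to_numpy(), rcond=None)[0]
        assert res["regression"]["WM"].mean_difference == pytest.approx(
            beta[2], abs=1e-8
        )

    def test_modal_null_contrast_centres_on_zero(self):
        # equal meta-noise generator: modal-set-size AUROC-2 gap ~ 0
        from metastair.simulate import (
            ExperimentConfig,
            ObserverParams,
            simulate_experiment,
        )

        covered = 0
        cohorts = 6
        for seed in range(cohorts):
            obs = ObserverParams(meta_noise_im=0.0, meta_noise_wm=0.0)
            cfg = ExperimentConfig(n_subjects=12, seed=3000 + seed, observer=obs)
            kept, _ = preprocess(simulate_experiment(cfg))
            s = subject_summaries(kept)
            res = setsize_variability_analysis(s, kept)
            t = res["modal_t"]
            from scipy.stats import t as tdist

            half = tdist.ppf(0.975, t.df) * abs(
                t.mean_difference / t.statistic
            ) if t.statistic != 0 else np.inf
            covered += abs(t.mean_difference) <= half
        assert covered >= int(0.9 * cohorts)
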