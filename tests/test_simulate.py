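"""Observer model, staircase dynamics and the experiment generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metastair.simulate import (
    ExperimentConfig,
    ObserverParams,
    Staircase,
    generate_confidence,
    p_correct,
    simulate_confidence_dataset,
    simulate_experiment,
    staircase_fixed_point,
    staircase_update,
)


class TestPCorrect:
    def test_capacity_covers_display(self):
        assert p_correct(4, capacity=6, lapse=0.0) == 1.0

    def test_zero_capacity_is_positional_guessing(self):
        assert p_correct(8, capacity=0, lapse=0.0) == pytest.approx(1 / 8)

    def test_matches_slot_model_monte_carlo(self, rng):
        # brute-force slot observer: encode 4 of 8 items uniformly; guess
        # uniformly among the 8 positions when the probed item is unencoded
        n, cap, draws = 8, 4, 100_000
        encoded = rng.random(draws) < cap / n  # probed item among the 4 stored
        guess_right = rng.integers(0, n, draws) == 0
        hits = np.where(encoded, True, guess_right)
        mc = hits.mean()
        se = np.sqrt(mc * (1 - mc) / draws)
        assert abs(p_correct(n, cap, 0.0) - mc) < 3 * se

    @given(cap=st.floats(0.0, 16.0), lapse=st.floats(0.0, 0.2))
    @settings(max_examples=40, derandomize=True)
    def test_monotone_in_set_size(self, cap, lapse):
        vals = [p_correct(n, cap, lapse) for n in range(1, 17)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_rejects_empty_display(self):
        with pytest.raises(ValueError):
            p_correct(0, 4.0)


class TestStaircase:
    def test_one_up_one_down(self):
        s = Staircase("IM", 8)
        assert staircase_update(s, "correct").current_n_items == 9
        assert staircase_update(s, "incorrect").current_n_items == 7
        assert staircase_update(s, "no_response").current_n_items == 8

    def test_bounds_clamp(self):
        assert staircase_update(Staircase("IM", 16), "correct").current_n_items == 16
        assert staircase_update(Staircase("IM", 1), "incorrect").current_n_items == 1

    @given(
        outcomes=st.lists(
            st.sampled_from(["correct", "incorrect", "no_response"]),
            min_size=1,
            max_size=300,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_never_leaves_bounds(self, outcomes):
        s = Staircase("WM", 8)
        for o in outcomes:
            s.update(o)
            assert 1 <= s.current_n_items <= 16

    def test_fixed_point_increasing_in_capacity(self):
        pts = [staircase_fixed_point(c, 0.02) for c in (2, 3, 4, 5, 6)]
        assert all(a < b for a, b in zip(pts, pts[1:]))


class TestGenerateConfidence:
    def test_degenerate_thresholds_pin_lowest_level(self, rng):
        params = ObserverParams(tau=(50.0, 60.0, 70.0))
        draws = {
            generate_confidence(1, 8, "WM", 0.0, params, rng) for _ in range(200)
        }
        assert draws == {1}

    def test_matches_closed_form_cell_probabilities(self, rng):
        params = ObserverParams(meta_noise_im=0.0, meta_noise_wm=0.0)
        acc, n_items, cond, u = 1, 9, "IM", 0.3
        draws = np.array(
            [
                generate_confidence(acc, n_items, cond, u, params, rng)
                for _ in range(100_000)
            ]
        )
        from scipy.stats import norm

        eta = (
            params.beta_im + params.beta_nitems * n_items + params.beta_accuracy + u
        )
        cuts = np.concatenate([[-np.inf], params.tau, [np.inf]])
        probs = np.diff(norm.cdf(cuts - eta))
        for k in range(4):
            freq = (draws == k + 1).mean()
            se = np.sqrt(probs[k] * (1 - probs[k]) / len(draws))
            assert abs(freq - probs[k]) < 3 * max(se, 1e-4)

    def test_conditions_symmetric_when_beta_im_zero(self, rng):
        params = ObserverParams(
            beta_im=0.0, meta_noise_im=0.0, meta_noise_wm=0.0
        )
        n = 50_000
        im = np.array(
            [generate_confidence(1, 8, "IM", 0.0, params, rng) for _ in range(n)]
        )
        wm = np.array(
            [generate_confidence(1, 8, "WM", 0.0, params, rng) for _ in range(n)]
        )
        from scipy.stats import chi2_contingency

        table = np.array(
            [[np.sum(im == k), np.sum(wm == k)] for k in range(1, 5)]
        )
        assert chi2_contingency(table).pvalue > 0.01

    def test_nonincreasing_thresholds_rejected(self, rng):
        with pytest.raises(ValueError):
            ObserverParams(tau=(0.0, 0.0, 1.0))


class TestSimulateExperiment:
    def test_design_bookkeeping(self, small_cohort):
        per_session = small_cohort.groupby(["subject_id", "session"]).size()
        assert (per_session == 270).all()
        exp = small_cohort[small_cohort["phase"] == "experimental"]
        per_cond = exp.groupby(["subject_id", "session", "condition"]).size()
        assert (per_cond == 130).all()
        cfg = ExperimentConfig(n_subjects=12)
        assert cfg.valid_trials_per_subject == 400

    def test_seeded_runs_bit_reproducible(self):
        cfg = ExperimentConfig(n_subjects=2, seed=99)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_staircase_holds_accuracy_near_half(self, small_cohort):
        exp = small_cohort[
            (small_cohort["phase"] == "experimental")
            & (small_cohort["staircase_order"] > 30)
        ]
        acc = exp["correct"].astype(float).mean()
        assert 0.47 <= acc <= 0.53

    def test_capacity_contrast_drives_set_size(self):
        # strongly separated capacities: IM staircases should sit higher
        wins = 0
        cohorts = 10
        for seed in range(cohorts):
            obs = ObserverParams(capacity_im=6.0, capacity_wm=3.0)
            cfg = ExperimentConfig(n_subjects=8, seed=1000 + seed, observer=obs)
            df = simulate_experiment(cfg)
            exp = df[(df["phase"] == "experimental") & (df["staircase_order"] > 30)]
            means = exp.groupby("condition")["n_items"].mean()
            wins += means["IM"] > means["WM"]
        assert wins >= int(0.95 * cohorts)

    def test_confidence_only_with_confidence_rt(self, small_cohort):
        has_conf = small_cohort["confidence"].notna()
        has_rt = small_cohort["rt_confidence_s"].notna()
        assert (has_conf == has_rt).all()


class TestConfidenceDataset:
    def test_induced_im_nitems_correlation(self, rng):
        data = simulate_confidence_dataset(
            50, 300, rho_im_nitems=0.77, rng=rng
        )
        r = np.corrcoef(
            (data["condition"] == "IM").astype(float), data["n_items"]
        )[0, 1]
        assert r == pytest.approx(0.77, abs=0.05)

    def test_random_slopes_add_subject_variation(self, rng):
        params = ObserverParams(meta_noise_im=0.0, meta_noise_wm=0.0, sigma_u=0.0)
        data = simulate_confidence_dataset(
            40,
            200,
            params=params,
            random_slope_sd={"accuracy": 1.0},
            rng=rng,
        )
        # per-subject confidence gap between correct and incorrect trials
        gap = (
            data.groupby(["subject_id", "correct"])["confidence"]
            .mean()
            .unstack()
        )
        spread = (gap[1] - gap[0]).std()
        data0 = simulate_confidence_dataset(40, 200, params=params, rng=rng)
        gap0 = (
            data0.groupby(["subject_id", "correct"])["confidence"]
            .mean()
            .unstack()
        )
        assert spread > 2.0 * (gap0[1] - gap0[0]).std()
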