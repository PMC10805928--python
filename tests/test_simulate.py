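"""Generative simulator: staircase rule, trial sampling, session structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metaconf as mc
from metaconf.simulate import EXTREME, StaircaseState, records_to_frame, sample_trial


CFG = mc.SessionConfig()


class TestStaircase:
    @pytest.mark.parametrize(
        "majority, streak, correct, exp_majority, exp_streak",
        [
            (27, 1, True, 26, 0),   # second consecutive correct: harder
            (27, 0, True, 27, 1),   # first correct: count the streak
            (27, 0, False, 28, 0),  # error: easier
            (27, 1, False, 28, 0),  # error resets the streak
            (25, 1, True, 25, 0),   # clamped at the floor
            (39, 0, False, 39, 0),  # clamped at the ceiling
        ],
    )
    def test_two_up_one_down_rule(self, majority, streak, correct, exp_majority, exp_streak):
        state = StaircaseState(majority, streak)
        new = mc.staircase_update(state, correct, CFG)
        assert (new.majority_count, new.consecutive_correct) == (exp_majority, exp_streak)

    @given(st.lists(st.booleans(), min_size=1, max_size=300))
    @settings(deadline=None, max_examples=50)
    def test_majority_stays_within_bounds(self, outcomes):
        state = StaircaseState(CFG.staircase_start_majority)
        for correct in outcomes:
            state = mc.staircase_update(state, correct, CFG)
            assert CFG.min_majority <= state.majority_count <= CFG.ceiling
            assert state.consecutive_correct in (0, 1)


class TestSampleTrial:
    def test_deterministic_given_seed(self, observer):
        state = StaircaseState(27)
        r1 = sample_trial(observer, state, "X", np.random.default_rng(5), CFG)
        r2 = sample_trial(observer, state, "X", np.random.default_rng(5), CFG)
        assert r1 == r2

    def test_zero_meta_noise_forces_adjacent_second_rating(self):
        obs = mc.ObserverParams(meta_noise_sd_1=0.0, meta_noise_sd_2=0.0, meta_noise_corr=0.0)
        rng = np.random.default_rng(0)
        state = StaircaseState(27)
        seen_non_extreme = 0
        for _ in range(500):
            rec = sample_trial(obs, state, "X", rng, CFG)
            if rec.shift != EXTREME:
                seen_non_extreme += 1
                assert abs(rec.conf2 - rec.conf1) == 1
        assert seen_non_extreme > 100

    def test_insensitive_observer_is_at_chance(self):
        obs = mc.ObserverParams(sensitivity_slope=0.0)
        rng = np.random.default_rng(1)
        state = StaircaseState(30)
        correct = [
            sample_trial(obs, state, "X" if i % 2 else "O", rng, CFG).correct
            for i in range(10_000)
        ]
        # binomial 99.7% interval around 0.5 at n = 10,000 is +/- 0.015
        assert abs(np.mean(correct) - 0.5) < 0.015

    def test_invalid_imbalance_rejected(self, observer):
        bad_cfg = mc.SessionConfig(min_majority=25)
        with pytest.raises(ValueError, match="imbalance"):
            sample_trial(observer, StaircaseState(24), "X", np.random.default_rng(0), bad_cfg)

    def test_expected_accuracy_monotone_in_slope(self):
        accs = [
            mc.ObserverParams(sensitivity_slope=s).expected_accuracy(5)
            for s in np.linspace(0.0, 1.5, 40)
        ]
        assert np.all(np.diff(accs) >= 0)
        assert accs[0] == pytest.approx(0.5)


class TestSession:
    def test_default_session_structure(self, single_session):
        df = single_session
        assert len(df) == 450
        assert sorted(df["block"].unique()) == list(range(1, 10))
        assert (df.groupby("block").size() == 50).all()
        assert set(df["conf1"]).issubset(set(CFG.scale_values))

    def test_shift_partition(self, single_session):
        counts = single_session["shift"].value_counts()
        assert counts.sum() == 450
        assert set(counts.index) <= {"up", "down", "extreme"}
        # non-extreme trials always carry a distinct second rating
        mid = single_session[single_session["shift"] != "extreme"]
        assert mid["conf2"].notna().all()
        assert (mid["conf2"] != mid["conf1"]).all()

    def test_stimulus_classes_balanced(self, single_session):
        assert (single_session["stimulus"] == "X").sum() == 225

    def test_cohort_deterministic(self, session_config, observer):
        a = mc.simulate_cohort(session_config, observer, 3, seed=9, variation=mc.CohortVariation())
        b = mc.simulate_cohort(session_config, observer, 3, seed=9, variation=mc.CohortVariation())
        assert a.equals(b)

    def test_staircase_tracks_seventy_percent(self, observer):
        cfg = mc.SessionConfig(n_trials=6000, n_blocks=6)
        recs = mc.simulate_session(cfg, observer, "p", seed=3)
        acc = np.mean([r.correct for r in recs[500:]])
        assert abs(acc - 0.707) < 0.04  # quick check; long-run bound in acceptance
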