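"""meta-d' estimation: binning, likelihood machinery, recovery properties."""

import warnings

import numpy as np
import pandas as pd
import pytest

import metaconf as mc
from metaconf.metad import MetaDModel, Type2Counts, bin_confidence

from conftest import plain_sdt_counts


class TestBinning:
    def test_bin_index_equals_rating_index_at_full_resolution(self):
        vals = np.arange(10, 101, 10)
        assert list(bin_confidence(vals, 10)) == list(range(1, 11))

    def test_combined_half_step_values_fall_in_upper_bin(self):
        assert bin_confidence([95.0], 5)[0] == 5
        assert bin_confidence([15.0], 5)[0] == 1
        assert bin_confidence([50.0], 5)[0] == 3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_confidence([0.0], 5)
        with pytest.raises(ValueError):
            bin_confidence([101.0], 5)

    def test_top_confidence_trials_land_in_top_cell(self):
        df = pd.DataFrame(
            {
                "participant_id": "p",
                "stimulus": ["O", "O", "X"],
                "response": ["O", "O", "X"],
                "correct": [1, 1, 1],
                "conf1": [100, 100, 10],
                "conf2": [90.0, 90.0, 20.0],
                "shift": ["down", "down", "up"],
            }
        )
        counts = mc.build_type2_counts(df, "first", 5)
        assert counts.counts_s1[0] == 2  # highest-confidence class-O cell
        assert counts.counts_s1.sum() == 2

    def test_streams_share_trials(self, single_session):
        sizes = {
            w: mc.build_type2_counts(single_session, w, 5).counts_s1.sum()
            + mc.build_type2_counts(single_session, w, 5).counts_s2.sum()
            for w in ("first", "second", "combined")
        }
        assert len(set(sizes.values())) == 1


class TestFit:
    def test_recovers_dprime_without_metacognitive_noise(self):
        counts, *_ = plain_sdt_counts(d=1.2, n=20_000, seed=5)
        fit = mc.fit_meta_d(counts)
        assert fit.converged
        assert fit.meta_d == pytest.approx(fit.d1, abs=0.1)

    def test_shuffled_confidence_destroys_meta_d(self):
        _, stim, resp_x, conf = plain_sdt_counts(d=1.2, n=20_000, seed=6)
        rng = np.random.default_rng(7)
        conf = conf.copy()
        for r in (True, False):  # shuffle ratings within each response group
            idx = np.where(resp_x == r)[0]
            conf[idx] = conf[rng.permutation(idx)]
        K = 5
        counts = np.zeros((2, 2 * K))
        cell = np.where(resp_x, K - 1 + conf, K - conf)
        np.add.at(counts, (stim.astype(int), cell), 1)
        fit = mc.fit_meta_d(Type2Counts(K, counts[0], counts[1]))
        assert abs(fit.meta_d) <= 0.1

    def test_mirror_invariance(self):
        counts, *_ = plain_sdt_counts(d=1.0, n=4000, seed=8, criterion=0.3)
        a = mc.fit_meta_d(counts)
        b = mc.fit_meta_d(counts.mirrored())
        assert b.c1 == pytest.approx(-a.c1, abs=1e-9)
        assert b.meta_d == pytest.approx(a.meta_d, abs=1e-5)

    def test_predicted_probs_sum_to_one(self):
        counts, *_ = plain_sdt_counts(d=1.0, n=3000, seed=9)
        fit = mc.fit_meta_d(counts)
        for probs in fit.predicted_probs().values():
            assert probs.sum() == pytest.approx(1.0, abs=1e-8)

    def test_optimum_beats_naive_start(self):
        counts, *_ = plain_sdt_counts(d=1.1, n=3000, seed=10)
        model = MetaDModel(counts)
        fit = model.fit()
        naive = model.loglike(model.d1, model._empirical_criteria(model.d1))
        assert fit.log_likelihood >= naive - 1e-9

    def test_degenerate_counts_flagged(self):
        K = 4
        s1 = np.zeros(2 * K)
        s2 = np.zeros(2 * K)
        s1[K] = 30  # every trial: lowest confidence, response X
        s2[K] = 30
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fit = mc.fit_meta_d(Type2Counts(K, s1, s2))
        assert fit.degenerate
        assert fit.meta_d == 0.0

    def test_grid_search_oracle_small_tables(self):
        """The joint optimizer must land on the profile-likelihood maximum
        found by a brute-force scan over meta_d (criteria re-fit per point)."""
        rng = np.random.default_rng(11)
        for _ in range(2):  # larger battery runs in the acceptance suite
            counts, *_ = plain_sdt_counts(
                d=float(rng.uniform(0.6, 1.8)), n=300, seed=int(rng.integers(2**31)), n_bins=3,
                edges=(0.5, 1.2),
            )
            model = MetaDModel(counts)
            fit = model.fit()
            grid = np.arange(0.0, 4.0001, 0.02)
            lls = [model.fit(fixed_meta_d=g).log_likelihood for g in grid]
            assert fit.meta_d == pytest.approx(grid[int(np.argmax(lls))], abs=0.02 + 0.02)

    def test_profile_shares_trial_set(self, single_session):
        profile = mc.meta_d_profile(single_session, n_bins=5)
        assert set(profile) == {"first", "second", "combined"}
        assert len({f.n_trials for f in profile.values()}) == 1
        assert all(f.converged for f in profile.values())

    def test_summary_mentions_key_quantities(self):
        counts, *_ = plain_sdt_counts(d=1.0, n=2000, seed=12)
        text = mc.fit_meta_d(counts).summary()
        assert "meta-d'" in text and "type 1 d'" in text
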