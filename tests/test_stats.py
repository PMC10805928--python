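"""Paired tests, power/sample-size planning, and the cohort report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.power import TTestPower

import metaconf as mc
from metaconf.stats import COMPARISONS, shift_split_type1


class TestPairedT:
    def test_hand_computed_example(self):
        res = mc.paired_t([2, 3, 4], [1, 1, 1])
        assert res.t_stat == pytest.approx(2 * np.sqrt(3), abs=1e-10)
        assert res.df == 2
        assert res.cohen_dz == pytest.approx(2.0)
        assert res.mean_diff == pytest.approx(2.0)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            x, y = rng.normal(size=(2, 12))
            res = mc.paired_t(x, y)
            ref = sps.ttest_rel(x, y)
            assert res.t_stat == pytest.approx(ref.statistic, abs=1e-8)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_antisymmetric_in_roles(self):
        x, y = [1.0, 2.0, 4.0], [0.5, 2.5, 1.0]
        a, b = mc.paired_t(x, y), mc.paired_t(y, x)
        assert a.t_stat == pytest.approx(-b.t_stat)
        assert a.cohen_dz == pytest.approx(-b.cohen_dz)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            mc.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_one_sample_against_zero(self):
        res = mc.paired_t([0.1, 0.3, 0.2])
        assert res.mean_diff == pytest.approx(0.2)


class TestSampleSize:
    def test_matches_independent_power_solver(self):
        for dz, power in [(0.62, 0.95), (0.5, 0.8), (1.0, 0.9)]:
            mine = mc.required_sample_size(dz, alpha=0.05, power=power, tails="one")
            ref = TTestPower().solve_power(
                effect_size=dz, alpha=0.05, power=power, alternative="larger"
            )
            assert mine == int(np.ceil(ref))

    def test_defining_property(self):
        for dz, power, tails in [(0.62, 0.95, "one"), (0.8, 0.9, "two")]:
            n = mc.required_sample_size(dz, 0.05, power, tails)
            assert mc.power_paired_t(n, dz, 0.05, tails) >= power
            assert mc.power_paired_t(n - 1, dz, 0.05, tails) < power

    def test_monotone_in_effect_size(self):
        ns = [mc.required_sample_size(dz, 0.05, 0.95, "one") for dz in np.linspace(0.3, 1.5, 13)]
        assert np.all(np.diff(ns) <= 0)

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            mc.required_sample_size(0.0)


class TestShiftSplit:
    def test_identical_subsets_identical_dprime(self):
        rng = np.random.default_rng(32)
        n = 200
        base = pd.DataFrame(
            {
                "participant_id": "p",
                "stimulus": np.where(rng.random(n) < 0.5, "X", "O"),
                "response": np.where(rng.random(n) < 0.5, "X", "O"),
            }
        )
        up = base.assign(shift="up")
        down = base.assign(shift="down")
        out = shift_split_type1(pd.concat([up, down], ignore_index=True))
        assert out["d_up"].iloc[0] == pytest.approx(out["d_down"].iloc[0])

    def test_random_shifts_give_similar_dprime(self):
        rng = np.random.default_rng(33)
        n = 20_000
        stim = np.where(rng.random(n) < 0.5, "X", "O")
        # imperfect observer, shifts assigned independently of everything
        resp = np.where(rng.random(n) < 0.75, stim, np.where(stim == "X", "O", "X"))
        df = pd.DataFrame(
            {
                "participant_id": "p",
                "stimulus": stim,
                "response": resp,
                "shift": np.where(rng.random(n) < 0.5, "up", "down"),
            }
        )
        out = shift_split_type1(df)
        assert out["d_up"].iloc[0] == pytest.approx(out["d_down"].iloc[0], abs=0.1)


class TestFullReport:
    def test_report_contains_all_comparisons(self, cohort):
        rep = mc.full_report(cohort, n_permutations=150, seed=2)
        assert tuple(rep.comparisons["comparison"]) == COMPARISONS
        assert len(rep.comparisons) == 7
        assert rep.comparisons["p"].between(0, 1).all()
        text = rep.to_text()
        assert "participants" in text and "d2_vs_chance" in text

    def test_report_deterministic(self, cohort):
        a = mc.full_report(cohort, n_permutations=100, seed=5)
        b = mc.full_report(cohort, n_permutations=100, seed=5)
        assert a.comparisons.equals(b.comparisons)
        assert a.descriptives == b.descriptives
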