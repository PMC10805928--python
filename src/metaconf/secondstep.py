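"""Second-step metacognitive sensitivity.

The re-evaluation itself is scored as a discrimination of the type 1
outcome: a *hit* is a correct type 1 response followed by an up-shift
(second confidence above the first), a *false alarm* an incorrect response
followed by an up-shift.  Sensitivity (d2) and criterion (c2) then follow
from the conventional equal-variance formulas on those rates.

Because confidence shifts are coarse, chance is calibrated empirically:
permuting the correct/incorrect labels across a participant's up/down
trials (shift labels held fixed) destroys any shift-accuracy association
while preserving the overall up-shift probability, and the permuted d2
distribution provides the chance level against which the observed d2 is
judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .sdt import RatePair, criterion, dprime, rates_from_counts
from .simulate import EXTREME, UP

__all__ = [
    "PermutationNull",
    "SecondStepResults",
    "SecondStepModel",
    "second_step_rates",
    "empirical_chance",
    "second_step_analysis",
]


def _up_down(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials[trials["shift"] != EXTREME]
    if len(t) == 0:
        raise ValueError("no up/down-shift trials")
    return t


def second_step_rates(trials: pd.DataFrame) -> RatePair:
    """Hit/false-alarm rates of the up-shift 'report' on a participant's
    up/down trials: hits = correct & up, false alarms = incorrect & up."""
    t = _up_down(trials)
    correct = t["correct"].to_numpy(dtype=bool)
    up = (t["shift"] == UP).to_numpy()
    if correct.all() or (~correct).all():
        raise ValueError("need both correct and incorrect trials")
    hits = int((correct & up).sum())
    misses = int((correct & ~up).sum())
    fas = int((~correct & up).sum())
    crs = int((~correct & ~up).sum())
    return rates_from_counts(hits, misses, fas, crs)


@dataclass(frozen=True)
class PermutationNull:
    """Summary of the shuffled-label d2 distribution."""

    values: np.ndarray
    n_permutations: int
    seed: int

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))

    def percentile_of(self, d2: float) -> float:
        """Fraction of the null at or below ``d2``."""
        return float((self.values <= d2).mean())


def _permuted_d2(correct: np.ndarray, up: np.ndarray, n_permutations: int, rng) -> np.ndarray:
    """Vectorised permutation of correctness labels; d2 per permutation,
    with the same 1/(2N) edge correction as the observed statistic."""
    n = correct.size
    n_correct = int(correct.sum())
    n_error = n - n_correct
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm_correct = correct[order]
    hits = (perm_correct & up).sum(axis=1)
    fas = ((~perm_correct) & up).sum(axis=1)
    hr = hits / n_correct
    fr = fas / n_error
    hr = np.clip(hr, 1.0 / (2 * n_correct), 1.0 - 1.0 / (2 * n_correct))
    fr = np.clip(fr, 1.0 / (2 * n_error), 1.0 - 1.0 / (2 * n_error))
    return ndtri(hr) - ndtri(fr)


def empirical_chance(
    trials: pd.DataFrame, n_permutations: int = 1000, seed: int = 0
) -> PermutationNull:
    """Null distribution of d2 under shuffled correctness labels."""
    t = _up_down(trials)
    correct = t["correct"].to_numpy(dtype=bool)
    up = (t["shift"] == UP).to_numpy()
    if correct.all() or (~correct).all():
        raise ValueError("need both correct and incorrect trials")
    rng = np.random.default_rng(seed)
    values = _permuted_d2(correct, up, n_permutations, rng)
    return PermutationNull(values=values, n_permutations=n_permutations, seed=seed)


@dataclass
class SecondStepResults:
    """Observed second-step sensitivity with its permutation chance level."""

    hr: float
    far: float
    d2: float
    c2: float
    null: PermutationNull = field(repr=False)
    n_trials: int = 0

    @property
    def null_mean(self) -> float:
        return self.null.mean

    @property
    def null_sd(self) -> float:
        return self.null.sd

    @property
    def perm_p(self) -> float:
        """One-sided permutation p-value for d2 above chance."""
        ge = int((self.null.values >= self.d2).sum())
        return (1 + ge) / (self.null.n_permutations + 1)

    def summary(self) -> str:
        return "\n".join(
            [
                "second-step metacognitive sensitivity",
                "=" * 37,
                f"up/down trials      {self.n_trials}",
                f"P(up | correct)     {self.hr: .4f}",
                f"P(up | incorrect)   {self.far: .4f}",
                f"d2                  {self.d2: .4f}",
                f"c2                  {self.c2: .4f}",
                f"chance (perm mean)  {self.null_mean: .4f} +/- {self.null_sd:.4f}",
                f"permutation p       {self.perm_p: .4f}  ({self.null.n_permutations} shuffles)",
            ]
        )


class SecondStepModel:
    """Second-step discrimination model for one participant's trials.

    ``fit`` computes the observed rates, d2 and c2, and the permutation
    null; results are deterministic given the seed.
    """

    def __init__(self, trials: pd.DataFrame):
        self.trials = _up_down(trials)

    def fit(self, n_permutations: int = 1000, seed: int = 0) -> SecondStepResults:
        rates = second_step_rates(self.trials)
        null = empirical_chance(self.trials, n_permutations=n_permutations, seed=seed)
        return SecondStepResults(
            hr=rates.hit_rate,
            far=rates.fa_rate,
            d2=dprime(rates),
            c2=criterion(rates),
            null=null,
            n_trials=len(self.trials),
        )


def second_step_analysis(
    trials: pd.DataFrame, n_permutations: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Per-participant second-step results for a cohort trial table.

    Per-participant permutation seeds are drawn from a master generator
    seeded with ``seed`` (kept below 2**31), so any single participant can
    be recomputed in isolation.  Group-level tests on the returned columns
    (observed d2 vs null mean, c2 vs 0) live in :mod:`metaconf.stats`.
    """
    master = np.random.default_rng(seed)
    rows = []
    for pid, g in trials.groupby("participant_id", sort=True):
        sub = int(master.integers(2**31))
        res = SecondStepModel(g).fit(n_permutations=n_permutations, seed=sub)
        rows.append(
            {
                "participant_id": pid,
                "hr": res.hr,
                "far": res.far,
                "d2": res.d2,
                "c2": res.c2,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "perm_p": res.perm_p,
            }
        )
    return pd.DataFrame(rows)
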