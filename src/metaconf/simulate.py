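"""Generative simulator of the two-step confidence paradigm.

The simulated task is an ensemble discrimination: a 7x7 array contains two
shape classes (Xs and Os) and the observer reports which class predominates.
Difficulty is controlled by a two-up-one-down adaptive staircase on the
majority count, which converges on ~70.7% correct.  After the choice the
observer gives a confidence rating on a 10-level scale, then — unless the
first rating was at either endpoint of the scale, which ends the trial —
a second rating that may not repeat the first.

The observer is an equal-variance signal-detection model.  Sensory evidence
``x ~ N(± slope * imbalance / 2, 1)`` drives the choice; each confidence
report reads a noisy copy ``y_i = x + eps_i`` of the same evidence, where
``(eps_1, eps_2)`` is zero-mean bivariate normal with per-report SDs and a
correlation.  Partially independent, unequally sized metacognitive noise on
the two reports is the mechanism of interest: it makes re-evaluated (and
averaged) confidence more diagnostic of accuracy than the first report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "UP",
    "DOWN",
    "EXTREME",
    "SessionConfig",
    "ObserverParams",
    "CohortVariation",
    "StaircaseState",
    "TrialRecord",
    "staircase_update",
    "sample_trial",
    "simulate_session",
    "simulate_cohort",
    "records_to_frame",
]

UP = "up"
DOWN = "down"
EXTREME = "extreme"

#: Column order of the trial table written/read by the pipeline.
TRIAL_COLUMNS = [
    "participant_id",
    "block",
    "trial",
    "majority_count",
    "stimulus",
    "response",
    "correct",
    "conf1",
    "conf2",
    "shift",
]


@dataclass(frozen=True)
class SessionConfig:
    """Structure of one experimental session.

    Defaults follow the reference protocol: 450 trials in 9 blocks of 50,
    a 7x7 (49-element) stimulus array, and a 10-level confidence scale with
    values 10, 20, ..., 100.  The staircase floor is the smallest possible
    majority (25 of 49) and the ceiling keeps at least 10 minority elements
    visible.
    """

    n_trials: int = 450
    n_blocks: int = 9
    grid_total: int = 49
    n_scale_levels: int = 10
    scale_values: tuple = tuple(range(10, 101, 10))
    staircase_start_majority: int = 27
    staircase_step: int = 1
    min_majority: int = 25
    max_majority: int | None = None  # defaults to grid_total - 10

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_blocks < 1:
            raise ValueError("n_trials and n_blocks must be positive")
        if self.n_trials % self.n_blocks != 0:
            raise ValueError("n_trials must be divisible by n_blocks")
        if len(self.scale_values) != self.n_scale_levels:
            raise ValueError("scale_values length must equal n_scale_levels")
        if any(b <= a for a, b in zip(self.scale_values, self.scale_values[1:])):
            raise ValueError("scale_values must be strictly increasing")
        if not self.min_majority > self.grid_total / 2:
            raise ValueError("min_majority must exceed grid_total / 2")
        if self.staircase_start_majority < self.min_majority:
            raise ValueError("staircase_start_majority must be >= min_majority")
        if self.ceiling < self.min_majority or self.ceiling > self.grid_total:
            raise ValueError("invalid staircase ceiling")

    @property
    def ceiling(self) -> int:
        return self.grid_total - 10 if self.max_majority is None else self.max_majority

    @property
    def block_length(self) -> int:
        return self.n_trials // self.n_blocks


def _default_criteria() -> tuple:
    # deciles of the folded normal |N(0.5, 1)| — the distribution of
    # normalized confidence evidence at the staircase design point
    # (d' ~ 1.1, unit-SD evidence).  Decile criteria give near-uniform use
    # of the 10-level scale, mimicking observers nudged to use its full
    # range; the two endpoint levels then hold ~20% of trials between them,
    # the share of early-terminated trials seen empirically.
    return (0.142, 0.287, 0.436, 0.593, 0.762, 0.95, 1.167, 1.439, 1.839)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the signal-detection observer.

    ``sensitivity_slope`` is the type 1 d' contributed per element of ratio
    imbalance; the default 0.22 places the staircase equilibrium near a
    27:22 array, matching typical human thresholds on this task.  The two
    metacognitive noise SDs and their correlation control how much each
    confidence report degrades the underlying evidence; the defaults encode
    a second report with attenuated, partially independent noise.

    When ``normalize_confidence`` is true (default) the confidence criteria
    are interpreted in units of each report's own evidence SD
    ``sqrt(1 + meta_noise_sd_i**2)``.  This models scale-use calibration:
    observers spread their ratings over the range of confidence signals
    they actually experience, which keeps the marginal rating distribution
    (and hence the up/down-shift balance) stable across reports with
    different noise levels.  The rescaling is monotone per report, so it
    does not change how much information a report carries about accuracy.
    With ``normalize_confidence=False`` the criteria cut the raw evidence
    axis ``|y_i - c|`` directly and must be supplied on that scale.
    """

    sensitivity_slope: float = 0.22
    type1_criterion: float = 0.0
    meta_noise_sd_1: float = 0.6
    meta_noise_sd_2: float = 0.3
    meta_noise_corr: float = 0.5
    confidence_criteria: tuple = field(default_factory=_default_criteria)
    lapse_rate: float = 0.0
    normalize_confidence: bool = True

    def __post_init__(self) -> None:
        if self.sensitivity_slope < 0:
            raise ValueError("sensitivity_slope must be >= 0")
        if self.meta_noise_sd_1 < 0 or self.meta_noise_sd_2 < 0:
            raise ValueError("metacognitive noise SDs must be >= 0")
        if not -1.0 <= self.meta_noise_corr <= 1.0:
            raise ValueError("meta_noise_corr must lie in [-1, 1]")
        crit = self.confidence_criteria
        if any(b <= a for a, b in zip(crit, crit[1:])):
            raise ValueError("confidence_criteria must be strictly increasing")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must lie in [0, 1)")

    def evidence_sd(self, report: int) -> float:
        """Total SD of the confidence evidence for report 1 or 2."""
        sd = self.meta_noise_sd_1 if report == 1 else self.meta_noise_sd_2
        return math.sqrt(1.0 + sd * sd)

    def expected_accuracy(self, imbalance: int) -> float:
        """Analytic P(correct) at a fixed ratio imbalance (staircase off)."""
        mu = self.sensitivity_slope * imbalance / 2.0
        c = self.type1_criterion
        p = 0.5 * ndtr(mu - c) + 0.5 * ndtr(mu + c)
        return float(self.lapse_rate * 0.5 + (1.0 - self.lapse_rate) * p)


@dataclass(frozen=True)
class CohortVariation:
    """Between-participant heterogeneity for cohort simulation.

    Multiplicative lognormal jitter on the sensitivity slope and on both
    metacognitive noise SDs (coefficients of variation), plus additive
    normal jitter on the type 1 criterion.  Defaults give the modest
    individual differences seen in online psychophysics cohorts.
    """

    slope_cv: float = 0.15
    noise_cv: float = 0.15
    criterion_sd: float = 0.05

    def draw(self, base: ObserverParams, rng: np.random.Generator) -> ObserverParams:
        def jitter(x: float, cv: float) -> float:
            if cv <= 0 or x == 0:
                return x
            sigma = math.sqrt(math.log(1.0 + cv * cv))
            return x * math.exp(rng.normal(-0.5 * sigma * sigma, sigma))

        return replace(
            base,
            sensitivity_slope=jitter(base.sensitivity_slope, self.slope_cv),
            meta_noise_sd_1=jitter(base.meta_noise_sd_1, self.noise_cv),
            meta_noise_sd_2=jitter(base.meta_noise_sd_2, self.noise_cv),
            type1_criterion=base.type1_criterion + rng.normal(0.0, self.criterion_sd),
        )


@dataclass(frozen=True)
class StaircaseState:
    """Current position of the two-up-one-down staircase."""

    majority_count: int
    consecutive_correct: int = 0


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial.

    ``conf1``/``conf2`` are rating levels (1..K); ``conf2`` is ``None`` on
    extreme trials, which end after the first rating.
    """

    participant_id: str
    block: int
    trial_index: int
    majority_count: int
    stimulus_class: str  # "X" or "O" (majority class)
    response: str
    correct: bool
    conf1: int
    conf2: int | None
    shift: str

    def __post_init__(self) -> None:
        if (self.shift == EXTREME) != (self.conf2 is None):
            raise ValueError("extreme trials and only extreme trials lack conf2")
        if self.conf2 is not None and self.conf2 == self.conf1:
            raise ValueError("second rating may not repeat the first")


def staircase_update(
    state: StaircaseState, correct: bool, config: SessionConfig
) -> StaircaseState:
    """Two-up-one-down rule: two consecutive correct responses make the
    stimulus harder (majority shrinks by one step); any error makes it
    easier.  The majority count is clamped to the configured bounds."""
    lo, hi = config.min_majority, config.ceiling
    step = config.staircase_step
    if correct:
        streak = state.consecutive_correct + 1
        if streak >= 2:
            return StaircaseState(max(lo, state.majority_count - step), 0)
        return StaircaseState(state.majority_count, streak)
    return StaircaseState(min(hi, state.majority_count + step), 0)


def _rating_level(z: float, criteria: Sequence[float]) -> int:
    """Map nonnegative confidence evidence to a 1-based rating level."""
    return int(np.searchsorted(criteria, z, side="right")) + 1


def sample_trial(
    observer: ObserverParams,
    state: StaircaseState,
    stimulus_class: str,
    rng: np.random.Generator,
    config: SessionConfig,
    *,
    participant_id: str = "sim",
    block: int = 1,
    trial_index: int = 0,
) -> TrialRecord:
    """Simulate one trial at the staircase's current difficulty.

    Random draws occur in a fixed order — lapse uniform, sensory evidence,
    the two metacognitive noise deviates (and one extra uniform only on
    lapse trials) — so identical seeds give identical records.
    """
    imbalance = 2 * state.majority_count - config.grid_total
    if imbalance < 1:
        raise ValueError("majority_count must give an imbalance of at least 1")
    sign = 1.0 if stimulus_class == "X" else -1.0
    mu = sign * observer.sensitivity_slope * imbalance / 2.0

    u = rng.uniform()
    x = rng.normal(mu, 1.0)
    z1, z2 = rng.standard_normal(2)
    sd1, sd2, rho = (
        observer.meta_noise_sd_1,
        observer.meta_noise_sd_2,
        observer.meta_noise_corr,
    )
    eps1 = sd1 * z1
    eps2 = sd2 * (rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * z2)

    if u < observer.lapse_rate:
        response = "X" if rng.uniform() < 0.5 else "O"
    else:
        response = "X" if x > observer.type1_criterion else "O"
    correct = response == stimulus_class

    c = observer.type1_criterion
    crit = np.asarray(observer.confidence_criteria)
    conf_ev = []
    for i, eps in ((1, eps1), (2, eps2)):
        z = abs(x + eps - c)
        if observer.normalize_confidence:
            z /= observer.evidence_sd(i)
        conf_ev.append(z)
    k = config.n_scale_levels
    conf1 = _rating_level(conf_ev[0], crit)
    conf1 = min(conf1, k)

    if conf1 == 1 or conf1 == k:
        conf2 = None
        shift = EXTREME
    else:
        conf2 = min(_rating_level(conf_ev[1], crit), k)
        if conf2 == conf1:
            # forced re-evaluation: nudge one level toward the raw
            # second-evidence direction; exact tie goes one level down
            conf2 += 1 if conf_ev[1] > conf_ev[0] else -1
        shift = UP if conf2 > conf1 else DOWN

    return TrialRecord(
        participant_id=participant_id,
        block=block,
        trial_index=trial_index,
        majority_count=state.majority_count,
        stimulus_class=stimulus_class,
        response=response,
        correct=correct,
        conf1=conf1,
        conf2=conf2,
        shift=shift,
    )


def _balanced_classes(n: int, rng: np.random.Generator) -> np.ndarray:
    classes = np.array(["X"] * (n // 2) + ["O"] * (n - n // 2))
    rng.shuffle(classes)
    return classes


def simulate_session(
    config: SessionConfig,
    observer: ObserverParams,
    participant_id: str = "sim",
    seed: int | np.random.Generator = 0,
) -> list[TrialRecord]:
    """Simulate one participant's session.

    One seeded stream drives the whole session: the balanced-random stimulus
    sequence is drawn first, then each trial consumes its draws in the order
    documented in :func:`sample_trial`.  The staircase threads through all
    trials in order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = _balanced_classes(config.n_trials, rng)
    state = StaircaseState(config.staircase_start_majority)
    records: list[TrialRecord] = []
    for t in range(config.n_trials):
        rec = sample_trial(
            observer,
            state,
            str(classes[t]),
            rng,
            config,
            participant_id=participant_id,
            block=t // config.block_length + 1,
            trial_index=t + 1,
        )
        records.append(rec)
        state = staircase_update(state, rec.correct, config)
    return records


def records_to_frame(records: Iterable[TrialRecord], config: SessionConfig) -> pd.DataFrame:
    """Trial records as a tidy table; confidence columns carry scale values
    (e.g. 10..100), with an absent second rating as NA."""
    vals = config.scale_values
    rows = [
        {
            "participant_id": r.participant_id,
            "block": r.block,
            "trial": r.trial_index,
            "majority_count": r.majority_count,
            "stimulus": r.stimulus_class,
            "response": r.response,
            "correct": int(r.correct),
            "conf1": vals[r.conf1 - 1],
            "conf2": np.nan if r.conf2 is None else vals[r.conf2 - 1],
            "shift": r.shift,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["conf2"] = df["conf2"].astype("Float64")
    return df


def simulate_cohort(
    config: SessionConfig,
    observer: ObserverParams,
    cohort_size: int,
    seed: int = 0,
    variation: CohortVariation | None = None,
) -> pd.DataFrame:
    """Simulate a cohort of participants into one trial table.

    A master generator seeded with ``seed`` first draws per-participant
    observer parameters (if ``variation`` is given), then one sub-seed per
    participant below 2**31, so individual sessions can be reproduced
    independently.
    """
    master = np.random.default_rng(seed)
    frames = []
    for i in range(cohort_size):
        obs = variation.draw(observer, master) if variation is not None else observer
        sub = int(master.integers(2**31))
        pid = f"p{i + 1:03d}"
        frames.append(records_to_frame(simulate_session(config, obs, pid, sub), config))
    return pd.concat(frames, ignore_index=True)
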