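"""Group-level inference: paired t tests, effect sizes, power, and the
full battery of cohort comparisons.

All cohort comparisons are paired within participants and reported with
Cohen's dz (mean of paired differences over their SD).  Sample-size
planning uses exact noncentral-t power, iterated upward until the
requested power is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import metad, preprocess, secondstep
from .sdt import dprime, rates_from_counts
from .simulate import DOWN, UP

__all__ = [
    "PairedTestResult",
    "paired_t",
    "power_paired_t",
    "required_sample_size",
    "shift_split_type1",
    "GroupReport",
    "full_report",
]


@dataclass(frozen=True)
class PairedTestResult:
    """Paired (or one-sample) t test with effect size and 95% CI."""

    t_stat: float
    df: int
    p_value: float
    cohen_dz: float
    mean_diff: float
    ci95: tuple
    tails: str
    n: int

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"t({self.df}) = {self.t_stat:.3f}, p = {self.p_value:.4g} ({self.tails}-tailed), "
            f"dz = {self.cohen_dz:.3f}, mean diff = {self.mean_diff:.4f} "
            f"[{lo:.4f}, {hi:.4f}]"
        )


def paired_t(x, y=None, tails: str = "two") -> PairedTestResult:
    """Paired t test of ``x`` against ``y`` (or against 0 when ``y`` is None).

    ``tails='one'`` tests the directional hypothesis mean(x - y) > 0.
    The 95% CI of the mean difference is always two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance differences")
    mean = d.mean()
    se = sd / math.sqrt(n)
    t = mean / se
    df = n - 1
    if tails == "two":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif tails == "one":
        p = sps.t.sf(t, df)
    else:
        raise ValueError("tails must be 'one' or 'two'")
    half = sps.t.ppf(0.975, df) * se
    return PairedTestResult(
        t_stat=float(t),
        df=df,
        p_value=float(p),
        cohen_dz=float(mean / sd),
        mean_diff=float(mean),
        ci95=(float(mean - half), float(mean + half)),
        tails=tails,
        n=n,
    )


def power_paired_t(n: int, effect_dz: float, alpha: float = 0.05, tails: str = "one") -> float:
    """Exact power of a paired t test at sample size ``n`` via the
    noncentral t distribution (noncentrality dz * sqrt(n), df = n - 1)."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = effect_dz * math.sqrt(n)
    if tails == "one":
        tcrit = sps.t.ppf(1.0 - alpha, df)
        return float(sps.nct.sf(tcrit, df, ncp))
    if tails == "two":
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    raise ValueError("tails must be 'one' or 'two'")


def required_sample_size(
    effect_dz: float,
    alpha: float = 0.05,
    power: float = 0.95,
    tails: str = "one",
    max_n: int = 1_000_000,
) -> int:
    """Smallest n at which the paired t test reaches the requested power.

    Computed by exact noncentral-t evaluation, iterating n upward from 2;
    no normal approximation.
    """
    if effect_dz <= 0:
        raise ValueError("effect_dz must be positive")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, max_n + 1):
        if power_paired_t(n, effect_dz, alpha, tails) >= power:
            return n
    raise ValueError("requested power not achievable within max_n")


def _type1_dprime(trials: pd.DataFrame) -> float:
    """Stimulus-class-conditional type 1 d' on a set of trials (class X as
    'signal'), with the standard edge correction."""
    stim_x = (trials["stimulus"] == "X").to_numpy()
    resp_x = (trials["response"] == "X").to_numpy()
    hits = int((stim_x & resp_x).sum())
    misses = int((stim_x & ~resp_x).sum())
    fas = int((~stim_x & resp_x).sum())
    crs = int((~stim_x & ~resp_x).sum())
    return dprime(rates_from_counts(hits, misses, fas, crs))


def shift_split_type1(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant type 1 d' computed separately on up-shift and
    down-shift trials."""
    rows = []
    for pid, g in trials.groupby("participant_id", sort=True):
        rows.append(
            {
                "participant_id": pid,
                "d_up": _type1_dprime(g[g["shift"] == UP]),
                "d_down": _type1_dprime(g[g["shift"] == DOWN]),
            }
        )
    return pd.DataFrame(rows)


#: names of the seven cohort comparisons, in report order
COMPARISONS = (
    "metad_second_vs_first",
    "metad_combined_vs_first",
    "metad_combined_vs_second",
    "type1_d_up_vs_down",
    "d2_vs_chance",
    "c2_vs_zero",
    "up_vs_down_counts",
)


@dataclass
class GroupReport:
    """Cohort-level analysis bundle produced by :func:`full_report`."""

    summaries: pd.DataFrame
    metad_table: pd.DataFrame
    secondstep_table: pd.DataFrame
    shift_dprimes: pd.DataFrame
    comparisons: pd.DataFrame
    descriptives: dict

    def to_text(self) -> str:
        d = self.descriptives
        lines = [
            "cohort analysis report",
            "=" * 22,
            f"participants: {d['n_included']} included of {d['n_total']} "
            f"(accuracy rule: {d['n_excluded_accuracy']}, shift-count rule: {d['n_excluded_shift']})",
            f"type 1 accuracy: {d['accuracy_mean']:.3f} +/- {d['accuracy_se']:.3f} (mean +/- SE)",
            f"extreme trials: {d['pct_extreme']:.2f}% of all trials",
            f"up-shifts: {d['up_mean']:.1f} +/- {d['up_sd']:.1f}; "
            f"down-shifts: {d['down_mean']:.1f} +/- {d['down_sd']:.1f} (mean +/- SD)",
            f"staircase ratio: {d['majority_mean']:.1f}:{d['minority_mean']:.1f}",
            "",
            "paired comparisons (two-tailed unless noted):",
        ]
        for _, row in self.comparisons.iterrows():
            lines.append(
                f"  {row['comparison']:<26} t({row['df']:.0f}) = {row['t']: .3f}, "
                f"p = {row['p']:.4g}, dz = {row['dz']: .3f}, "
                f"mean diff = {row['mean_diff']: .4f}"
            )
        return "\n".join(lines)


def _comparison_row(name: str, res: PairedTestResult) -> dict:
    return {
        "comparison": name,
        "t": res.t_stat,
        "df": res.df,
        "p": res.p_value,
        "dz": res.cohen_dz,
        "mean_diff": res.mean_diff,
        "ci_lo": res.ci95[0],
        "ci_hi": res.ci95[1],
        "n": res.n,
    }


def full_report(
    trials: pd.DataFrame,
    n_bins: int = 5,
    n_permutations: int = 1000,
    seed: int = 0,
    z_cut: float = 2.5,
    min_count: int = 50,
    tails: str = "two",
    grid_total: int = 49,
) -> GroupReport:
    """Run the complete cohort analysis on a trial table.

    Applies the exclusion rules, fits meta-d' for the three confidence
    streams, computes shift-split type 1 d' and the second-step statistic
    with its permutation chance level, and reports the seven paired
    comparisons with descriptives.
    """
    summaries = preprocess.apply_exclusions(
        preprocess.summarize_participants(trials), z_cut=z_cut, min_count=min_count
    )
    included = preprocess.included_trials(trials, summaries)
    if included.empty:
        raise ValueError(
            "no participants remain after exclusions "
            f"(0 of {len(summaries)} included); see the exclusion log"
        )

    metad_rows = []
    for pid, g in included.groupby("participant_id", sort=True):
        profile = metad.meta_d_profile(g, n_bins=n_bins)
        for stream, fit in profile.items():
            metad_rows.append(
                {
                    "participant_id": pid,
                    "stream": stream,
                    "d": fit.d1,
                    "c": fit.c1,
                    "meta_d": fit.meta_d,
                    "converged": fit.converged,
                }
            )
    metad_table = pd.DataFrame(metad_rows)

    ss_table = secondstep.second_step_analysis(
        included, n_permutations=n_permutations, seed=seed
    )
    shift_d = shift_split_type1(included)
    inc_sum = summaries[summaries["included"]].set_index("participant_id").sort_index()

    wide = metad_table.pivot(index="participant_id", columns="stream", values="meta_d").sort_index()
    ss = ss_table.set_index("participant_id").sort_index()
    shift_d = shift_d.set_index("participant_id").sort_index()

    rows = [
        _comparison_row("metad_second_vs_first", paired_t(wide["second"], wide["first"], tails)),
        _comparison_row("metad_combined_vs_first", paired_t(wide["combined"], wide["first"], tails)),
        _comparison_row("metad_combined_vs_second", paired_t(wide["combined"], wide["second"], tails)),
        _comparison_row("type1_d_up_vs_down", paired_t(shift_d["d_up"], shift_d["d_down"], tails)),
        _comparison_row("d2_vs_chance", paired_t(ss["d2"], ss["null_mean"], tails)),
        _comparison_row("c2_vs_zero", paired_t(ss["c2"], None, tails)),
        _comparison_row("up_vs_down_counts", paired_t(inc_sum["n_up"], inc_sum["n_down"], tails)),
    ]
    comparisons = pd.DataFrame(rows)

    acc = inc_sum["accuracy"].to_numpy(dtype=float)
    n_inc = len(inc_sum)
    descriptives = {
        "n_total": int(len(summaries)),
        "n_included": n_inc,
        "n_excluded_accuracy": int(summaries["excluded_accuracy"].sum()),
        "n_excluded_shift": int(
            (summaries["excluded_shift"] & ~summaries["excluded_accuracy"]).sum()
        ),
        "accuracy_mean": float(acc.mean()),
        "accuracy_se": float(acc.std(ddof=1) / math.sqrt(n_inc)) if n_inc > 1 else 0.0,
        "pct_extreme": float(
            100.0 * inc_sum["n_extreme"].sum() / inc_sum["n_trials"].sum()
        ),
        "up_mean": float(inc_sum["n_up"].mean()),
        "up_sd": float(inc_sum["n_up"].std(ddof=1)) if n_inc > 1 else 0.0,
        "down_mean": float(inc_sum["n_down"].mean()),
        "down_sd": float(inc_sum["n_down"].std(ddof=1)) if n_inc > 1 else 0.0,
        "majority_mean": float(included["majority_count"].mean()),
        "minority_mean": float(grid_total - included["majority_count"].mean()),
    }
    return GroupReport(
        summaries=summaries,
        metad_table=metad_table,
        secondstep_table=ss_table,
        shift_dprimes=shift_d.reset_index(),
        comparisons=comparisons,
        descriptives=descriptives,
    )
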