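"""Participant-level screening and shift labelling.

Two exclusion rules are applied, in this order:

1. type 1 accuracy outside 2.5 sample SDs of the group mean (group
   statistics computed over *all* submitted participants, before any
   exclusion);
2. fewer than 50 up-shift or fewer than 50 down-shift trials — such
   participants polarise their first ratings, leaving too few
   re-evaluations for second-interval SDT measures.

Extreme trials (first rating at either scale endpoint, hence no second
rating) are dropped from all confidence-based analyses so that the first,
second and averaged-confidence measures are computed on one and the same
trial set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import DOWN, EXTREME, UP

__all__ = [
    "classify_shift",
    "add_shift_labels",
    "average_confidence",
    "summarize_participants",
    "exclude_by_group_accuracy",
    "exclude_by_shift_counts",
    "apply_exclusions",
    "included_trials",
    "non_extreme",
    "exclusions_log",
]


def classify_shift(conf1, conf2) -> str:
    """Label a trial UP, DOWN or EXTREME from its two confidence values.

    ``conf2`` equal to ``conf1`` is a data error: the paradigm forbids
    repeating the first rating.
    """
    if pd.isna(conf2):
        return EXTREME
    if conf2 == conf1:
        raise ValueError("conf2 equal to conf1 is not a valid trial")
    return UP if conf2 > conf1 else DOWN


def add_shift_labels(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the ``shift`` column (re)derived from conf1/conf2."""
    out = trials.copy()
    out["shift"] = [classify_shift(c1, c2) for c1, c2 in zip(out["conf1"], out["conf2"])]
    return out


def average_confidence(conf1, conf2):
    """Mid-value of the two ratings; undefined (error) if conf2 is absent."""
    c1 = np.asarray(conf1, dtype=float)
    c2 = np.asarray(conf2, dtype=float)
    if np.any(np.isnan(c2)):
        raise ValueError("average_confidence requires both ratings; filter extreme trials first")
    out = (c1 + c2) / 2.0
    return float(out) if out.ndim == 0 else out


def summarize_participants(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant trial counts, accuracy and shift tallies."""
    rows = []
    for pid, g in trials.groupby("participant_id", sort=True):
        shifts = g["shift"].value_counts()
        rows.append(
            {
                "participant_id": pid,
                "n_trials": len(g),
                "accuracy": g["correct"].mean(),
                "n_up": int(shifts.get(UP, 0)),
                "n_down": int(shifts.get(DOWN, 0)),
                "n_extreme": int(shifts.get(EXTREME, 0)),
            }
        )
    return pd.DataFrame(rows)


def exclude_by_group_accuracy(summaries: pd.DataFrame, z_cut: float = 2.5) -> pd.DataFrame:
    """Flag participants whose accuracy deviates more than ``z_cut`` sample
    SDs from the group mean (both computed before any exclusion)."""
    if len(summaries) < 2:
        raise ValueError("group accuracy screening needs at least 2 participants")
    out = summaries.copy()
    acc = out["accuracy"].to_numpy(dtype=float)
    mean, sd = acc.mean(), acc.std(ddof=1)
    if sd == 0.0:
        out["excluded_accuracy"] = False
    else:
        out["excluded_accuracy"] = np.abs(acc - mean) > z_cut * sd
    return out


def exclude_by_shift_counts(summary_row, min_count: int = 50) -> bool:
    """True (included) iff the participant has at least ``min_count`` up-shift
    AND ``min_count`` down-shift trials."""
    return bool(summary_row["n_up"] >= min_count and summary_row["n_down"] >= min_count)


def apply_exclusions(
    summaries: pd.DataFrame, z_cut: float = 2.5, min_count: int = 50
) -> pd.DataFrame:
    """Apply both rules in order; adds ``included`` and ``exclusion_reason``."""
    out = exclude_by_group_accuracy(summaries, z_cut=z_cut)
    out["excluded_shift"] = [
        not exclude_by_shift_counts(row, min_count) for _, row in out.iterrows()
    ]
    reason = np.where(
        out["excluded_accuracy"], "accuracy", np.where(out["excluded_shift"], "shift_count", "")
    )
    out["exclusion_reason"] = reason
    out["included"] = reason == ""
    return out


def included_trials(trials: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Trials of participants that survive both exclusion rules."""
    keep = set(summaries.loc[summaries["included"], "participant_id"])
    return trials[trials["participant_id"].isin(keep)].reset_index(drop=True)


def non_extreme(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop extreme trials (no second rating)."""
    return trials[trials["shift"] != EXTREME].reset_index(drop=True)


def exclusions_log(summaries: pd.DataFrame) -> str:
    """Human-readable log of exclusions, one line per excluded participant."""
    lines = []
    n_acc = int(summaries["excluded_accuracy"].sum())
    n_shift = int((summaries["excluded_shift"] & ~summaries["excluded_accuracy"]).sum())
    lines.append(f"accuracy rule (2.5 SD): {n_acc} excluded")
    lines.append(f"shift-count rule: {n_shift} excluded")
    for _, row in summaries.iterrows():
        if not row["included"]:
            lines.append(
                f"excluded {row['participant_id']}: {row['exclusion_reason']} "
                f"(accuracy={row['accuracy']:.3f}, n_up={row['n_up']}, n_down={row['n_down']})"
            )
    lines.append(
        f"included {int(summaries['included'].sum())} of {len(summaries)} participants"
    )
    return "\n".join(lines)
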