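"""Maximum-likelihood meta-d' from response-conditional confidence counts.

meta-d' expresses type 2 (metacognitive) sensitivity in type 1 d' units:
it is the d' an ideal equal-variance SDT observer would need in order to
produce the observed confidence-rating distributions, given the actual
type 1 response counts.  Because the ideal observer's type 1 criterion is
pinned at the same *relative* position as the empirical one
(``c' = c1 * meta_d / d1``), the measure is insensitive to response bias.

The fit maximises the multinomial likelihood of the confidence counts,
conditional on stimulus and response, over ``meta_d`` and the 2(K-1)
type 2 criteria (K confidence bins), the criteria being constrained to
stay ordered around the scaled type 1 criterion.

Count layout (the Maniscalco & Lau convention): for each stimulus class,
cells run from the highest-confidence "class O" response down to
confidence 1, then confidence 1 up to the highest-confidence "class X"
response — ``2K`` cells per stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from . import preprocess
from .sdt import criterion as _criterion
from .sdt import dprime as _dprime
from .sdt import rates_from_counts

__all__ = [
    "Type2Counts",
    "MetaDModel",
    "MetaDResults",
    "bin_confidence",
    "build_type2_counts",
    "fit_meta_d",
    "meta_d_profile",
    "STREAMS",
]

STREAMS = ("first", "second", "combined")

_CLASS1, _CLASS2 = "O", "X"  # stimulus/response labels; class X plays "signal"


@dataclass(frozen=True)
class Type2Counts:
    """Confidence-by-response counts for the two stimulus classes.

    ``counts_s1``/``counts_s2`` each have ``2 * n_bins`` cells ordered from
    the highest-confidence class-O response to the highest-confidence
    class-X response.
    """

    n_bins: int
    counts_s1: np.ndarray
    counts_s2: np.ndarray

    def __post_init__(self) -> None:
        k = self.n_bins
        if k < 2:
            raise ValueError("need at least 2 confidence bins")
        for name in ("counts_s1", "counts_s2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (2 * k,):
                raise ValueError(f"{name} must have 2*n_bins cells")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
            object.__setattr__(self, name, arr)
        if self.counts_s1.sum() < 1 or self.counts_s2.sum() < 1:
            raise ValueError("each stimulus class needs at least one trial")

    def mirrored(self) -> "Type2Counts":
        """Counts with the stimulus classes relabelled (and cells reversed)."""
        return Type2Counts(self.n_bins, self.counts_s2[::-1], self.counts_s1[::-1])


def bin_confidence(values, n_bins: int, scale_max: float = 100.0) -> np.ndarray:
    """Map confidence values in (0, scale_max] to 1-based equal-width bins.

    With ``n_bins`` equal to the number of scale levels the bin index equals
    the rating index; averaged (half-step) values fall unambiguously into
    the half-open bins ``(edge_{k-1}, edge_k]``.
    """
    v = np.asarray(values, dtype=float)
    if np.any(~(v > 0) | (v > scale_max)):
        raise ValueError("confidence values must lie in (0, scale_max]")
    idx = np.ceil(v * n_bins / scale_max).astype(int)
    return idx


def build_type2_counts(
    trials: pd.DataFrame, which: str = "first", n_bins: int = 5, scale_max: float = 100.0
) -> Type2Counts:
    """Tabulate one participant's non-extreme trials into type 2 counts.

    ``which`` selects the confidence stream: ``first``, ``second`` or
    ``combined`` (the per-trial mean of the two ratings).  The three streams
    share bin edges, so their fits are directly comparable.
    """
    if which not in STREAMS:
        raise ValueError(f"which must be one of {STREAMS}")
    t = preprocess.non_extreme(trials)
    if which == "first":
        conf = t["conf1"].to_numpy(dtype=float)
    elif which == "second":
        conf = t["conf2"].to_numpy(dtype=float)
    else:
        conf = preprocess.average_confidence(t["conf1"], t["conf2"])
    bins = bin_confidence(conf, n_bins, scale_max)
    resp_x = (t["response"] == _CLASS2).to_numpy()
    stim_x = (t["stimulus"] == _CLASS2).to_numpy()

    k = n_bins
    counts = np.zeros((2, 2 * k))
    # cell index: response O with conf b -> k - b; response X with conf b -> k - 1 + b
    cell = np.where(resp_x, k - 1 + bins, k - bins)
    for s, c in zip(stim_x.astype(int), cell):
        counts[s, c] += 1
    return Type2Counts(n_bins=k, counts_s1=counts[0], counts_s2=counts[1])


@dataclass
class MetaDResults:
    """Estimates from a :class:`MetaDModel` fit."""

    d1: float
    c1: float
    meta_d: float
    type2_criteria: np.ndarray  # 2(K-1) ordered values (below then above c1')
    log_likelihood: float
    converged: bool
    degenerate: bool
    n_trials: int
    model: "MetaDModel" = field(repr=False)

    @property
    def m_ratio(self) -> float:
        return self.meta_d / self.d1 if self.d1 != 0 else np.nan

    @property
    def scaled_criterion(self) -> float:
        """The ideal observer's type 1 criterion, c1 * meta_d / d1."""
        return self.c1 * self.meta_d / self.d1 if self.d1 != 0 else self.c1

    def predicted_probs(self) -> dict[str, np.ndarray]:
        """Model cell probabilities, conditional on stimulus x response."""
        return self.model.conditional_probs(self.meta_d, self.type2_criteria)

    def summary(self) -> str:
        lines = [
            "meta-d' fit (maximum likelihood)",
            "=" * 34,
            f"trials            {self.n_trials}",
            f"type 1 d'         {self.d1: .4f}",
            f"type 1 criterion  {self.c1: .4f}",
            f"meta-d'           {self.meta_d: .4f}",
            f"M-ratio           {self.m_ratio: .4f}",
            f"log-likelihood    {self.log_likelihood: .4f}",
            f"converged         {self.converged}",
        ]
        if self.degenerate:
            lines.append("WARNING: degenerate confidence counts (single bin)")
        return "\n".join(lines)


class MetaDModel:
    """Equal-variance type 2 SDT observer fitted to confidence counts.

    Parameters
    ----------
    counts
        Response-conditional confidence counts for both stimulus classes.
    pad
        Add ``1/(2K)`` to every type 2 cell before fitting (default), which
        keeps the likelihood finite when some cells are empty.  Padding is
        applied uniformly to every fit so comparisons between confidence
        streams are unaffected.
    """

    def __init__(self, counts: Type2Counts, pad: bool = True):
        self.counts = counts
        k = counts.n_bins
        self.pad = 1.0 / (2 * k) if pad else 0.0
        self._padded = np.stack([counts.counts_s1, counts.counts_s2]) + self.pad

        # type 1 marginals from the raw counts
        resp_x_s1 = counts.counts_s1[k:].sum()
        resp_x_s2 = counts.counts_s2[k:].sum()
        n_s1 = counts.counts_s1.sum()
        n_s2 = counts.counts_s2.sum()
        rates = rates_from_counts(
            hits=int(round(resp_x_s2)),
            misses=int(round(n_s2 - resp_x_s2)),
            fas=int(round(resp_x_s1)),
            crs=int(round(n_s1 - resp_x_s1)),
        )
        self.d1 = _dprime(rates)
        self.c1 = _criterion(rates)
        self.n_trials = int(round(n_s1 + n_s2))

    # ---- model probabilities -------------------------------------------

    def _scaled_c1(self, meta_d: float) -> float:
        return self.c1 * meta_d / self.d1 if self.d1 != 0 else self.c1

    def conditional_probs(self, meta_d: float, criteria: np.ndarray) -> dict[str, np.ndarray]:
        """P(confidence bin | stimulus, response) for each of the four groups.

        Keys ``"s1_rO"``, ``"s1_rX"``, ``"s2_rO"``, ``"s2_rX"``; each value
        has ``n_bins`` entries ordered by confidence level.
        """
        k = self.counts.n_bins
        criteria = np.asarray(criteria, dtype=float)
        c1s = self._scaled_c1(meta_d)
        below = criteria[: k - 1]  # ascending, all < c1s
        above = criteria[k - 1 :]  # ascending, all > c1s
        # ascending boundaries for response-O cells: [-inf, below..., c1s]
        bound_o = np.concatenate(([-np.inf], below, [c1s]))
        bound_x = np.concatenate(([c1s], above, [np.inf]))
        out = {}
        for s, mu in (("s1", -meta_d / 2.0), ("s2", meta_d / 2.0)):
            cdf_o = ndtr(bound_o - mu)
            cdf_x = ndtr(bound_x - mu)
            p_resp_o = max(cdf_o[-1], 1e-300)
            p_resp_x = max(1.0 - cdf_o[-1], 1e-300)
            # conf level j for response O occupies (bound_o[k-j], bound_o[k-j+1])
            cells_o = np.diff(cdf_o)[::-1]  # ordered conf 1..K after reversal? see below
            # np.diff gives intervals left-to-right = conf K..1; reverse -> conf 1..K
            cells_x = np.diff(cdf_x)  # conf 1..K already
            out[f"{s}_rO"] = np.clip(cells_o / p_resp_o, 1e-300, 1.0)
            out[f"{s}_rX"] = np.clip(cells_x / p_resp_x, 1e-300, 1.0)
        return out

    def loglike(self, meta_d: float, criteria: np.ndarray) -> float:
        """Multinomial log-likelihood of the (padded) counts, conditional on
        stimulus and response."""
        k = self.counts.n_bins
        probs = self.conditional_probs(meta_d, criteria)
        ll = 0.0
        for s_idx, s in ((0, "s1"), (1, "s2")):
            row = self._padded[s_idx]
            conf_o = row[:k][::-1]  # cells 0..k-1 are resp O conf K..1
            conf_x = row[k:]  # conf 1..K
            ll += float(conf_o @ np.log(probs[f"{s}_rO"]))
            ll += float(conf_x @ np.log(probs[f"{s}_rX"]))
        return ll

    # ---- fitting --------------------------------------------------------

    def _unpack(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        k = self.counts.n_bins
        meta_d = float(x[0])
        c1s = self._scaled_c1(meta_d)
        gaps_lo = np.exp(np.clip(x[1:k], -20, 20))
        gaps_hi = np.exp(np.clip(x[k:], -20, 20))
        below = c1s - np.cumsum(gaps_lo)[::-1]  # ascending
        above = c1s + np.cumsum(gaps_hi)
        return meta_d, np.concatenate([below, above])

    def _pack(self, meta_d: float, criteria: np.ndarray) -> np.ndarray:
        k = self.counts.n_bins
        c1s = self._scaled_c1(meta_d)
        below = criteria[: k - 1]
        above = criteria[k - 1 :]
        gaps_lo = np.diff(np.concatenate([[0.0], c1s - below[::-1]]))
        gaps_hi = np.diff(np.concatenate([[c1s], above]))
        return np.concatenate([[meta_d], np.log(np.maximum(gaps_lo, 1e-6)), np.log(np.maximum(gaps_hi, 1e-6))])

    def _empirical_criteria(self, meta_d: float) -> np.ndarray:
        """Initial criteria from empirical response-conditional confidence
        quantiles, mapped through a half-normal positioned at the scaled
        type 1 criterion."""
        k = self.counts.n_bins
        c1s = self._scaled_c1(meta_d)
        pooled = self._padded.sum(axis=0)
        conf_o = pooled[:k][::-1]  # conf 1..K for response O
        conf_x = pooled[k:]

        def half_normal_cuts(conf_counts):
            cum = np.cumsum(conf_counts)[:-1] / conf_counts.sum()
            cum = np.clip(cum, 0.02, 0.98)
            z = ndtri((1.0 + cum) / 2.0)  # half-normal quantiles, increasing
            z = np.maximum.accumulate(z + 1e-3 * np.arange(len(z)))
            return z

        above = c1s + half_normal_cuts(conf_x)
        below = (c1s - half_normal_cuts(conf_o))[::-1]
        return np.concatenate([below, above])

    def fit(self, n_starts: int = 3, tol: float = 1e-6, fixed_meta_d: float | None = None) -> MetaDResults:
        """Maximise the conditional likelihood.

        Three deterministic starts (meta_d at 0.5x, 1x and 1.5x the type 1
        d', criteria at empirical quantiles) guard against local optima;
        the best final likelihood wins.  ``fixed_meta_d`` re-optimises only
        the type 2 criteria at a pinned meta_d (used by grid-search
        diagnostics).
        """
        k = self.counts.n_bins
        # degenerate: every observed trial in one confidence bin
        raw = np.stack([self.counts.counts_s1, self.counts.counts_s2]).sum(axis=0)
        conf_totals = raw[:k][::-1] + raw[k:]
        if np.count_nonzero(conf_totals) <= 1:
            warnings.warn("degenerate confidence counts: meta-d' set to 0", RuntimeWarning)
            crit = self._empirical_criteria(0.0)
            return MetaDResults(
                d1=self.d1, c1=self.c1, meta_d=0.0, type2_criteria=crit,
                log_likelihood=self.loglike(0.0, crit), converged=True,
                degenerate=True, n_trials=self.n_trials, model=self,
            )

        base = self.d1 if abs(self.d1) > 1e-3 else 1.0
        if fixed_meta_d is not None:
            starts = [fixed_meta_d]
        else:
            starts = [f * base for f in (0.5, 1.0, 1.5)][:n_starts]

        best = None
        for md0 in starts:
            x0 = self._pack(md0, self._empirical_criteria(md0))

            if fixed_meta_d is None:
                def nll(x):
                    meta_d, crit = self._unpack(x)
                    return -self.loglike(meta_d, crit)
                xinit = x0
            else:
                def nll(x):
                    meta_d, crit = self._unpack(np.concatenate([[fixed_meta_d], x]))
                    return -self.loglike(meta_d, crit)
                xinit = x0[1:]

            res = minimize(
                nll,
                xinit,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": tol, "maxiter": 4000 * len(xinit), "maxfev": 4000 * len(xinit)},
            )
            if best is None or res.fun < best.fun:
                best = res

        xbest = best.x if fixed_meta_d is None else np.concatenate([[fixed_meta_d], best.x])
        meta_d, criteria = self._unpack(xbest)
        ll = -float(best.fun)
        return MetaDResults(
            d1=self.d1,
            c1=self.c1,
            meta_d=meta_d,
            type2_criteria=criteria,
            log_likelihood=ll,
            converged=bool(best.success) and np.isfinite(ll),
            degenerate=False,
            n_trials=self.n_trials,
            model=self,
        )


def fit_meta_d(counts: Type2Counts, **kwargs) -> MetaDResults:
    """Convenience wrapper: ``MetaDModel(counts).fit(**kwargs)``."""
    return MetaDModel(counts).fit(**kwargs)


def meta_d_profile(trials: pd.DataFrame, n_bins: int = 5, scale_max: float = 100.0) -> dict[str, MetaDResults]:
    """Fit meta-d' for the first, second and averaged confidence streams of
    one participant, on the identical (non-extreme) trial set."""
    return {
        which: fit_meta_d(build_type2_counts(trials, which, n_bins, scale_max))
        for which in STREAMS
    }
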