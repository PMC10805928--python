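"""Equal-variance signal-detection primitives.

Classical d' and criterion on hit/false-alarm rates, with a 1/(2N)
edge correction so degenerate count tables (all hits, no false alarms)
stay finite.  The correction is applied identically everywhere these
rates are formed — type 1 sensitivity, the second-step statistic and
its permutation null — so that comparisons between them are unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

__all__ = ["RatePair", "rates_from_counts", "correct_rate", "dprime", "criterion"]


@dataclass(frozen=True)
class RatePair:
    """Edge-corrected hit and false-alarm rates with their trial counts."""

    hit_rate: float
    fa_rate: float
    n_signal: int
    n_noise: int

    def __post_init__(self) -> None:
        if not (0.0 < self.hit_rate < 1.0 and 0.0 < self.fa_rate < 1.0):
            raise ValueError("rates must lie strictly inside (0, 1) after correction")

    @property
    def dprime(self) -> float:
        return dprime(self)

    @property
    def criterion(self) -> float:
        return criterion(self)


def correct_rate(k: int | float, n: int) -> float:
    """Proportion ``k/n`` with 0 and 1 pulled to ``1/(2n)`` and ``1 - 1/(2n)``."""
    if n < 1:
        raise ValueError("need at least one trial in the class")
    r = k / n
    if r <= 0.0:
        return 1.0 / (2 * n)
    if r >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return r


def rates_from_counts(hits: int, misses: int, fas: int, crs: int) -> RatePair:
    """Hit/false-alarm rates from a 2x2 count table, edge-corrected.

    ``hits + misses`` are the signal trials, ``fas + crs`` the noise trials.
    A rate of exactly 0 or 1 is replaced by 1/(2N) or 1 - 1/(2N) for the
    relevant class size N.
    """
    n_signal = hits + misses
    n_noise = fas + crs
    if n_signal < 1 or n_noise < 1:
        raise ValueError("empty signal or noise class")
    return RatePair(
        hit_rate=correct_rate(hits, n_signal),
        fa_rate=correct_rate(fas, n_noise),
        n_signal=n_signal,
        n_noise=n_noise,
    )


def _unpack(rates, far):
    if far is None:
        return rates.hit_rate, rates.fa_rate
    return float(rates), float(far)


def dprime(rates: RatePair | float, far: float | None = None) -> float:
    """Sensitivity d' = Phi^-1(HR) - Phi^-1(FAR).

    Accepts a :class:`RatePair` or a plain ``(hr, far)`` pair.
    """
    hr, fa = _unpack(rates, far)
    return float(ndtri(hr) - ndtri(fa))


def criterion(rates: RatePair | float, far: float | None = None) -> float:
    """Decision criterion c = -(Phi^-1(HR) + Phi^-1(FAR)) / 2."""
    hr, fa = _unpack(rates, far)
    return float(-0.5 * (ndtri(hr) + ndtri(fa)))
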