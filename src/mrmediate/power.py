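"""Analytic power for two-sample MR with a binary (case-control) outcome.

The non-centrality approximation used by the standard MR power calculators
for binary outcomes: with total outcome sample size n, case fraction K,
instrument variance explained R²xz and a causal odds ratio OR, the two-sided
test at level alpha has

    power = Phi( sqrt(n · R²xz · K·(1−K)) · |ln OR| − z_{1−alpha/2} ).

K·(1−K) is the variance factor of the binary outcome; n·R²xz·K·(1−K)·ln²OR
is the non-centrality parameter of the IVW z-statistic.
:func:`min_detectable_or` inverts the formula by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerParams:
    n: float  # total outcome sample size
    k: float  # case fraction ("case composition ratio")
    r2_xz: float  # instrument variance explained in the exposure
    odds_ratio: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not (0 < self.k < 1):
            raise ValueError(f"case fraction k must be in (0,1), got {self.k}")
        if not (0 <= self.r2_xz <= 1):
            raise ValueError(f"r2_xz must be in [0,1], got {self.r2_xz}")
        if self.odds_ratio <= 0:
            raise ValueError(f"odds_ratio must be > 0, got {self.odds_ratio}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")


def mr_power_binary(p: PowerParams) -> float:
    """Power of the two-sample MR test for a binary outcome (see module doc)."""
    z_crit = stats.norm.ppf(1.0 - p.alpha / 2.0)
    ncp = math.sqrt(p.n * p.r2_xz * p.k * (1.0 - p.k)) * abs(math.log(p.odds_ratio))
    return float(stats.norm.cdf(ncp - z_crit))


def min_detectable_or(
    p: PowerParams,
    target_power: float = 0.8,
    tol: float = 1e-6,
) -> float:
    """Smallest OR > 1 reaching ``target_power``, by bisection to ``tol``.

    ``p.odds_ratio`` is ignored; power is symmetric in OR <-> 1/OR so the
    protective-direction threshold is the reciprocal of the returned value.
    """
    if not (p.alpha < target_power < 1):
        raise ValueError(f"target_power must be in (alpha, 1), got {target_power}")

    def power_at(or_):
        return mr_power_binary(PowerParams(p.n, p.k, p.r2_xz, or_, p.alpha))

    hi = 1.0 + 1e-6
    while power_at(hi) < target_power:
        hi = 1.0 + (hi - 1.0) * 2.0
        if hi > 1e6:
            raise ValueError("target power unreachable at these parameters")
    lo = 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def power_grid(n: float, k: float, r2_xz: float, odds_ratios, alpha: float = 0.05):
    """Power across a grid of odds ratios (rows: or, power)."""
    return [
        (float(or_), mr_power_binary(PowerParams(n, k, r2_xz, float(or_), alpha)))
        for or_ in odds_ratios
    ]


__all__ = ["PowerParams", "min_detectable_or", "mr_power_binary", "power_grid"]
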