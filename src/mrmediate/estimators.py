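"""Causal-effect estimators for two-sample MR.

Given harmonized instruments (per-SNP exposure and outcome betas with
standard errors), four estimators are provided:

* **Wald ratio** — single-instrument base case, beta_out/beta_exp with the
  first-order SE se_out/|beta_exp|.
* **IVW** — inverse-variance-weighted meta-analysis of Wald ratios with
  weights beta_exp²/se_out², algebraically identical to weighted least
  squares of beta_out on beta_exp through the origin with weights se_out⁻².
  A fixed-effects SE is (Σw)^{-1/2}; the multiplicative random-effects SE
  scales it by max(1, sqrt(Q/(J−1))) where Q is Cochran's statistic. The
  ``auto`` model applies the fixed model when the Q test's p exceeds 0.05
  and the random model otherwise.
* **MR-Egger** — weighted regression *with* an intercept, after orienting
  every instrument to a positive exposure beta. The slope is a
  pleiotropy-adjusted causal estimate and the intercept estimates the mean
  directional pleiotropic effect. SEs are scaled by max(1, sqrt(RSS_w/(J−2)))
  and inference uses t(J−2).
* **Weighted median** — consistent when at least half the weight comes from
  valid instruments; the point estimate interpolates the inverse-variance-
  weighted cumulative distribution of sorted Wald ratios at one half, and the
  SE comes from a seeded parametric bootstrap.

For binary outcomes, estimates on the log-odds scale are exponentiated to
odds ratios with :func:`to_odds_ratio`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate from one MR method."""

    method: str  # ivw | egger | weighted_median | wald
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int
    effects_model: str = "not_applicable"  # fixed | random | not_applicable
    or_scale: tuple[float, float, float] | None = None  # (OR, ci_low, ci_high)


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept: the mean directional pleiotropic effect."""

    intercept: float
    se: float
    pval: float


def _normal_estimate(method, beta, se, nsnp, effects_model="not_applicable") -> MREstimate:
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(p),
        nsnp=nsnp,
        effects_model=effects_model,
    )


def wald_ratio(h: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp (first-order SE)."""
    if h.beta_exp == 0:
        raise ValueError(f"{h.snp_id}: beta_exp is zero; Wald ratio undefined")
    return _normal_estimate("wald", h.wald_ratio, h.wald_se, 1)


def _arrays(hs: Sequence[HarmonizedInstrument]):
    bx = np.array([h.beta_exp for h in hs], dtype=float)
    sx = np.array([h.se_exp for h in hs], dtype=float)
    by = np.array([h.beta_out for h in hs], dtype=float)
    sy = np.array([h.se_out for h in hs], dtype=float)
    return bx, sx, by, sy


def ivw_q_statistic(hs: Sequence[HarmonizedInstrument]) -> tuple[float, float]:
    """Cochran's Q about the fixed-effects IVW estimate; returns (Q, beta)."""
    bx, _, by, sy = _arrays(hs)
    w = bx**2 / sy**2
    r = by / bx
    beta = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta) ** 2))
    return q, beta


def ivw(hs: Sequence[HarmonizedInstrument], effects_model: str = "auto",
        het_alpha: float = 0.05) -> MREstimate:
    """Inverse-variance-weighted estimate over >= 2 instruments.

    ``effects_model``: "fixed", "random" (multiplicative, underdispersion
    clipped at 1), or "auto" — fixed when Cochran's Q p > ``het_alpha``,
    random otherwise.
    """
    if len(hs) < 2:
        raise ValueError("ivw requires >= 2 instruments; use wald_ratio for a single SNP")
    if effects_model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    bx, _, by, sy = _arrays(hs)
    w = bx**2 / sy**2
    q, beta = ivw_q_statistic(hs)
    se_fixed = float(np.sum(w)) ** -0.5
    j = len(hs)
    if effects_model == "auto":
        q_p = float(stats.chi2.sf(q, j - 1))
        effects_model = "fixed" if q_p > het_alpha else "random"
    if effects_model == "random":
        se = se_fixed * max(1.0, math.sqrt(q / (j - 1)))
    else:
        se = se_fixed
    return _normal_estimate("ivw", beta, se, j, effects_model)


def mr_egger(hs: Sequence[HarmonizedInstrument]) -> tuple[MREstimate, PleiotropyResult]:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Instruments are first oriented so every exposure beta is positive (both
    betas negated where needed); weights are se_out⁻². The residual scale is
    clipped below at 1 (multiplicative overdispersion only) and p-values use
    t with J−2 degrees of freedom.
    """
    j = len(hs)
    if j < 3:
        raise ValueError("mr_egger requires >= 3 instruments")
    bx, _, by, sy = _arrays(hs)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = sy**-2.0
    # weighted normal equations for [intercept, slope]
    x = np.column_stack([np.ones(j), bx])
    xtw = x.T * w
    xtwx = xtw @ x
    coef = np.linalg.solve(xtwx, xtw @ by)
    resid = by - x @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss_w / (j - 2)))
    cov = np.linalg.inv(xtwx) * scale**2
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    tq = stats.t.ppf(0.975, j - 2)
    slope, intercept = float(coef[1]), float(coef[0])
    est = MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pval=float(2.0 * stats.t.sf(abs(slope / se_slope), j - 2)),
        nsnp=j,
        effects_model="not_applicable",
    )
    pleio = PleiotropyResult(
        intercept=intercept,
        se=se_int,
        pval=float(2.0 * stats.t.sf(abs(intercept / se_int), j - 2)),
    )
    return est, pleio


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``ratios`` (weights need not sum to 1)."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def weighted_median(
    hs: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Weights are inverse first-order Wald-ratio variances (beta_exp²/se_out²).
    The bootstrap redraws beta_exp and beta_out from normal distributions at
    their standard errors and recomputes the weighted median ``n_boot`` times.
    """
    j = len(hs)
    if j < 3:
        raise ValueError("weighted_median requires >= 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    bx, sx, by, sy = _arrays(hs)
    ratios = by / bx
    weights = bx**2 / sy**2
    point = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ok = bxs != 0
        boots[b] = _weighted_median_point(bys[ok] / bxs[ok], bxs[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_median", point, se, j)


def to_odds_ratio(e: MREstimate) -> MREstimate:
    """Populate the odds-ratio scale: exp of beta and its CI endpoints."""
    return dc_replace(
        e, or_scale=(math.exp(e.beta), math.exp(e.ci_low), math.exp(e.ci_high))
    )


__all__ = [
    "MREstimate",
    "PleiotropyResult",
    "Z95",
    "ivw",
    "ivw_q_statistic",
    "mr_egger",
    "to_odds_ratio",
    "wald_ratio",
    "weighted_median",
]
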