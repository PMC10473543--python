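"""Sensitivity diagnostics: heterogeneity, pleiotropy, leave-one-out, MR-PRESSO.

The heterogeneity rule mirrors the usual two-sample MR practice: compute
Cochran's Q about the IVW (df J−1) or MR-Egger (df J−2) fit; when its
chi-square p exceeds 0.05 a fixed-effects IVW model is used, otherwise a
multiplicative random-effects model. Directional pleiotropy is screened with
the MR-Egger intercept (pass when |intercept| < 0.1 and p > 0.05), and
instrument-level outliers with MR-PRESSO: a Monte-Carlo residual-sum-of-
squares global test, per-SNP outlier tests with Bonferroni adjustment, an
outlier-corrected IVW estimate, and a distortion test comparing corrected
and uncorrected estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import MREstimate, ivw, ivw_q_statistic, mr_egger
from .harmonize import HarmonizedInstrument

logger = logging.getLogger("mrmediate")


@dataclass(frozen=True)
class HeterogeneityResult:
    q_stat: float
    df: int
    pval: float


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_indices: list[int]
    outlier_pvals: list[float]  # Bonferroni-adjusted, one per instrument
    corrected_estimate: MREstimate | None
    distortion_pval: float | None


def cochran_q(hs: Sequence[HarmonizedInstrument], method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q about the IVW (df J−1) or MR-Egger (df J−2) fitted values."""
    j = len(hs)
    if method == "ivw":
        if j < 2:
            raise ValueError("cochran_q(ivw) requires >= 2 instruments")
        q, _ = ivw_q_statistic(hs)
        df = j - 1
    elif method == "egger":
        if j < 3:
            raise ValueError("cochran_q(egger) requires >= 3 instruments")
        est, pleio = mr_egger(hs)
        bx = np.array([h.beta_exp for h in hs])
        by = np.array([h.beta_out for h in hs])
        sy = np.array([h.se_out for h in hs])
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        fitted = pleio.intercept + est.beta * bx
        q = float(np.sum((by - fitted) ** 2 / sy**2))
        df = j - 2
    else:
        raise ValueError(f"unknown method {method!r}")
    return HeterogeneityResult(q_stat=q, df=df, pval=float(stats.chi2.sf(q, df)))


def select_effects_model(h: HeterogeneityResult, alpha: float = 0.05) -> str:
    """Fixed effects when the heterogeneity p strictly exceeds alpha."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return "fixed" if h.pval > alpha else "random"


def egger_pleiotropy_check(
    pleio, intercept_bound: float = 0.1, alpha: float = 0.05
) -> str:
    """'pass' iff |intercept| < bound and its p > alpha (pleiotropy excluded)."""
    if intercept_bound <= 0 or not (0 < alpha < 1):
        raise ValueError("bounds must be positive / alpha in (0,1)")
    ok = abs(pleio.intercept) < intercept_bound and pleio.pval > alpha
    return "pass" if ok else "fail"


def leave_one_out(
    hs: Sequence[HarmonizedInstrument], effects_model: str = "auto"
) -> tuple[list[tuple[str, MREstimate]], bool]:
    """IVW on every J−1 subset; returns the per-SNP table and a robustness flag.

    The flag is True when every leave-one-out estimate keeps the full-set
    estimate's sign and, if the full-set estimate is significant at 0.05,
    no single exclusion renders it non-significant.
    """
    j = len(hs)
    if j < 3:
        raise ValueError("leave_one_out requires >= 3 instruments")
    full = ivw(hs, effects_model=effects_model)
    results = []
    robust = True
    full_sig = full.pval < 0.05
    for i in range(j):
        subset = [h for k, h in enumerate(hs) if k != i]
        est = ivw(subset, effects_model=effects_model)
        results.append((hs[i].snp_id, est))
        if full.beta != 0 and est.beta * full.beta < 0:
            robust = False
        if full_sig and est.pval >= 0.05:
            robust = False
    return results, robust


def _loo_ivw_matrix(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effects IVW estimates b_{−j} for every j, vectorized."""
    w = bx**2 / sy**2
    wr = bx * by / sy**2  # w_j * r_j
    return (wr.sum() - wr) / (w.sum() - w)


def mr_presso(
    hs: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    Global test: observed residuals d_j = beta_out_j − b_{−j}·beta_exp_j
    (b_{−j} the leave-one-out IVW estimate), RSS_obs = Σ_j d_j²/se_out_j²;
    the null distribution of RSS is simulated by redrawing
    beta_exp*_j ~ N(beta_exp_j, se_exp_j) and
    beta_out*_j ~ N(b_{−j}·beta_exp_j, se_out_j), with the add-one Monte-Carlo
    p-value (1 + #{RSS* >= RSS_obs})/(n_sim + 1).

    Outlier test: per-SNP add-one p of d_j² against its simulated
    distribution, Bonferroni-adjusted across J; adjusted p < ``outlier_alpha``
    flags the SNP. The corrected estimate is IVW on the unflagged set, and the
    distortion p compares the observed shift in the estimate against shifts
    from removing random same-size subsets.
    """
    j = len(hs)
    if j < 4:
        raise ValueError("mr_presso requires >= 4 instruments")
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")
    rng = np.random.default_rng(seed)
    bx = np.array([h.beta_exp for h in hs])
    sx = np.array([h.se_exp for h in hs])
    by = np.array([h.beta_out for h in hs])
    sy = np.array([h.se_out for h in hs])

    b_loo = _loo_ivw_matrix(bx, by, sy)
    d_obs = by - b_loo * bx
    w = sy**-2.0
    rss_obs = float(np.sum(w * d_obs**2))

    # simulate under the no-pleiotropy null (vectorized across n_sim rows)
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(b_loo * bx, sy, size=(n_sim, j))
    w_star = bx_star**2 / sy**2
    wr_star = bx_star * by_star / sy**2
    b_loo_star = (wr_star.sum(axis=1, keepdims=True) - wr_star) / (
        w_star.sum(axis=1, keepdims=True) - w_star
    )
    d_star = by_star - b_loo_star * bx_star
    rss_star = np.sum(w * d_star**2, axis=1)

    global_pval = (1.0 + np.sum(rss_star >= rss_obs)) / (n_sim + 1.0)

    # per-SNP outlier p-values (weighted squared residuals), Bonferroni-adjusted
    raw_p = (1.0 + np.sum(d_star**2 >= d_obs**2, axis=0)) / (n_sim + 1.0)
    adj_p = np.minimum(raw_p * j, 1.0)
    outliers = [int(i) for i in np.flatnonzero(adj_p < outlier_alpha)]

    corrected = None
    distortion_pval = None
    if outliers:
        keep = [i for i in range(j) if i not in outliers]
        if len(keep) < 2:
            raise ValueError("mr_presso flagged all (or all but one) instruments as outliers")
        corrected = ivw([hs[i] for i in keep], effects_model="auto")
        original = ivw(list(hs), effects_model="auto")
        d_shift_obs = abs(original.beta - corrected.beta)
        n_dist = min(n_sim, 1000)
        shifts = np.empty(n_dist)
        for b in range(n_dist):
            drop = rng.choice(j, size=len(outliers), replace=False)
            sub = [hs[i] for i in range(j) if i not in set(drop.tolist())]
            shifts[b] = abs(original.beta - ivw(sub, effects_model="fixed").beta)
        distortion_pval = float((1.0 + np.sum(shifts >= d_shift_obs)) / (n_dist + 1.0))
        logger.info(
            "mr_presso: %d outliers flagged (global p=%.4g, distortion p=%.4g)",
            len(outliers), global_pval, distortion_pval,
        )
    return PressoResult(
        global_rss=rss_obs,
        global_pval=float(global_pval),
        outlier_indices=outliers,
        outlier_pvals=[float(p) for p in adj_p],
        corrected_estimate=corrected,
        distortion_pval=distortion_pval,
    )


__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "cochran_q",
    "egger_pleiotropy_check",
    "leave_one_out",
    "mr_presso",
    "select_effects_model",
]
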