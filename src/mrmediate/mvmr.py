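"""Multivariable MR: joint weighted regression on several exposures.

Used for the second step of two-step mediation MR: the outcome betas are
regressed jointly on the exposure's and the mediator's per-SNP betas (no
intercept, weights se_out⁻²), so the mediator coefficient is its *direct*
effect on the outcome conditional on the exposure. SEs carry a
multiplicative overdispersion scale clipped at 1 and inference uses
t(J − K).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import harmonize_pair
from .instruments import LDMatrix, filter_by_pvalue, ld_clump
from .sumstats import SumStatSet, SumStatsError

logger = logging.getLogger("mrmediate")


@dataclass
class MVMRInput:
    """Per-SNP betas for K exposures plus the outcome, rows complete."""

    snp_ids: list[str]
    exposure_labels: list[str]
    exposure_matrix: np.ndarray  # J x K
    exposure_se_matrix: np.ndarray  # J x K
    beta_out: np.ndarray
    se_out: np.ndarray

    def __post_init__(self) -> None:
        self.exposure_matrix = np.atleast_2d(np.asarray(self.exposure_matrix, float))
        self.exposure_se_matrix = np.atleast_2d(np.asarray(self.exposure_se_matrix, float))
        self.beta_out = np.asarray(self.beta_out, float)
        self.se_out = np.asarray(self.se_out, float)
        j, k = self.exposure_matrix.shape
        if len(self.snp_ids) != j or len(self.beta_out) != j or len(self.se_out) != j:
            raise ValueError("row counts disagree across MVMR input fields")
        if len(self.exposure_labels) != k:
            raise ValueError("exposure label count does not match matrix columns")
        if not np.isfinite(self.exposure_matrix).all():
            raise ValueError("MVMR exposure matrix has missing values; rows must be complete")


@dataclass
class MVMREstimate:
    exposure_labels: list[str]
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    nsnp: int
    conditional_f: np.ndarray | None = None

    def for_exposure(self, label: str) -> tuple[float, float, float]:
        i = self.exposure_labels.index(label)
        return float(self.beta[i]), float(self.se[i]), float(self.pval[i])


def mvmr_fit(inp: MVMRInput) -> MVMREstimate:
    """Weighted least squares of beta_out on the exposure betas, no intercept.

    An exposure column that is identically zero carries no information; it is
    dropped from the fit (coefficient 0, SE inf, p 1) so the remaining
    coefficients reduce to the lower-dimensional fit.
    """
    x_full = inp.exposure_matrix
    j, k_full = x_full.shape
    active = [a for a in range(k_full) if np.any(x_full[:, a] != 0)]
    if not active:
        raise ValueError("all exposure columns are identically zero")
    x = x_full[:, active]
    k = len(active)
    if j <= k:
        raise ValueError(f"MVMR needs more SNPs ({j}) than exposures ({k})")
    w = inp.se_out**-2.0
    xtw = x.T * w
    xtwx = xtw @ x
    rank = np.linalg.matrix_rank(xtwx)
    if rank < k:
        # name the offending columns via pairwise correlation
        corr = np.corrcoef(x, rowvar=False)
        bad = [
            f"{inp.exposure_labels[active[a]]}~{inp.exposure_labels[active[b]]}"
            for a in range(k) for b in range(a + 1, k)
            if abs(np.atleast_2d(corr)[a, b]) > 0.999
        ]
        raise ValueError(f"rank-deficient exposure matrix (collinear: {bad or 'unknown'})")
    coef = np.linalg.solve(xtwx, xtw @ inp.beta_out)
    resid = inp.beta_out - x @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss_w / (j - k)))
    cov = np.linalg.inv(xtwx) * scale**2
    se = np.sqrt(np.diag(cov))
    pval = 2.0 * stats.t.sf(np.abs(coef / se), j - k)

    # conditional instrument strength: residual chi-square of each exposure
    # column after weighted projection on the others, per remaining df
    cond_f = np.empty(k)
    for a in range(k):
        xa = x[:, a]
        wx = inp.exposure_se_matrix[:, active[a]] ** -2.0
        if k == 1:
            resid_a = xa
        else:
            others = np.delete(x, a, axis=1)
            otw = others.T * wx
            gamma = np.linalg.lstsq(otw @ others, otw @ xa, rcond=None)[0]
            resid_a = xa - others @ gamma
        cond_f[a] = float(np.sum(wx * resid_a**2)) / max(j - k + 1, 1)

    # expand back to the full column set: zero columns get (0, inf, 1)
    beta_full = np.zeros(k_full)
    se_full = np.full(k_full, np.inf)
    pval_full = np.ones(k_full)
    cond_full = np.zeros(k_full)
    beta_full[active] = coef
    se_full[active] = se
    pval_full[active] = pval
    cond_full[active] = cond_f
    return MVMREstimate(
        exposure_labels=list(inp.exposure_labels),
        beta=beta_full,
        se=se_full,
        pval=pval_full,
        nsnp=j,
        conditional_f=cond_full,
    )


def build_mvmr_input(
    exposure_sets: list[SumStatSet],
    outcome_set: SumStatSet,
    ld: LDMatrix | None = None,
    p_threshold: float = 5e-8,
    r2_max: float = 0.001,
    window_kb: float = 10000.0,
    palindrome_policy: str = "exclude_palindromic",
) -> MVMRInput:
    """Assemble the joint instrument set for an MVMR fit.

    Instruments are the union of each exposure's genome-wide-significant,
    clumped SNPs, jointly re-clumped across the union on each SNP's best
    p-value; every row is harmonized against all exposures and the outcome
    (the first exposure defines the reference orientation) and SNPs missing
    any trait are dropped with logged counts.
    """
    if len(exposure_sets) < 2:
        raise ValueError("build_mvmr_input requires >= 2 exposure sets")
    union: dict[str, object] = {}
    for es in exposure_sets:
        sig = filter_by_pvalue(es, p_threshold)
        if ld is not None and len(sig):
            sig = ld_clump(sig, ld, r2_max=r2_max, window_kb=window_kb)
        for r in sig.records:
            if r.snp_id not in union or r.pval < union[r.snp_id].pval:
                union[r.snp_id] = r
    if not union:
        raise SumStatsError("no instruments pass selection for any exposure")
    union_set = SumStatSet("mvmr_union", "quantitative", sorted(union.values(), key=lambda r: r.snp_id))
    if ld is not None:
        union_set = ld_clump(union_set, ld, r2_max=r2_max, window_kb=window_kb)

    by_trait = [{r.snp_id: r for r in es.records} for es in exposure_sets]
    out_by_id = {r.snp_id: r for r in outcome_set.records}

    rows = []
    n_missing = n_excluded = 0
    for rec in union_set.records:
        sid = rec.snp_id
        if sid not in out_by_id or any(sid not in bt for bt in by_trait):
            n_missing += 1
            continue
        ref = by_trait[0][sid]
        betas, ses, ok = [], [], True
        for t, bt in enumerate(by_trait):
            if t == 0:
                betas.append(ref.beta)
                ses.append(ref.se)
                continue
            h, status = harmonize_pair(ref, bt[sid], policy=palindrome_policy)
            if h is None:
                ok = False
                break
            betas.append(h.beta_out)
            ses.append(h.se_out)
        if ok:
            h, status = harmonize_pair(ref, out_by_id[sid], policy=palindrome_policy)
            if h is None:
                ok = False
        if not ok:
            n_excluded += 1
            continue
        rows.append((sid, betas, ses, h.beta_out, h.se_out))
    if not rows:
        raise SumStatsError("MVMR instrument set is empty after harmonization")
    logger.info(
        "build_mvmr_input: %d instruments (%d missing a trait, %d excluded in harmonization)",
        len(rows), n_missing, n_excluded,
    )
    return MVMRInput(
        snp_ids=[r[0] for r in rows],
        exposure_labels=[es.trait_label for es in exposure_sets],
        exposure_matrix=np.array([r[1] for r in rows]),
        exposure_se_matrix=np.array([r[2] for r in rows]),
        beta_out=np.array([r[3] for r in rows]),
        se_out=np.array([r[4] for r in rows]),
    )


__all__ = ["MVMREstimate", "MVMRInput", "build_mvmr_input", "mvmr_fit"]
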