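"""Synthetic GWAS summary statistics with known causal structure.

The generator emulates the summary-level inputs of a two-sample, two-step MR
study of a psychiatric exposure, a behavioural mediator and a case-control
outcome, without any individual-level genotypes. Per SNP j:

* minor-allele frequency maf_j ~ Uniform(maf_range);
* true SNP->exposure effect gamma_j ~ Normal(0, gamma_sd²) for the
  ``n_snps`` exposure instruments (zero for mediator-specific SNPs);
* true SNP->mediator effect delta_j = b1·gamma_j for exposure instruments,
  and delta_j ~ Normal(0, delta_sd²) for the ``n_med_snps``
  mediator-specific instruments;
* true SNP->outcome effect Gamma_j = direct_effect·gamma_j + b2·delta_j +
  alpha_j, where alpha_j is a horizontal-pleiotropy effect drawn
  Normal(pleiotropy_mean, pleiotropy_sd²) for a ``pleiotropy_frac`` subset
  (mean 0 = balanced, nonzero = directional) and zero elsewhere.

Observed betas are drawn around the truth with per-SNP standard errors from
the standard per-allele variance approximation se ≈ 1/sqrt(2·maf·(1−maf)·n),
with the effective n of the binary outcome shrunk by the case-control
variance factor k·(1−k). P-values are the two-sided normal p of beta/se.
The exposure-outcome total effect is therefore direct_effect + b1·b2 and the
true proportion mediated b1·b2/(direct_effect + b1·b2).

Palindromic allele pairs (A/T, C/G) and discordant allele codings (swapped
effect/other allele with negated beta and complemented EAF in the mediator
and outcome files) are injected at configurable rates, with bookkeeping in
:class:`SimTruth` so harmonization can be audited against ground truth.
Default sample sizes and effect sizes mirror a schizophrenia -> smoking ->
breast-cancer analysis (exposure GWAS n≈150k, mediator n≈633k, outcome
n=228,951 with 53.7% cases, total effect ln 1.06, b1=0.0438, b2=0.1467).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .instruments import LDMatrix, write_ld_matrix
from .sumstats import SumStatSet, from_arrays, write_sumstats

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of one synthetic dataset (seed mandatory)."""

    seed: int
    n_snps: int = 150  # exposure instruments
    n_med_snps: int = 150  # mediator-specific instruments (needed for MVMR)
    n_exp: float = 150_064
    n_med: float = 632_802
    n_out: float = 228_951
    k_cases: float = 122_977 / 228_951  # outcome case fraction
    gamma_sd: float = 0.03
    delta_sd: float = 0.015
    direct_effect: float = float(np.log(1.06))
    b1: float = 0.0438  # exposure -> mediator
    b2: float = 0.1467  # mediator -> outcome
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    frac_palindromic: float = 0.0
    frac_allele_swapped: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1  # >1 switches on block LD (exercises clumping)
    ld_block_r2: float = 0.0

    def validate(self) -> None:
        fracs = {
            "pleiotropy_frac": self.pleiotropy_frac,
            "frac_palindromic": self.frac_palindromic,
            "frac_allele_swapped": self.frac_allele_swapped,
            "k_cases": self.k_cases,
        }
        for name, v in fracs.items():
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name, v in (("gamma_sd", self.gamma_sd), ("delta_sd", self.delta_sd),
                        ("pleiotropy_sd", self.pleiotropy_sd)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.gamma_sd == 0 and (self.direct_effect != 0 or self.b1 != 0):
            raise ValueError(
                "degenerate config: gamma_sd = 0 leaves no exposure instruments "
                "to carry the requested nonzero effects"
            )
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


@dataclass
class SimTruth:
    """Ground truth kept alongside the generated summary statistics."""

    snp_ids: list[str]
    maf: np.ndarray
    gamma: np.ndarray  # SNP -> exposure
    delta: np.ndarray  # SNP -> mediator
    alpha: np.ndarray  # SNP -> outcome, not through exposure/mediator
    direct_effect: float
    b1: float
    b2: float
    palindromic: np.ndarray  # bool mask
    swapped_med: np.ndarray  # bool mask, mediator file coding swapped
    swapped_out: np.ndarray  # bool mask, outcome file coding swapped
    config: SimConfig | None = None

    @property
    def total_effect(self) -> float:
        return self.direct_effect + self.b1 * self.b2

    @property
    def proportion_mediated_true(self) -> float:
        return self.b1 * self.b2 / self.total_effect

    def to_json_dict(self) -> dict:
        d = {
            "snp_ids": self.snp_ids,
            "maf": self.maf.tolist(),
            "gamma": self.gamma.tolist(),
            "delta": self.delta.tolist(),
            "alpha": self.alpha.tolist(),
            "direct_effect": self.direct_effect,
            "b1": self.b1,
            "b2": self.b2,
            "total_effect": self.total_effect,
            "proportion_mediated_true": self.proportion_mediated_true,
            "palindromic": self.palindromic.astype(int).tolist(),
            "swapped_med": self.swapped_med.astype(int).tolist(),
            "swapped_out": self.swapped_out.astype(int).tolist(),
        }
        if self.config is not None:
            cfg = dataclasses.asdict(self.config)
            cfg["maf_range"] = list(cfg["maf_range"])
            d["config"] = cfg
        return d


def _se_quantitative(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _se_binary(maf: np.ndarray, n: float, k: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * k * (1.0 - k))


def simulate_sumstats(
    cfg: SimConfig,
) -> tuple[SumStatSet, SumStatSet, SumStatSet, LDMatrix, SimTruth]:
    """Generate paired exposure/mediator/outcome summary statistics.

    Returns ``(exposure, mediator, outcome, ld, truth)``. Bit-reproducible
    for a fixed config (single seeded generator, fixed draw order).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps + cfg.n_med_snps
    snp_ids = [f"rs{100000 + i}" for i in range(j)]

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=j)
    gamma = np.zeros(j)
    gamma[: cfg.n_snps] = rng.normal(0.0, cfg.gamma_sd, size=cfg.n_snps)
    delta = cfg.b1 * gamma
    if cfg.n_med_snps:
        delta[cfg.n_snps:] = rng.normal(0.0, cfg.delta_sd, size=cfg.n_med_snps)
    alpha = np.zeros(j)
    if cfg.pleiotropy_frac > 0:
        mask = rng.random(j) < cfg.pleiotropy_frac
        alpha[mask] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=int(mask.sum()))
    # pleiotropy is defined relative to the exposure-increasing allele (the
    # orientation MR-Egger uses), so its direction survives instrument
    # re-orientation; on the reported effect allele it enters as sign(gamma)·alpha
    big_gamma = cfg.direct_effect * gamma + cfg.b2 * delta + np.where(gamma < 0, -1.0, 1.0) * alpha

    se_exp = _se_quantitative(maf, cfg.n_exp)
    se_med = _se_quantitative(maf, cfg.n_med)
    se_out = _se_binary(maf, cfg.n_out, cfg.k_cases)
    beta_exp = rng.normal(gamma, se_exp)
    beta_med = rng.normal(delta, se_med)
    beta_out = rng.normal(big_gamma, se_out)

    palindromic = rng.random(j) < cfg.frac_palindromic
    pair_pick = rng.integers(0, 8, size=j)
    ea = np.empty(j, dtype=object)
    oa = np.empty(j, dtype=object)
    for i in range(j):
        pool = _PALINDROMIC_PAIRS if palindromic[i] else _NONPALINDROMIC_PAIRS
        ea[i], oa[i] = pool[pair_pick[i] % len(pool)]
    swapped_med = rng.random(j) < cfg.frac_allele_swapped
    swapped_out = rng.random(j) < cfg.frac_allele_swapped

    exp_set = from_arrays(
        "exposure", "binary", snp_ids, ea, oa, beta_exp, se_exp, eaf=maf, n=cfg.n_exp
    )

    def _coded(betas, ses, swap_mask, n, label, trait_type):
        ea2 = np.where(swap_mask, oa, ea)
        oa2 = np.where(swap_mask, ea, oa)
        b2_ = np.where(swap_mask, -betas, betas)
        eaf2 = np.where(swap_mask, 1.0 - maf, maf)
        return from_arrays(label, trait_type, snp_ids, ea2, oa2, b2_, ses, eaf=eaf2, n=n)

    med_set = _coded(beta_med, se_med, swapped_med, cfg.n_med, "mediator", "quantitative")
    out_set = _coded(beta_out, se_out, swapped_out, cfg.n_out, "outcome", "binary")

    if cfg.ld_block_size > 1 and cfg.ld_block_r2 > 0:
        r2 = np.eye(j)
        for start in range(0, j, cfg.ld_block_size):
            stop = min(start + cfg.ld_block_size, j)
            r2[start:stop, start:stop] = cfg.ld_block_r2
            np.fill_diagonal(r2[start:stop, start:stop], 1.0)
        ld = LDMatrix(snp_ids, r2)
    else:
        ld = LDMatrix.identity(snp_ids)

    truth = SimTruth(
        snp_ids=snp_ids, maf=maf, gamma=gamma, delta=delta, alpha=alpha,
        direct_effect=cfg.direct_effect, b1=cfg.b1, b2=cfg.b2,
        palindromic=palindromic, swapped_med=swapped_med, swapped_out=swapped_out,
        config=cfg,
    )
    return exp_set, med_set, out_set, ld, truth


#: deterministic small scenarios for regression tests (J <= 30)
FIXTURES: dict[str, SimConfig] = {
    "clean": SimConfig(seed=20230901, n_snps=20, n_med_snps=0),
    "null": SimConfig(
        seed=20230902, n_snps=20, n_med_snps=0, direct_effect=0.0, b1=0.0, b2=0.0
    ),
    "one_outlier": SimConfig(seed=20230903, n_snps=20, n_med_snps=0),
    "directional_pleiotropy": SimConfig(
        seed=20230904, n_snps=25, n_med_snps=0,
        pleiotropy_frac=1.0, pleiotropy_mean=0.025, pleiotropy_sd=0.005,
    ),
    "full_mediation": SimConfig(
        seed=20230905, n_snps=15, n_med_snps=20,
        direct_effect=0.0, b1=0.1, b2=0.5, delta_sd=0.02,
    ),
}


def make_fixture(name: str):
    """Generate a named deterministic scenario.

    Returns ``(exposure, mediator, outcome, ld, truth)``. ``one_outlier``
    displaces the first SNP's outcome beta by exactly 10·se_out, recorded in
    ``truth.alpha``.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    exp_set, med_set, out_set, ld, truth = simulate_sumstats(FIXTURES[name])
    if name == "one_outlier":
        rec = out_set.records[0]
        shift = 10.0 * rec.se
        displaced = dataclasses.replace(rec, beta=rec.beta + shift)
        out_set.records[0] = dataclasses.replace(displaced, pval=displaced.pval_from_z())
        truth.alpha = truth.alpha.copy()
        truth.alpha[0] += shift if not truth.swapped_out[0] else -shift
    return exp_set, med_set, out_set, ld, truth


def save_dataset(dataset, outdir) -> None:
    """Write a simulated dataset (TSVs, LD matrix, truth JSON) to a directory."""
    exp_set, med_set, out_set, ld, truth = dataset
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sumstats(exp_set, outdir / "exposure.tsv")
    write_sumstats(med_set, outdir / "mediator.tsv")
    write_sumstats(out_set, outdir / "outcome.tsv")
    write_ld_matrix(ld, outdir / "ld.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)


__all__ = ["FIXTURES", "SimConfig", "SimTruth", "make_fixture", "save_dataset", "simulate_sumstats"]
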