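"""Allele harmonization for two-sample MR.

Exposure and outcome summary statistics come from different consortia, which
need not agree on which allele is the "effect" allele nor on strand
convention. Harmonization puts each SNP's outcome association on the
exposure's effect-allele orientation:

* identical allele pair -> keep as is;
* swapped alleles -> negate the outcome beta (and complement its EAF);
* alleles matching only after strand complement (A<->T, C<->G) -> complement,
  then apply the same logic;
* palindromic SNPs (A/T or C/G) are strand-ambiguous and are excluded under
  the default policy; an optional frequency-inference policy keeps them when
  both EAFs are far from 0.5 and orients by frequency concordance;
* irreconcilable allele sets are excluded with a reason.

Each retained pair carries its Wald ratio (beta_out/beta_exp), its
first-order standard error (se_out/|beta_exp|) and the IVW weight
(beta_exp²/se_out²), which downstream estimators consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .sumstats import SumStatRecord, SumStatSet, SumStatsError, VALID_ALLELES

logger = logging.getLogger("mrmediate")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: |EAF - 0.5| must exceed 0.5 - this for frequency-based palindrome rescue
PALINDROME_EAF_THRESHOLD = 0.42


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    for a in (effect_allele, other_allele):
        if a not in VALID_ALLELES:
            raise SumStatsError(f"invalid allele {a!r}")
    return _COMPLEMENT[effect_allele] == other_allele


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure-outcome SNP pair on a common effect-allele orientation."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None

    @property
    def wald_ratio(self) -> float:
        return self.beta_out / self.beta_exp

    @property
    def wald_se(self) -> float:
        return self.se_out / abs(self.beta_exp)

    @property
    def weight(self) -> float:
        """IVW weight: inverse first-order variance of the Wald ratio."""
        return self.beta_exp**2 / self.se_out**2


@dataclass
class HarmonizeReport:
    """Bookkeeping: every matched input pair is accounted for exactly once."""

    n_input: int = 0
    n_harmonized: int = 0
    n_palindromic_excluded: int = 0
    n_allele_mismatch: int = 0
    n_zero_beta_exp: int = 0
    n_flipped: int = 0

    def check(self) -> None:
        total = (
            self.n_harmonized
            + self.n_palindromic_excluded
            + self.n_allele_mismatch
            + self.n_zero_beta_exp
        )
        if total != self.n_input:
            raise AssertionError(f"harmonization bookkeeping broken: {self}")


def harmonize_pair(
    exp: SumStatRecord,
    out: SumStatRecord,
    policy: str = "exclude_palindromic",
):
    """Harmonize one exposure/outcome record pair.

    Returns ``(HarmonizedInstrument | None, status)`` where status is one of
    ``"ok"``, ``"flipped"`` (ok after swap), ``"palindromic"``,
    ``"allele_mismatch"``, ``"zero_beta_exp"``.
    """
    if exp.snp_id != out.snp_id:
        raise SumStatsError(f"snp id mismatch: {exp.snp_id} vs {out.snp_id}")
    if policy not in ("exclude_palindromic", "infer_palindromic"):
        raise ValueError(f"unknown palindrome policy {policy!r}")

    ea, oa = exp.effect_allele, exp.other_allele
    ea2, oa2 = out.effect_allele, out.other_allele

    if is_palindromic(ea, oa) or is_palindromic(ea2, oa2):
        return _handle_palindrome(exp, out, policy)

    flipped = False
    if (ea2, oa2) == (ea, oa):
        pass
    elif (ea2, oa2) == (oa, ea):
        flipped = True
    else:
        # try strand complement
        cea2, coa2 = _COMPLEMENT[ea2], _COMPLEMENT[oa2]
        if (cea2, coa2) == (ea, oa):
            pass
        elif (cea2, coa2) == (oa, ea):
            flipped = True
        else:
            return None, "allele_mismatch"

    beta_out = -out.beta if flipped else out.beta
    h, status = _build(exp, beta_out, out.se)
    if h is None:
        return None, status
    return h, ("flipped" if flipped else "ok")


def _handle_palindrome(exp: SumStatRecord, out: SumStatRecord, policy: str):
    ea, oa = exp.effect_allele, exp.other_allele
    ea2, oa2 = out.effect_allele, out.other_allele
    if not (is_palindromic(ea, oa) and is_palindromic(ea2, oa2) and {ea2, oa2} == {ea, oa}):
        return None, "allele_mismatch"
    if policy == "exclude_palindromic":
        return None, "palindromic"
    # frequency inference: both EAFs must be informative and far from 0.5
    t = PALINDROME_EAF_THRESHOLD
    if exp.eaf is None or out.eaf is None:
        return None, "palindromic"
    if not (min(exp.eaf, 1 - exp.eaf) < t and min(out.eaf, 1 - out.eaf) < t):
        return None, "palindromic"
    # orient by frequency concordance: same-side minor allele => same orientation
    same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
    nominal_same = (ea2, oa2) == (ea, oa)
    flip = same_side != nominal_same
    beta_out = -out.beta if flip else out.beta
    h, status = _build(exp, beta_out, out.se)
    if h is None:
        return None, status
    return h, ("flipped" if flip else "ok")


def _build(exp: SumStatRecord, beta_out: float, se_out: float):
    if exp.beta == 0:
        return None, "zero_beta_exp"
    h = HarmonizedInstrument(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=se_out,
        eaf_exp=exp.eaf,
    )
    return h, "ok"


def harmonize_sets(
    exp_set: SumStatSet,
    out_set: SumStatSet,
    policy: str = "exclude_palindromic",
) -> tuple[list[HarmonizedInstrument], HarmonizeReport]:
    """Inner-join on snp id and harmonize every matched pair.

    Order follows the exposure set. Raises if the two sets share no SNPs.
    """
    out_by_id = {r.snp_id: r for r in out_set.records}
    matched = [r for r in exp_set.records if r.snp_id in out_by_id]
    if not matched:
        raise SumStatsError(
            f"no shared SNPs between {exp_set.trait_label} and {out_set.trait_label}"
        )
    report = HarmonizeReport(n_input=len(matched))
    harmonized: list[HarmonizedInstrument] = []
    for exp in matched:
        h, status = harmonize_pair(exp, out_by_id[exp.snp_id], policy=policy)
        if h is not None:
            harmonized.append(h)
            report.n_harmonized += 1
            if status == "flipped":
                report.n_flipped += 1
        elif status == "palindromic":
            report.n_palindromic_excluded += 1
        elif status == "zero_beta_exp":
            report.n_zero_beta_exp += 1
        else:
            report.n_allele_mismatch += 1
    report.check()
    logger.info(
        "harmonize(%s -> %s): %d input, %d kept (%d flipped), %d palindromic, %d mismatch",
        exp_set.trait_label, out_set.trait_label, report.n_input, report.n_harmonized,
        report.n_flipped, report.n_palindromic_excluded, report.n_allele_mismatch,
    )
    return harmonized, report


def harmonized_to_dataframe(hs: list[HarmonizedInstrument]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": [h.snp_id for h in hs],
            "beta_exp": [h.beta_exp for h in hs],
            "se_exp": [h.se_exp for h in hs],
            "beta_out": [h.beta_out for h in hs],
            "se_out": [h.se_out for h in hs],
            "wald_ratio": [h.wald_ratio for h in hs],
            "wald_se": [h.wald_se for h in hs],
        }
    )


def write_harmonized(hs: list[HarmonizedInstrument], path) -> None:
    harmonized_to_dataframe(hs).to_csv(path, sep="\t", index=False, float_format="%.10g")


__all__ = [
    "HarmonizeReport",
    "HarmonizedInstrument",
    "PALINDROME_EAF_THRESHOLD",
    "harmonize_pair",
    "harmonize_sets",
    "harmonized_to_dataframe",
    "is_palindromic",
    "write_harmonized",
]
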