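"""Reading, validating and writing GWAS summary statistics.

The canonical on-disk format is a tab-separated file with a header row and
columns ``snp, effect_allele, other_allele, eaf, beta, se, pval, n`` (``NA``
for missing values). Files produced by other consortia are absorbed through a
*dialect*: a mapping from the canonical column names to the names actually
present in the file. Gzip-compressed files are read and written transparently
(pandas dispatches on the ``.gz`` suffix).

Rows violating hard invariants (non-ACGT or identical alleles, ``se <= 0``,
``eaf`` outside [0, 1], ``pval`` outside (0, 1]) are dropped and counted;
a p-value inconsistent with |beta/se| under the two-sided normal
approximation by more than a factor of ten only triggers a warning, because
published summary statistics are routinely rounded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrmediate")

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of the on-disk format
CANONICAL_COLUMNS = ("snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")

#: columns that must be present (possibly via a dialect mapping)
MANDATORY_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se")


class SumStatsError(ValueError):
    """Fatal problem with a summary-statistics file or record."""


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP's association with one trait.

    ``beta`` is on the log-odds scale for binary traits and in trait units
    otherwise; ``se`` is its standard error; ``eaf`` is the effect-allele
    frequency and may be missing (None), as may the sample size ``n``.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise SumStatsError(
                f"{self.snp_id}: alleles must be single-base A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise SumStatsError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise SumStatsError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not math.isfinite(self.beta):
            raise SumStatsError(f"{self.snp_id}: beta is not finite")
        if not (0 < self.pval <= 1):
            raise SumStatsError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SumStatsError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.n is not None and self.n < 1:
            raise SumStatsError(f"{self.snp_id}: n must be >= 1, got {self.n}")

    def zscore(self) -> float:
        return self.beta / self.se

    def pval_from_z(self) -> float:
        """Two-sided normal p implied by beta/se."""
        return float(2.0 * stats.norm.sf(abs(self.zscore())))


@dataclass
class SumStatSet:
    """Ordered collection of :class:`SumStatRecord` with unique SNP ids."""

    trait_label: str
    trait_type: str  # "binary" | "quantitative"
    records: list[SumStatRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise SumStatsError(f"trait_type must be binary|quantitative, got {self.trait_type}")
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise SumStatsError(f"duplicate snp ids in {self.trait_label}: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> SumStatRecord:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    def subset(self, keep: Iterable[str]) -> "SumStatSet":
        keep = set(keep)
        return SumStatSet(
            trait_label=self.trait_label,
            trait_type=self.trait_type,
            records=[r for r in self.records if r.snp_id in keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "snp": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": np.nan if r.n is None else r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _float_or_none(x) -> float | None:
    if x is None:
        return None
    try:
        v = float(x)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_label: str = "trait",
    trait_type: str = "quantitative",
) -> tuple[SumStatSet, dict]:
    """Read a delimited summary-statistics file into a validated SumStatSet.

    Parameters
    ----------
    path
        Delimited text file with a header row (``.gz`` handled transparently).
    dialect
        Mapping from canonical column names (:data:`CANONICAL_COLUMNS`) to the
        file's column names, e.g. ``{"snp": "SNP", "beta": "b"}``. Canonical
        names absent from the mapping are looked up verbatim.

    Returns
    -------
    (SumStatSet, meta)
        ``meta`` counts rows read, kept and dropped (with reasons).
    """
    import csv as _csv

    dialect = dict(dialect or {})
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, _csv.Error):
        raise SumStatsError(f"{path}: file is empty or not delimited text") from None
    if df.empty and df.columns.empty:
        raise SumStatsError(f"{path}: file is empty")

    colmap = {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}
    for canon in MANDATORY_COLUMNS:
        if colmap[canon] not in df.columns:
            raise SumStatsError(f"{path}: missing mandatory column '{colmap[canon]}' (for '{canon}')")

    have_pval = colmap["pval"] in df.columns
    have_eaf = colmap["eaf"] in df.columns
    have_n = colmap["n"] in df.columns

    records: list[SumStatRecord] = []
    drop_reasons: dict[str, int] = {}
    n_pz_warn = 0
    for _, row in df.iterrows():
        try:
            beta = float(row[colmap["beta"]])
            se = float(row[colmap["se"]])
            if have_pval and _float_or_none(row[colmap["pval"]]) is not None:
                pval = float(row[colmap["pval"]])
            else:
                # rebuild from z when absent: standard for files lacking p
                pval = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else math.nan
                pval = max(pval, 5e-324)
            rec = SumStatRecord(
                snp_id=str(row[colmap["snp"]]),
                effect_allele=str(row[colmap["effect_allele"]]).upper(),
                other_allele=str(row[colmap["other_allele"]]).upper(),
                beta=beta,
                se=se,
                pval=pval,
                eaf=_float_or_none(row[colmap["eaf"]]) if have_eaf else None,
                n=_float_or_none(row[colmap["n"]]) if have_n else None,
            )
            rec.validate()
        except (SumStatsError, ValueError, TypeError) as exc:
            reason = str(exc)
            key = "invalid_allele" if "allele" in reason else (
                "bad_se" if "se" in reason.split(":")[-1] else "invalid_value"
            )
            drop_reasons[key] = drop_reasons.get(key, 0) + 1
            continue
        # soft check: p consistent with |beta/se| within a factor of 10
        pz = rec.pval_from_z()
        if pz > 0 and rec.pval > 0 and abs(math.log10(rec.pval) - math.log10(max(pz, 5e-324))) > 1:
            n_pz_warn += 1
        records.append(rec)

    n_dropped = sum(drop_reasons.values())
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d invalid rows: %s", path, n_dropped, drop_reasons)
    if n_pz_warn:
        logger.warning(
            "read_sumstats(%s): %d rows with p-value inconsistent with beta/se (>10x)",
            path, n_pz_warn,
        )
    meta = {
        "n_read": int(len(df)),
        "n_kept": len(records),
        "n_dropped": n_dropped,
        "drop_reasons": drop_reasons,
        "n_pz_inconsistent": n_pz_warn,
    }
    sset = SumStatSet(trait_label=trait_label, trait_type=trait_type, records=records)
    return sset, meta


def write_sumstats(sset: SumStatSet, path) -> None:
    """Write the canonical TSV (columns :data:`CANONICAL_COLUMNS`, NA token).

    Numeric fields are written with 10 significant digits so that
    ``read_sumstats(write_sumstats(s))`` reproduces ``s``.
    """
    df = sset.to_dataframe()
    try:
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    except OSError as exc:
        raise SumStatsError(f"cannot write {path}: {exc}") from exc


def from_arrays(
    trait_label: str,
    trait_type: str,
    snp_ids: Sequence[str],
    effect_allele: Sequence[str],
    other_allele: Sequence[str],
    beta: Sequence[float],
    se: Sequence[float],
    pval: Sequence[float] | None = None,
    eaf: Sequence[float] | None = None,
    n: float | Sequence[float] | None = None,
) -> SumStatSet:
    """Assemble a SumStatSet from parallel arrays (used by the simulator)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if pval is None:
        pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    pval = np.maximum(np.asarray(pval, dtype=float), 5e-324)
    if np.isscalar(n) or n is None:
        n = [n] * len(beta)
    recs = []
    for i, sid in enumerate(snp_ids):
        rec = SumStatRecord(
            snp_id=str(sid),
            effect_allele=effect_allele[i],
            other_allele=other_allele[i],
            beta=float(beta[i]),
            se=float(se[i]),
            pval=float(pval[i]),
            eaf=None if eaf is None else float(eaf[i]),
            n=None if n[i] is None else float(n[i]),
        )
        rec.validate()
        recs.append(rec)
    return SumStatSet(trait_label=trait_label, trait_type=trait_type, records=recs)


__all__ = [
    "CANONICAL_COLUMNS",
    "MANDATORY_COLUMNS",
    "SumStatRecord",
    "SumStatSet",
    "SumStatsError",
    "from_arrays",
    "read_sumstats",
    "write_sumstats",
]
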