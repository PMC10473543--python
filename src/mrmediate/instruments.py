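"""Instrument selection and strength grading.

Instruments are SNPs robustly associated with the exposure: genome-wide
significant (p < 5e-8 by default), mutually quasi-independent after greedy LD
clumping (r² < 0.001 within 10 Mb by default), and strong (F = beta²/se² > 10).
The variance in the exposure explained by an instrument is approximated by
2·EAF·(1−EAF)·beta², and summed over instruments for the power calculation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import SumStatSet, SumStatsError

logger = logging.getLogger("mrmediate")


@dataclass
class LDMatrix:
    """Squared-correlation matrix between SNPs, with optional positions (bp)."""

    snp_ids: list[str]
    r2: np.ndarray
    positions: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 matrix shape {self.r2.shape} does not match {k} snp ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-9):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-9):
            raise ValueError("r2 diagonal must be exactly 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @classmethod
    def identity(cls, snp_ids, positions=None) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(list(snp_ids))), positions)

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD matrix from TSV.

    Two layouts are accepted: square (header row of snp ids, first column of
    snp ids) and long (three columns snp_a, snp_b, r2; missing pairs are 0).
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if len(df.columns) == 3 and set(cols) >= {"snp_a", "snp_b", "r2"}:
        df.columns = cols
        ids = sorted(set(df["snp_a"]).union(df["snp_b"]))
        idx = {s: i for i, s in enumerate(ids)}
        mat = np.eye(len(ids))
        for _, row in df.iterrows():
            i, j = idx[row["snp_a"]], idx[row["snp_b"]]
            mat[i, j] = mat[j, i] = float(row["r2"])
        return LDMatrix(ids, mat)
    # square layout: first column holds the row snp ids
    ids = [str(s) for s in df.iloc[:, 0]]
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    header_ids = [str(c) for c in df.columns[1:]]
    if header_ids != ids:
        raise SumStatsError("square LD matrix header ids do not match row ids")
    return LDMatrix(ids, mat)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    df = pd.DataFrame(ld.r2, columns=ld.snp_ids)
    df.insert(0, "snp", ld.snp_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass(frozen=True)
class InstrumentMetrics:
    snp_id: str
    f_stat: float
    r2_explained: float | None


def filter_by_pvalue(sset: SumStatSet, threshold: float = 5e-8) -> SumStatSet:
    """Keep records with p strictly below ``threshold``, preserving order."""
    if not (0 < threshold < 1) and threshold != 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept = [r for r in sset.records if r.pval < threshold or threshold == 1.0]
    if not kept:
        logger.warning("filter_by_pvalue(%s): no records below %g", sset.trait_label, threshold)
    return SumStatSet(sset.trait_label, sset.trait_type, kept)


def ld_clump(
    sset: SumStatSet,
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_kb: float = 10000.0,
) -> SumStatSet:
    """Greedy LD clumping: best p first, discard correlated/nearby neighbours.

    Repeatedly select the remaining SNP with the smallest p-value (ties broken
    by lexicographic snp id) and discard every remaining SNP whose r² with it
    is >= ``r2_max`` and — when positions are available — that lies within
    ``window_kb`` of it. With r²-only input the r² criterion alone governs.
    The result keeps the input's record objects, ordered by selection.
    """
    if not (0 < r2_max < 1):
        raise ValueError(f"r2_max must be in (0, 1), got {r2_max}")
    if window_kb <= 0:
        raise ValueError(f"window_kb must be > 0, got {window_kb}")
    missing = [r.snp_id for r in sset.records if r.snp_id not in ld]
    if missing:
        raise SumStatsError(f"SNPs missing from LD matrix: {missing}")

    pos = ld.positions
    remaining = sorted(sset.records, key=lambda r: (r.pval, r.snp_id))
    selected = []
    while remaining:
        index = remaining.pop(0)
        selected.append(index)
        survivors = []
        for r in remaining:
            conflict = ld.lookup(index.snp_id, r.snp_id) >= r2_max
            if conflict and pos is not None and index.snp_id in pos and r.snp_id in pos:
                conflict = abs(pos[index.snp_id] - pos[r.snp_id]) <= window_kb * 1000.0
            if not conflict:
                survivors.append(r)
        remaining = survivors
    logger.info("ld_clump(%s): %d -> %d index SNPs", sset.trait_label, len(sset), len(selected))
    return SumStatSet(sset.trait_label, sset.trait_type, selected)


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, beta²/se²."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def filter_by_f(sset: SumStatSet, f_min: float = 10.0) -> SumStatSet:
    """Keep records with F = beta²/se² strictly above ``f_min``."""
    if f_min < 0:
        raise ValueError(f"f_min must be >= 0, got {f_min}")
    kept = [r for r in sset.records if f_statistic(r.beta, r.se) > f_min]
    if kept:
        fs = [f_statistic(r.beta, r.se) for r in kept]
        logger.info(
            "filter_by_f(%s): kept %d/%d, F range %.2f-%.2f",
            sset.trait_label, len(kept), len(sset), min(fs), max(fs),
        )
    return SumStatSet(sset.trait_label, sset.trait_type, kept)


def instrument_metrics(sset: SumStatSet) -> list[InstrumentMetrics]:
    out = []
    for r in sset.records:
        r2x = None if r.eaf is None else 2.0 * r.eaf * (1.0 - r.eaf) * r.beta**2
        out.append(InstrumentMetrics(r.snp_id, f_statistic(r.beta, r.se), r2x))
    return out


def total_variance_explained(sset: SumStatSet) -> float:
    """Sum of 2·EAF·(1−EAF)·beta² over records (R²xz of the instrument set)."""
    missing = [r.snp_id for r in sset.records if r.eaf is None]
    if missing:
        raise SumStatsError(f"records missing eaf: {missing}")
    return float(sum(2.0 * r.eaf * (1.0 - r.eaf) * r.beta**2 for r in sset.records))


def select_instruments(
    sset: SumStatSet,
    ld: LDMatrix | None = None,
    p_threshold: float = 5e-8,
    r2_max: float = 0.001,
    window_kb: float = 10000.0,
    f_min: float = 10.0,
) -> SumStatSet:
    """Full selection cascade: p filter -> LD clump -> F filter."""
    out = filter_by_pvalue(sset, p_threshold)
    if ld is not None and len(out):
        out = ld_clump(out, ld, r2_max=r2_max, window_kb=window_kb)
    return filter_by_f(out, f_min)


__all__ = [
    "InstrumentMetrics",
    "LDMatrix",
    "f_statistic",
    "filter_by_f",
    "filter_by_pvalue",
    "instrument_metrics",
    "ld_clump",
    "read_ld_matrix",
    "select_instruments",
    "total_variance_explained",
    "write_ld_matrix",
]
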