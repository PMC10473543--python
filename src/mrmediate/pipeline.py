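"""Config-driven orchestration of the full two-sample / two-step MR workflow.

``analyze_pair`` runs one exposure-outcome analysis in memory: instrument
selection (p < 5e-8, LD clumping, F > 10), harmonization, the three
estimators (IVW with the heterogeneity-driven fixed/random rule, MR-Egger,
weighted median) and the sensitivity battery (Cochran's Q, Egger intercept,
leave-one-out, MR-PRESSO). ``run_two_sample`` applies it to every configured
exposure x outcome pair; ``run_two_step`` adds the mediation analysis:
beta1 per mediator by two-sample MR, beta2 by multivariable MR with the
exposure as covariate, then the significance decision table and the
proportion mediated. Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import ivw, mr_egger, to_odds_ratio, wald_ratio, weighted_median
from .harmonize import harmonize_sets
from .instruments import LDMatrix, read_ld_matrix, select_instruments
from .mediation import EffectWithP, MediationInput, classify_mediation
from .mvmr import build_mvmr_input, mvmr_fit
from .power import power_grid
from .sensitivity import cochran_q, egger_pleiotropy_check, leave_one_out, mr_presso
from .sumstats import SumStatSet, read_sumstats

logger = logging.getLogger("mrmediate")


@dataclass
class TraitSource:
    """Where one trait's summary statistics come from."""

    label: str
    path: str
    trait_type: str = "quantitative"
    dialect: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are the study's printed settings."""

    exposures: list[TraitSource] = field(default_factory=list)
    mediators: list[TraitSource] = field(default_factory=list)
    outcomes: list[TraitSource] = field(default_factory=list)
    ld_path: str | None = None
    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10000.0
    f_min: float = 10.0
    alpha: float = 0.05
    egger_intercept_bound: float = 0.1
    palindrome_policy: str = "exclude_palindromic"
    presso_n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0
    output_dir: str = "mr_output"
    make_plots: bool = False

    def validate(self) -> None:
        checks = [
            (0 < self.p_instrument < 1, "p_instrument must be in (0,1)"),
            (0 < self.clump_r2 < 1, "clump_r2 must be in (0,1)"),
            (self.clump_kb > 0, "clump_kb must be > 0"),
            (self.f_min >= 0, "f_min must be >= 0"),
            (0 < self.alpha < 1, "alpha must be in (0,1)"),
            (self.egger_intercept_bound > 0, "egger_intercept_bound must be > 0"),
            (self.presso_n_sim >= 100, "presso_n_sim must be >= 100"),
            (self.n_boot >= 100, "n_boot must be >= 100"),
            (isinstance(self.seed, int), "seed must be an integer"),
            (self.palindrome_policy in ("exclude_palindromic", "infer_palindromic"),
             "unknown palindrome_policy"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("exposures", "mediators", "outcomes"):
            raw[key] = [TraitSource(**t) for t in raw.get(key, [])]
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class PairResult:
    """One exposure-outcome analysis: estimates plus diagnostics."""

    exposure: str
    outcome: str
    nsnp: int
    estimates: dict  # method -> MREstimate
    pleiotropy: object  # PleiotropyResult
    heterogeneity: dict  # method -> HeterogeneityResult
    pleiotropy_check: str
    leave_one_out: list
    loo_robust: bool
    presso: object | None
    harmonize_report: object
    snp_ids: list[str]
    instruments: list = field(default_factory=list)


def analyze_pair(
    exp_set: SumStatSet,
    out_set: SumStatSet,
    ld: LDMatrix | None = None,
    cfg: PipelineConfig | None = None,
    select: bool = True,
) -> PairResult:
    """Run the full two-sample MR battery for one exposure-outcome pair."""
    cfg = cfg or PipelineConfig()
    if select:
        exp_sel = select_instruments(
            exp_set, ld, cfg.p_instrument, cfg.clump_r2, cfg.clump_kb, cfg.f_min
        )
    else:
        exp_sel = exp_set
    hs, report = harmonize_sets(exp_sel, out_set, policy=cfg.palindrome_policy)
    if len(hs) == 0:
        raise ValueError(
            f"no harmonized instruments for {exp_set.trait_label} -> {out_set.trait_label}"
        )
    estimates: dict = {}
    het: dict = {}
    pleio = None
    check = "not_run"
    loo: list = []
    robust = False
    presso = None
    if len(hs) == 1:
        estimates["wald"] = wald_ratio(hs[0])
    else:
        het["ivw"] = cochran_q(hs, "ivw")
        estimates["ivw"] = ivw(hs, effects_model="auto", het_alpha=cfg.alpha)
        if len(hs) >= 3:
            est_egger, pleio = mr_egger(hs)
            estimates["egger"] = est_egger
            het["egger"] = cochran_q(hs, "egger")
            check = egger_pleiotropy_check(pleio, cfg.egger_intercept_bound, cfg.alpha)
            estimates["weighted_median"] = weighted_median(hs, n_boot=cfg.n_boot, seed=cfg.seed)
            loo, robust = leave_one_out(hs, effects_model="auto")
        if len(hs) >= 4:
            presso = mr_presso(hs, n_sim=cfg.presso_n_sim, seed=cfg.seed, outlier_alpha=cfg.alpha)
    if out_set.trait_type == "binary":
        estimates = {k: to_odds_ratio(v) for k, v in estimates.items()}
    return PairResult(
        exposure=exp_set.trait_label,
        outcome=out_set.trait_label,
        nsnp=len(hs),
        estimates=estimates,
        pleiotropy=pleio,
        heterogeneity=het,
        pleiotropy_check=check,
        leave_one_out=loo,
        loo_robust=robust,
        presso=presso,
        harmonize_report=report,
        snp_ids=[h.snp_id for h in hs],
        instruments=list(hs),
    )


_METHOD_NAMES = {
    "ivw": "Inverse variance weighted",
    "egger": "MR-Egger",
    "weighted_median": "Weighted median",
    "wald": "Wald ratio",
}


def pair_result_rows(res: PairResult) -> list[dict]:
    """Flatten a PairResult into report rows (Table-1-style schema)."""
    rows = []
    for key, est in res.estimates.items():
        het = res.heterogeneity.get(key)
        row = {
            "exposure": res.exposure,
            "outcome": res.outcome,
            "method": _METHOD_NAMES.get(key, key),
            "nsnp": est.nsnp,
            "beta": est.beta,
            "se": est.se,
            "pval": est.pval,
            "effects_model": est.effects_model,
            "het_q_pval": None if het is None else het.pval,
            "egger_intercept": None,
            "egger_intercept_pval": None,
        }
        if est.or_scale is not None:
            orv, lo, hi = est.or_scale
            row["or_ci"] = f"{orv:.2f} ({lo:.2f} {hi:.2f})"
        if key == "egger" and res.pleiotropy is not None:
            row["egger_intercept"] = res.pleiotropy.intercept
            row["egger_intercept_pval"] = res.pleiotropy.pval
        rows.append(row)
    return rows


def _load_traits(sources: list[TraitSource]) -> list[SumStatSet]:
    out = []
    for src in sources:
        sset, meta = read_sumstats(
            src.path, dialect=src.dialect, trait_label=src.label, trait_type=src.trait_type
        )
        logger.info("loaded %s: %d records (%d dropped)", src.label, meta["n_kept"], meta["n_dropped"])
        out.append(sset)
    return out


def _provenance(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["package_version"] = __version__
    return d


def run_two_sample(cfg: PipelineConfig, write: bool = True) -> dict:
    """Two-sample MR for every exposure x outcome pair in the config.

    A pair whose analysis fails is logged and skipped; other pairs continue.
    Returns a report dict with the estimate table, diagnostics and provenance.
    """
    cfg.validate()
    exposures = _load_traits(cfg.exposures)
    outcomes = _load_traits(cfg.outcomes)
    ld = read_ld_matrix(cfg.ld_path) if cfg.ld_path else None
    rows, pair_results, failures = [], {}, []
    for exp_set in exposures:
        for out_set in outcomes:
            key = f"{exp_set.trait_label}__{out_set.trait_label}"
            try:
                res = analyze_pair(exp_set, out_set, ld, cfg)
            except (ValueError, KeyError) as exc:
                logger.error("pair %s failed: %s", key, exc)
                failures.append({"pair": key, "error": str(exc)})
                continue
            pair_results[key] = res
            rows.extend(pair_result_rows(res))
    report = {
        "estimates": pd.DataFrame(rows),
        "pairs": pair_results,
        "failures": failures,
        "provenance": _provenance(cfg),
    }
    if write:
        _write_two_sample(report, cfg)
    return report


def run_two_step(cfg: PipelineConfig, write: bool = True) -> dict:
    """Two-step mediation MR for every exposure x mediator x outcome triple.

    beta0 = IVW total effect (exposure -> outcome), beta1 = IVW exposure ->
    mediator, beta2 = the mediator's coefficient in the MVMR of the outcome
    on (exposure, mediator). The decision table then classifies mediation and
    the proportion mediated is beta1·beta2/beta0 for partial/full mediation.
    """
    cfg.validate()
    two_sample = run_two_sample(cfg, write=False)
    exposures = _load_traits(cfg.exposures)
    mediators = _load_traits(cfg.mediators)
    outcomes = _load_traits(cfg.outcomes)
    ld = read_ld_matrix(cfg.ld_path) if cfg.ld_path else None

    med_rows, mvmr_rows, mediation_rows, failures = [], [], [], []
    for exp_set in exposures:
        for med_set in mediators:
            try:
                step1 = analyze_pair(exp_set, med_set, ld, cfg)
            except (ValueError, KeyError) as exc:
                logger.error("step-1 %s -> %s failed: %s", exp_set.trait_label, med_set.trait_label, exc)
                failures.append({"pair": f"{exp_set.trait_label}__{med_set.trait_label}", "error": str(exc)})
                continue
            med_rows.extend(pair_result_rows(step1))
            b1_est = step1.estimates.get("ivw") or step1.estimates.get("wald")
            for out_set in outcomes:
                key = f"{exp_set.trait_label}__{out_set.trait_label}"
                pair0 = two_sample["pairs"].get(key)
                if pair0 is None:
                    continue
                b0_est = pair0.estimates.get("ivw") or pair0.estimates.get("wald")
                try:
                    mv_inp = build_mvmr_input(
                        [exp_set, med_set], out_set, ld,
                        cfg.p_instrument, cfg.clump_r2, cfg.clump_kb, cfg.palindrome_policy,
                    )
                    mv = mvmr_fit(mv_inp)
                except (ValueError, KeyError) as exc:
                    logger.error("MVMR %s failed: %s", key, exc)
                    failures.append({"pair": f"{key}__{med_set.trait_label}", "error": str(exc)})
                    continue
                b2, b2_se, b2_p = mv.for_exposure(med_set.trait_label)
                mvmr_rows.append({
                    "exposure": med_set.trait_label,
                    "adjusted_for": exp_set.trait_label,
                    "outcome": out_set.trait_label,
                    "beta": b2, "se": b2_se, "pval": b2_p, "nsnp": mv.nsnp,
                })
                m_inp = MediationInput(
                    beta0=EffectWithP(b0_est.beta, b0_est.se, b0_est.pval),
                    beta1=EffectWithP(b1_est.beta, b1_est.se, b1_est.pval),
                    beta2=EffectWithP(b2, b2_se, b2_p),
                    alpha=cfg.alpha,
                )
                m_res = classify_mediation(m_inp)
                mediation_rows.append({
                    "exposure": exp_set.trait_label,
                    "mediator": med_set.trait_label,
                    "outcome": out_set.trait_label,
                    "beta0": b0_est.beta, "p0": b0_est.pval,
                    "beta1": b1_est.beta, "p1": b1_est.pval,
                    "beta2": b2, "p2": b2_p,
                    "classification": m_res.classification,
                    "indirect_effect": m_res.indirect_effect,
                    "indirect_se": m_res.indirect_se,
                    "proportion_mediated_pct": (
                        None if m_res.proportion_mediated is None
                        else round(100.0 * m_res.proportion_mediated, 2)
                    ),
                })
    report = {
        "total_effects": two_sample["estimates"],
        "pairs": two_sample["pairs"],
        "exposure_mediator": pd.DataFrame(med_rows),
        "mediator_outcome_mvmr": pd.DataFrame(mvmr_rows),
        "mediation": pd.DataFrame(mediation_rows),
        "failures": two_sample["failures"] + failures,
        "provenance": _provenance(cfg),
    }
    if write:
        _write_two_step(report, cfg)
    return report


def power_table(n: float, k: float, r2_xz: float, alpha: float = 0.05,
                odds_ratios=None) -> pd.DataFrame:
    """Power across a grid of ORs (the supplementary power-table analogue)."""
    if odds_ratios is None:
        odds_ratios = np.round(np.arange(1.01, 1.31, 0.01), 2)
    rows = power_grid(n, k, r2_xz, odds_ratios, alpha)
    return pd.DataFrame(rows, columns=["odds_ratio", "power"])


# ---------------------------------------------------------------- reporting

def _df_to_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_diagnostics(pairs: dict, outdir: Path, make_plots: bool) -> None:
    for key, res in pairs.items():
        if res.leave_one_out:
            loo_df = pd.DataFrame(
                {
                    "snp": [s for s, _ in res.leave_one_out],
                    "beta": [e.beta for _, e in res.leave_one_out],
                    "ci_low": [e.ci_low for _, e in res.leave_one_out],
                    "ci_high": [e.ci_high for _, e in res.leave_one_out],
                }
            )
            _df_to_tsv(loo_df, outdir / f"{key}_leave_one_out.tsv")
        diag = {
            "pair": key,
            "nsnp": res.nsnp,
            "snp_ids": res.snp_ids,
            "harmonization": dataclasses.asdict(res.harmonize_report),
            "pleiotropy_check": res.pleiotropy_check,
            "loo_robust": bool(res.loo_robust),
            "heterogeneity": {
                k: dataclasses.asdict(v) for k, v in res.heterogeneity.items()
            },
        }
        if res.presso is not None:
            diag["mr_presso"] = {
                "global_rss": res.presso.global_rss,
                "global_pval": res.presso.global_pval,
                "outlier_indices": res.presso.outlier_indices,
                "distortion_pval": res.presso.distortion_pval,
            }
        with open(outdir / f"{key}_diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=1, sort_keys=True)
        if make_plots:
            _plot_pair(res, outdir, key)


def _write_two_sample(report: dict, cfg: PipelineConfig) -> None:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _df_to_tsv(report["estimates"], outdir / "two_sample_estimates.tsv")
    _write_diagnostics(report["pairs"], outdir, cfg.make_plots)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(report["provenance"], fh, indent=1, sort_keys=True)


def _write_two_step(report: dict, cfg: PipelineConfig) -> None:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _df_to_tsv(report["total_effects"], outdir / "two_sample_estimates.tsv")
    _df_to_tsv(report["exposure_mediator"], outdir / "exposure_mediator_estimates.tsv")
    _df_to_tsv(report["mediator_outcome_mvmr"], outdir / "mediator_outcome_mvmr.tsv")
    _df_to_tsv(report["mediation"], outdir / "mediation_summary.tsv")
    _write_diagnostics(report["pairs"], outdir, cfg.make_plots)
    with open(outdir / "mediation_summary.json", "w") as fh:
        json.dump(report["mediation"].to_dict(orient="records"), fh, indent=1)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(report["provenance"], fh, indent=1, sort_keys=True)


def _plot_pair(res: PairResult, outdir: Path, key: str) -> None:
    """Plain scatter and leave-one-out forest plots (functional, unstyled)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if res.instruments:
        fig, ax = plt.subplots(figsize=(4, 4))
        bx = [h.beta_exp for h in res.instruments]
        by = [h.beta_out for h in res.instruments]
        ax.errorbar(
            bx, by,
            xerr=[h.se_exp for h in res.instruments],
            yerr=[h.se_out for h in res.instruments],
            fmt="o", ms=3, lw=0.5,
        )
        ivw_est = res.estimates.get("ivw")
        if ivw_est is not None:
            xs = np.linspace(min(bx + [0]), max(bx + [0]), 2)
            ax.plot(xs, ivw_est.beta * xs, "-", label="IVW")
            ax.legend(fontsize=6)
        ax.set_xlabel(f"SNP effect on {res.exposure}")
        ax.set_ylabel(f"SNP effect on {res.outcome}")
        fig.tight_layout()
        fig.savefig(outdir / f"{key}_scatter.png", dpi=100)
        plt.close(fig)

    if res.leave_one_out:
        fig, ax = plt.subplots(figsize=(5, max(2, 0.18 * len(res.leave_one_out))))
        ys = np.arange(len(res.leave_one_out))
        betas = [e.beta for _, e in res.leave_one_out]
        lows = [e.ci_low for _, e in res.leave_one_out]
        highs = [e.ci_high for _, e in res.leave_one_out]
        ax.hlines(ys, lows, highs)
        ax.plot(betas, ys, "o", ms=3)
        ax.axvline(0, ls=":")
        ax.set_yticks(ys)
        ax.set_yticklabels([s for s, _ in res.leave_one_out], fontsize=5)
        ax.set_xlabel("leave-one-out IVW beta")
        fig.tight_layout()
        fig.savefig(outdir / f"{key}_leave_one_out.png", dpi=100)
        plt.close(fig)


__all__ = [
    "PairResult",
    "PipelineConfig",
    "TraitSource",
    "analyze_pair",
    "pair_result_rows",
    "power_table",
    "run_two_sample",
    "run_two_step",
]
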