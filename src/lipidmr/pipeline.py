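"""End-to-end study orchestration.

Runs the drug-target MR arm (instrument selection, harmonization, the full
estimator battery, Bonferroni correction over drug classes), the binary
positive-control arm (estimates exponentiated to odds ratios), and the
pharmacovigilance arm (per-drug disproportionality signals), from a single
YAML-or-dataclass configuration. Re-running with identical configuration and
seeds reproduces byte-identical output files.
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

from . import estimators as est
from . import pharmacovigilance as pv
from .instruments import (
    LDMatrix, NoInstrumentsError, SelectionReport, SelectionThresholds,
    read_targets, select_instruments,
)
from .summary_stats import (
    ConfigurationError, harmonize, read_summary_stats, retained,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Paths, thresholds and estimator settings for one study run."""

    exposure_paths: dict[str, str]          # trait -> summary-stats path
    outcome_path: str
    targets_path: str
    ld_path: str
    positive_control_path: str | None = None
    reports_path: str | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    palindromic_eaf_limit: float = 0.42
    n_boot: int = 1000
    n_presso_sim: int = 1000
    seed: int = 0
    alpha: float = 0.05
    n_tests_for_bonferroni: int | None = None  # None -> number of drug classes

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        th = raw.pop("thresholds", {})
        cfg = cls(**raw)
        cfg.thresholds = SelectionThresholds(**th)
        return cfg


@dataclass
class DrugClassResult:
    """Everything computed for one drug class / target gene."""

    drug_class: str
    gene: str
    results: dict[str, est.MRResult | None] = field(default_factory=dict)
    selection: SelectionReport | None = None
    n_harmonized: int = 0
    n_dropped_harmonization: int = 0
    leave_one_out: pd.DataFrame | None = None
    loo_all_same_side: bool | None = None
    presso: est.PressoReport | None = None
    significant_after_bonferroni: bool = False
    direction_label: str = "null"
    error: str | None = None


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests; significance calls
    use strict < against it."""
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha outside (0, 1)")
    return alpha / n_tests


def _estimator_battery(insts: pd.DataFrame, n_boot: int, n_presso: int,
                       seed: int) -> tuple[dict, pd.DataFrame | None, bool | None,
                                           est.PressoReport | None]:
    """Run every estimator the instrument count permits."""
    results: dict[str, est.MRResult | None] = {}
    n = len(insts)

    results["ivw_fixed"] = est.ivw(insts, random_effects=False)
    results["ivw_random"] = est.ivw(insts, random_effects=True) if n >= 2 else None

    eg = est.egger(insts)
    results["egger"], results["egger_intercept"] = eg if eg else (None, None)
    results["weighted_median"] = est.weighted_median(insts, n_boot=n_boot, seed=seed)
    results["weighted_mode"] = est.weighted_mode(insts, n_boot=n_boot, seed=seed + 1)

    presso_report = None
    pr = est.mr_presso(insts, n_sim=n_presso, seed=seed + 2)
    if pr is not None:
        presso_report, corrected = pr
        results["presso_outlier_corrected"] = corrected
    else:
        results["presso_outlier_corrected"] = None

    loo_table, same_side = (None, None)
    if n >= 2:
        loo_table, same_side = est.leave_one_out(insts)
    return results, loo_table, same_side, presso_report


def run_mr_arm(config: StudyConfig, outcome_path: str | None = None) -> list[DrugClassResult]:
    """Drug-target MR for every configured target against the (continuous)
    outcome. Per-target failures are logged and carried as failed entries."""
    targets = read_targets(config.targets_path)
    ld = LDMatrix.from_tsv(config.ld_path)
    exposures = {
        trait: read_summary_stats(path, config.column_map)
        for trait, path in config.exposure_paths.items()
    }
    outcome = read_summary_stats(outcome_path or config.outcome_path, config.column_map)
    n_tests = config.n_tests_for_bonferroni or len(targets)
    p_threshold = bonferroni_threshold(config.alpha, n_tests)

    out: list[DrugClassResult] = []
    for k, target in enumerate(targets):
        entry = DrugClassResult(drug_class=target.drug_class, gene=target.gene_symbol)
        seed = config.seed + 1000 * k
        try:
            trait = target.trait or next(iter(exposures))
            if trait not in exposures:
                raise ConfigurationError(
                    f"{target.gene_symbol}: no exposure file for trait {trait!r}"
                )
            selected, report = select_instruments(
                exposures[trait], target, ld, config.thresholds
            )
            entry.selection = report
            harmonized = harmonize(
                selected, outcome, palindromic_eaf_limit=config.palindromic_eaf_limit
            )
            insts = retained(harmonized)
            entry.n_harmonized = len(insts)
            entry.n_dropped_harmonization = len(harmonized) - len(insts)
            if insts.empty:
                raise NoInstrumentsError(target.gene_symbol, "harmonization")

            (entry.results, entry.leave_one_out,
             entry.loo_all_same_side, entry.presso) = _estimator_battery(
                insts, config.n_boot, config.n_presso_sim, seed
            )
            ivw_res = entry.results["ivw_fixed"]
            entry.significant_after_bonferroni = ivw_res.pvalue < p_threshold
            if entry.significant_after_bonferroni:
                entry.direction_label = "adverse" if ivw_res.beta < 0 else "protective"
        except (NoInstrumentsError, ConfigurationError, est.EstimationError,
                ValueError) as exc:
            logger.warning("target %s failed: %s", target.gene_symbol, exc)
            entry.error = str(exc)
        out.append(entry)
    return out


def run_positive_control(config: StudyConfig) -> tuple[list[DrugClassResult], bool]:
    """Same battery against the binary positive-control outcome; betas are on
    the log-odds scale and reported as odds ratios. The validity verdict is
    True when every target's IVW OR confidence interval lies below 1."""
    if not config.positive_control_path:
        raise ConfigurationError("no positive-control outcome configured")
    results = run_mr_arm(config, outcome_path=config.positive_control_path)
    verdict = True
    for entry in results:
        res = entry.results.get("ivw_fixed") if entry.results else None
        if res is None or not (res.ci_high < 0):  # log-OR CI entirely below 0
            verdict = False
    return results, verdict


def odds_ratio_table(results: list[DrugClassResult]) -> pd.DataFrame:
    """Per-target IVW estimates exponentiated to odds ratios with
    exp(beta ± 1.959964·se) confidence bounds."""
    rows = []
    for entry in results:
        res = entry.results.get("ivw_fixed") if entry.results else None
        if res is None:
            continue
        rows.append({
            "drug_class": entry.drug_class, "gene": entry.gene,
            "odds_ratio": float(np.exp(res.beta)),
            "or_ci_low": float(np.exp(res.ci_low)),
            "or_ci_high": float(np.exp(res.ci_high)),
            "pvalue": res.pvalue, "n_snp": res.n_snp,
        })
    return pd.DataFrame(rows)


def run_faers_arm(config: StudyConfig) -> tuple[pd.DataFrame, tuple[int, int, float]]:
    """Disproportionality signals for every drug in the report table, sorted
    by ROR descending, plus the overall event-rate summary."""
    if not config.reports_path:
        raise ConfigurationError("no report table configured")
    reports = pd.read_csv(config.reports_path, sep="\t")
    table = pv.signal_table(reports)
    summary = pv.event_rate_summary(reports)
    return table, summary


def mr_results_table(results: list[DrugClassResult]) -> pd.DataFrame:
    """Stack every target's per-method estimates into the standard long table."""
    frames = [
        est.results_table(entry.results, entry.drug_class, entry.gene)
        for entry in results if entry.results
    ]
    if not frames:
        return pd.DataFrame(
            columns=["drug_class", "gene", "method", "beta", "ci_low",
                     "ci_high", "pvalue", "q_pvalue", "n_snp"]
        )
    return pd.concat(frames, ignore_index=True)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return [_json_safe(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_study(config: StudyConfig, outdir) -> dict[str, Path]:
    """Run every configured arm and write the result files.

    Outputs: ``mr_results.tsv`` (long per-method table),
    ``leave_one_out.tsv``, ``diagnostics.json`` (selection counts, drop
    reasons, pleiotropy/heterogeneity diagnostics, seeds),
    ``positive_control.tsv`` and ``signals.tsv`` when configured.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    mr_results = run_mr_arm(config)
    table = mr_results_table(mr_results)
    paths["mr_results"] = outdir / "mr_results.tsv"
    table.to_csv(paths["mr_results"], sep="\t", index=False, float_format="%.10g")

    loo_frames = []
    for entry in mr_results:
        if entry.leave_one_out is not None:
            loo = entry.leave_one_out.copy()
            loo.insert(0, "gene", entry.gene)
            loo_frames.append(loo)
    paths["leave_one_out"] = outdir / "leave_one_out.tsv"
    (pd.concat(loo_frames, ignore_index=True) if loo_frames else pd.DataFrame()).to_csv(
        paths["leave_one_out"], sep="\t", index=False, float_format="%.10g"
    )

    diagnostics = {
        "seed": config.seed,
        "alpha": config.alpha,
        "bonferroni_threshold": bonferroni_threshold(
            config.alpha, config.n_tests_for_bonferroni or len(mr_results)
        ),
        "targets": [],
    }
    for entry in mr_results:
        diagnostics["targets"].append(_json_safe({
            "drug_class": entry.drug_class,
            "gene": entry.gene,
            "error": entry.error,
            "selection_counts": entry.selection.counts if entry.selection else None,
            "n_harmonized": entry.n_harmonized,
            "n_dropped_harmonization": entry.n_dropped_harmonization,
            "significant_after_bonferroni": entry.significant_after_bonferroni,
            "direction": entry.direction_label,
            "loo_all_same_side": entry.loo_all_same_side,
            "presso_global_p": entry.presso.global_p if entry.presso else None,
            "presso_outliers": sorted(entry.presso.outliers_flagged) if entry.presso else None,
        }))

    if config.positive_control_path:
        control_results, verdict = run_positive_control(config)
        paths["positive_control"] = outdir / "positive_control.tsv"
        odds_ratio_table(control_results).to_csv(
            paths["positive_control"], sep="\t", index=False, float_format="%.10g"
        )
        diagnostics["positive_control_valid"] = verdict

    if config.reports_path:
        signals, (n_total, n_event, percent) = run_faers_arm(config)
        paths["signals"] = outdir / "signals.tsv"
        signals.to_csv(paths["signals"], sep="\t", index=False, float_format="%.10g")
        diagnostics["event_rate"] = {
            "n_total": n_total, "n_event": n_event, "percent": percent,
        }

    paths["diagnostics"] = outdir / "diagnostics.json"
    paths["diagnostics"].write_text(json.dumps(diagnostics, indent=2, sort_keys=True))
    return paths
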