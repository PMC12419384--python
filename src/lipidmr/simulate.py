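"""Ground-truthed synthetic inputs for the whole pipeline.

Two generators:

* :func:`simulate_two_sample` emits exposure and outcome GWAS summary
  statistics for one drug-target locus under the structural model

      beta_out_j = theta · beta_exp_true_j + alpha_j + noise,

  with known causal effect ``theta``, optional balanced or directional
  pleiotropy ``alpha_j``, optional planted outliers, block LD, and
  measurement noise at GWAS-realistic standard errors. The matching LD table
  and gene-target record are emitted alongside so instrument selection,
  harmonization and every estimator can run end to end against a known
  truth.

* :func:`simulate_reports` emits a spontaneous-report table whose expected
  drug-by-event 2×2 has a specified reporting odds ratio for one target
  drug against a background event rate.

Defaults are desk-scale analogues of the real data sources: 10 SNPs per
locus, exposure effects U(0.06, 0.15) SD per allele, per-SNP standard errors
0.005 (roughly N ≈ 2×10⁵ standardized-trait GWAS), 100,000 reports at a 2%
background cognitive-event rate. Identical truth + seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .instruments import GeneTarget, LDMatrix, write_targets
from .summary_stats import ConfigurationError, STANDARD_COLUMNS

_NON_PALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class SyntheticTruth:
    """Ground-truth parameters for one synthetic locus / report table."""

    theta: float = 0.0                      # causal effect (SD outcome per SD exposure)
    n_snp: int = 10
    pleiotropy_mode: str = "none"           # none | balanced | directional
    pleiotropy_sd: float = 0.0
    outlier_ids: frozenset = frozenset()    # SNP indices (int) or ids (str)
    outlier_shift: float = 0.0              # in units of se_out
    exposure_effect_range: tuple[float, float] = (0.06, 0.15)
    se_exp_scale: float = 0.005
    se_out_scale: float = 0.005
    ld_blocks: tuple = ()                   # ((block_size, within_block_r2), ...)
    allow_palindromic: bool = False
    #: suppress the measurement-noise draws (emitted SEs stay at their
    #: scales): every per-SNP ratio is then exactly theta (+ pleiotropy)
    noise_free: bool = False
    seed: int = 0
    #: selects an independent outcome-noise stream; two truths differing only
    #: here share the structural layer (positions, alleles, true exposure
    #: effects, exposure noise) but draw independent outcome noise — how a
    #: second outcome GWAS (e.g. a binary positive control) is emitted.
    outcome_noise_stream: int = 0
    # report-table parameters
    true_or: float = 1.0
    n_reports: int = 100_000
    background_event_rate: float = 0.02
    n_null_drugs: int = 4
    target_drug: str = "drug_signal"

    def __post_init__(self):
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"pleiotropy_mode: {self.pleiotropy_mode!r}")
        if self.n_snp < 1:
            raise ConfigurationError("n_snp must be >= 1")
        if self.se_exp_scale <= 0 or self.se_out_scale <= 0:
            raise ConfigurationError("se scales must be > 0")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")
        lo, hi = self.exposure_effect_range
        if not lo <= hi:
            raise ConfigurationError("exposure_effect_range: low > high")
        if sum(size for size, _ in self.ld_blocks) > self.n_snp:
            raise ConfigurationError("ld_blocks exceed n_snp")
        if self.true_or <= 0:
            raise ConfigurationError("true_or must be > 0")
        if not 0.0 < self.background_event_rate < 1.0:
            raise ConfigurationError("background_event_rate outside (0, 1)")


@dataclass
class TwoSampleDataset:
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: LDMatrix
    target: GeneTarget
    truth: SyntheticTruth
    truth_echo: dict = field(default_factory=dict)


def _two_sided_p(beta, se):
    from scipy import stats

    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def simulate_two_sample(
    truth: SyntheticTruth,
    snp_prefix: str = "rs",
    target: GeneTarget | None = None,
) -> TwoSampleDataset:
    """Generate one locus's exposure and outcome summary statistics.

    Exposure and outcome measurement noise come from independent sub-streams
    of ``truth.seed``, honouring the two-sample design. About a third of
    outcome rows are emitted with the allele order swapped (beta negated,
    eaf mirrored) so harmonization is exercised on every run.
    """
    ss = np.random.SeedSequence(truth.seed)
    children = ss.spawn(3 + truth.outcome_noise_stream)
    rng_struct = np.random.default_rng(children[0])
    rng_exp = np.random.default_rng(children[1])
    rng_out = np.random.default_rng(children[2 + truth.outcome_noise_stream])
    n = truth.n_snp

    if target is None:
        target = GeneTarget(
            gene_symbol="SYN_GENE", drug_class="synthetic", chrom="1",
            start=1_000_000, end=1_050_000, window_bp=100_000, trait="LDL-C",
        )
    pos = np.sort(
        rng_struct.choice(np.arange(target.start, target.end + 1), size=n, replace=False)
    )
    snps = [f"{snp_prefix}{i + 1:04d}" for i in range(n)]

    pairs = _NON_PALINDROMIC_PAIRS + (_PALINDROMIC_PAIRS if truth.allow_palindromic else ())
    allele_idx = rng_struct.integers(0, len(pairs), size=n)
    ea = np.array([pairs[k][0] for k in allele_idx])
    oa = np.array([pairs[k][1] for k in allele_idx])
    eaf = rng_struct.uniform(0.1, 0.9, size=n)

    lo, hi = truth.exposure_effect_range
    be_true = rng_struct.uniform(lo, hi, size=n)
    se_exp = np.full(n, truth.se_exp_scale)
    se_out = np.full(n, truth.se_out_scale)

    if truth.pleiotropy_mode == "none":
        alpha = np.zeros(n)
    elif truth.pleiotropy_mode == "balanced":
        alpha = rng_struct.normal(0.0, truth.pleiotropy_sd, size=n)
    else:  # directional
        alpha = np.abs(rng_struct.normal(0.0, truth.pleiotropy_sd, size=n))

    outlier_idx = sorted(
        i if isinstance(i, (int, np.integer)) else snps.index(i)
        for i in truth.outlier_ids
    )

    noise_exp = 0.0 if truth.noise_free else rng_exp.normal(0.0, se_exp)
    noise_out = 0.0 if truth.noise_free else rng_out.normal(0.0, se_out)
    beta_exp = be_true + noise_exp
    beta_out = truth.theta * be_true + alpha + noise_out
    for j in outlier_idx:
        beta_out[j] += truth.outlier_shift * se_out[j]

    exposure = pd.DataFrame({
        "snp": snps, "chrom": target.chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": np.round(eaf, 4),
        "beta": beta_exp, "se": se_exp, "pvalue": _two_sided_p(beta_exp, se_exp),
        "n": 188_000,
    })[list(STANDARD_COLUMNS)]

    swap = rng_struct.random(n) < 0.3
    outcome = pd.DataFrame({
        "snp": snps, "chrom": target.chrom, "pos": pos,
        "effect_allele": np.where(swap, oa, ea),
        "other_allele": np.where(swap, ea, oa),
        "eaf": np.round(np.where(swap, 1.0 - eaf, eaf), 4),
        "beta": np.where(swap, -beta_out, beta_out),
        "se": se_out, "pvalue": _two_sided_p(beta_out, se_out),
        "n": 257_841,
    })[list(STANDARD_COLUMNS)]

    ld = LDMatrix()
    start = 0
    for size, r2 in truth.ld_blocks:
        block = snps[start:start + size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                ld.set(block[i], block[j], r2)
        start += size

    echo = {
        "theta": truth.theta,
        "pleiotropy_mode": truth.pleiotropy_mode,
        "outlier_snps": [snps[j] for j in outlier_idx],
        "seed": truth.seed,
        "gene": target.gene_symbol,
    }
    return TwoSampleDataset(exposure, outcome, ld, target, truth, echo)


def simulate_reports(truth: SyntheticTruth) -> pd.DataFrame:
    """Generate a spontaneous-report table (report_id, drug, event_flag).

    Drugs are the target plus ``n_null_drugs`` null drugs with uniform
    report shares. Null drugs carry the background event rate; the target
    drug's event probability solves the odds relation
    odds_target = true_or × odds_background, so the expected 2×2 against all
    other drugs has reporting odds ratio exactly ``true_or``.
    """
    p0 = truth.background_event_rate
    odds_target = truth.true_or * p0 / (1.0 - p0)
    p1 = odds_target / (1.0 + odds_target)
    if not 0.0 < p1 < 1.0:
        raise ConfigurationError(
            f"target event probability {p1} outside (0, 1) for true_or={truth.true_or}"
        )
    drugs = [truth.target_drug] + [
        f"drug_null_{k + 1}" for k in range(truth.n_null_drugs)
    ]
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(1)[0])
    drug_idx = rng.integers(0, len(drugs), size=truth.n_reports)
    p_event = np.where(drug_idx == 0, p1, p0)
    events = rng.random(truth.n_reports) < p_event
    return pd.DataFrame({
        "report_id": [f"R{i + 1:08d}" for i in range(truth.n_reports)],
        "drug": np.array(drugs, dtype=object)[drug_idx],
        "event_flag": events.astype(int),
    })


def write_dataset(dataset: TwoSampleDataset, outdir) -> dict[str, Path]:
    """Write one locus dataset in the file dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "outcome": outdir / "outcome.tsv",
        "ld": outdir / "ld.tsv",
        "targets": outdir / "targets.tsv",
        "truth": outdir / "truth.json",
    }
    dataset.exposure.to_csv(paths["exposure"], sep="\t", index=False)
    dataset.outcome.to_csv(paths["outcome"], sep="\t", index=False)
    dataset.ld.to_tsv(paths["ld"])
    write_targets([dataset.target], paths["targets"])
    echo = dict(dataset.truth_echo)
    echo["truth"] = {
        k: (sorted(v) if isinstance(v, frozenset) else list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(dataset.truth).items()
    }
    paths["truth"].write_text(json.dumps(echo, indent=2, sort_keys=True))
    return paths


# --- multi-target study -----------------------------------------------------

#: the six synthetic drug-class analogues of a lipid-lowering drug study:
#: three LDL-C-instrumented targets, three TG-instrumented targets.
STUDY_TARGETS = (
    ("statins", "SYN_HMGCR", "LDL-C"),
    ("ezetimibe", "SYN_NPC1L1", "LDL-C"),
    ("PCSK9 inhibitors", "SYN_PCSK9", "LDL-C"),
    ("fibrates", "SYN_PPARG", "TG"),
    ("ANGPTL3 inhibitors", "SYN_ANGPTL3", "TG"),
    ("LPL enhancers", "SYN_LPL", "TG"),
)

#: default per-gene causal effects on the cognitive outcome: the two adverse
#: LDL-C targets carry nonzero effects, the rest are null.
DEFAULT_THETAS = {
    "SYN_HMGCR": -0.087,
    "SYN_NPC1L1": -0.319,
    "SYN_PCSK9": 0.0,
    "SYN_PPARG": 0.0,
    "SYN_ANGPTL3": 0.0,
    "SYN_LPL": 0.0,
}

#: default per-gene log odds ratio on the binary positive-control outcome
#: (coronary-disease analogue): uniformly protective, OR ~ 0.7 per SD.
DEFAULT_CONTROL_LOG_OR = float(np.log(0.7))


def simulate_study(
    outdir,
    seed: int = 0,
    theta_by_gene: dict[str, float] | None = None,
    control_log_or: float = DEFAULT_CONTROL_LOG_OR,
    n_snp_per_target: int = 10,
    se_out_control: float = 0.015,
    reports_truth: SyntheticTruth | None = None,
    **truth_kwargs,
) -> dict[str, Path]:
    """Emit a full six-target study: per-trait exposure files, a shared
    continuous outcome, a binary positive-control outcome, LD and target
    tables, a report table, and a truth JSON. Returns the path map.

    Each target lives on its own chromosome; the per-trait exposure file
    carries only that trait's targets' SNPs, the outcome files carry all.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thetas = dict(DEFAULT_THETAS)
    thetas.update(theta_by_gene or {})

    ss = np.random.SeedSequence(seed)
    target_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(STUDY_TARGETS) + 1)]

    exposures: dict[str, list[pd.DataFrame]] = {"LDL-C": [], "TG": []}
    outcome_parts, control_parts, targets, truth_echoes = [], [], [], []
    ld = LDMatrix()

    for i, (drug_class, gene, trait) in enumerate(STUDY_TARGETS):
        target = GeneTarget(
            gene_symbol=gene, drug_class=drug_class, chrom=str(i + 1),
            start=1_000_000, end=1_050_000, window_bp=100_000, trait=trait,
        )
        truth = SyntheticTruth(
            theta=thetas[gene], n_snp=n_snp_per_target,
            seed=target_seeds[i], **truth_kwargs,
        )
        ds = simulate_two_sample(truth, snp_prefix=f"rs{i + 1}x", target=target)
        exposures[trait].append(ds.exposure)
        outcome_parts.append(ds.outcome)
        targets.append(target)
        truth_echoes.append(ds.truth_echo)
        for (si, sj), v in ds.ld._r2.items():
            ld.set(si, sj, v)

        # positive-control outcome: same instruments, binary-trait effects
        control_truth = dataclasses.replace(
            truth, theta=control_log_or, se_out_scale=se_out_control,
            outcome_noise_stream=1,
        )
        ds_control = simulate_two_sample(control_truth, snp_prefix=f"rs{i + 1}x", target=target)
        control_parts.append(ds_control.outcome)

    reports = simulate_reports(
        reports_truth
        or SyntheticTruth(seed=target_seeds[-1], true_or=3.0)
    )

    paths = {
        "exposure_ldl": outdir / "exposure_ldl.tsv",
        "exposure_tg": outdir / "exposure_tg.tsv",
        "outcome": outdir / "outcome.tsv",
        "outcome_control": outdir / "outcome_control.tsv",
        "ld": outdir / "ld.tsv",
        "targets": outdir / "targets.tsv",
        "reports": outdir / "reports.tsv",
        "truth": outdir / "truth.json",
    }
    pd.concat(exposures["LDL-C"]).to_csv(paths["exposure_ldl"], sep="\t", index=False)
    pd.concat(exposures["TG"]).to_csv(paths["exposure_tg"], sep="\t", index=False)
    pd.concat(outcome_parts).to_csv(paths["outcome"], sep="\t", index=False)
    pd.concat(control_parts).to_csv(paths["outcome_control"], sep="\t", index=False)
    ld.to_tsv(paths["ld"])
    write_targets(targets, paths["targets"])
    reports.to_csv(paths["reports"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps({
        "seed": seed,
        "theta_by_gene": thetas,
        "control_log_or": control_log_or,
        "per_target": truth_echoes,
    }, indent=2, sort_keys=True))
    return paths
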