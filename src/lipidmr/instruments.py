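"""Drug-target instrument construction.

A drug's pharmacological action is proxied by variants in or near its target
gene that associate with the drug's biomarker (LDL-C or TG). Selection runs,
in order: cis-window filter, genome-wide significance filter, per-SNP
instrument-strength (F) filter, then greedy LD clumping, so the clump's
accepted set is the final analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .summary_stats import ConfigurationError

SELECTION_STAGES = ("input", "cis", "significance", "f_stat", "ld_clump")


class NoInstrumentsError(ValueError):
    """A selection stage emptied the candidate set."""

    def __init__(self, gene: str, stage: str):
        self.gene = gene
        self.stage = stage
        super().__init__(f"no valid instruments for target {gene}: "
                         f"{stage} stage left zero SNPs")


@dataclass
class GeneTarget:
    """A drug-target gene region (1-based, inclusive coordinates)."""

    gene_symbol: str
    drug_class: str
    chrom: str
    start: int
    end: int
    window_bp: int = 100_000
    trait: str | None = None  # exposure biomarker this target is instrumented on

    def __post_init__(self):
        self.chrom = str(self.chrom)
        if self.start > self.end:
            raise ConfigurationError(f"{self.gene_symbol}: start > end")
        if self.window_bp < 0:
            raise ConfigurationError(f"{self.gene_symbol}: negative window_bp")


def read_targets(path, window_bp: int = 100_000) -> list[GeneTarget]:
    """Read a BED-like TSV of targets: chrom, start, end, gene_symbol,
    drug_class and optionally trait. Coordinates are 1-based inclusive
    (declared in the header comment the writer emits)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    targets = []
    for rec in df.itertuples(index=False):
        targets.append(
            GeneTarget(
                gene_symbol=rec.gene_symbol,
                drug_class=rec.drug_class,
                chrom=str(rec.chrom),
                start=int(rec.start),
                end=int(rec.end),
                window_bp=window_bp,
                trait=getattr(rec, "trait", None),
            )
        )
    return targets


def write_targets(targets: list[GeneTarget], path) -> None:
    with open(path, "w") as fh:
        fh.write("# 1-based inclusive coordinates\n")
        fh.write("chrom\tstart\tend\tgene_symbol\tdrug_class\ttrait\n")
        for t in targets:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene_symbol}\t"
                f"{t.drug_class}\t{t.trait or ''}\n"
            )


class LDMatrix:
    """Sparse symmetric pairwise r-squared; absent pairs mean r² = 0,
    the diagonal is 1."""

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        for (i, j), v in (pairs or {}).items():
            self.set(i, j, v)

    @staticmethod
    def _key(i: str, j: str) -> tuple[str, str]:
        return (i, j) if i <= j else (j, i)

    def set(self, i: str, j: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ConfigurationError(f"r2({i},{j}) = {r2} outside [0, 1]")
        if i != j:
            self._r2[self._key(i, j)] = float(r2)

    def r2(self, i: str, j: str) -> float:
        if i == j:
            return 1.0
        return self._r2.get(self._key(i, j), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"snp_i": str, "snp_j": str})
        m = cls()
        for rec in df.itertuples(index=False):
            m.set(rec.snp_i, rec.snp_j, float(rec.r2))
        return m

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("snp_i\tsnp_j\tr2\n")
            for (i, j), v in sorted(self._r2.items()):
                fh.write(f"{i}\t{j}\t{v:.6g}\n")


def cis_filter(records: pd.DataFrame, target: GeneTarget) -> pd.DataFrame:
    """Keep SNPs on the target's chromosome within the window-expanded
    region [start - window_bp, end + window_bp], both ends inclusive."""
    lo = target.start - target.window_bp
    hi = target.end + target.window_bp
    mask = (
        (records["chrom"].astype(str) == target.chrom)
        & (records["pos"] >= lo)
        & (records["pos"] <= hi)
    )
    return records.loc[mask].reset_index(drop=True)


def significance_filter(records: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Keep SNPs with pvalue strictly below the genome-wide threshold."""
    if not 0.0 < p_threshold < 1.0:
        raise ConfigurationError(f"p_threshold {p_threshold} outside (0, 1)")
    return records.loc[records["pvalue"] < p_threshold].reset_index(drop=True)


def f_statistic(beta, se):
    """Per-SNP approximate F statistic, the squared z-score (beta/se)²."""
    return np.square(np.asarray(beta, dtype=float) / np.asarray(se, dtype=float))


def f_statistic_from_r2(beta, eaf, n):
    """Alternative F via explained variance: R² = 2·eaf·(1-eaf)·beta²,
    F = R²(n-2)/(1-R²). Requires eaf and n; assumes a standardized trait."""
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    return r2 * (n - 2.0) / (1.0 - r2)


def f_filter(records: pd.DataFrame, f_threshold: float = 10.0) -> pd.DataFrame:
    """Keep SNPs with F strictly above the weak-instrument cutoff."""
    f = f_statistic(records["beta"], records["se"])
    return records.loc[f > f_threshold].reset_index(drop=True)


def ld_clump(records: pd.DataFrame, ld: LDMatrix, r2_threshold: float = 0.001) -> pd.DataFrame:
    """Greedy LD clumping.

    Candidates are ranked by ascending p-value (ties: ascending position,
    then SNP id); the best remaining SNP is accepted and every remaining SNP
    with r² > r2_threshold against any accepted SNP is discarded. The result
    is the accepted set in acceptance order, pairwise independent at the
    threshold and invariant to input row order.
    """
    if not 0.0 <= r2_threshold <= 1.0:
        raise ConfigurationError(f"r2_threshold {r2_threshold} outside [0, 1]")
    ranked = records.sort_values(
        ["pvalue", "pos", "snp"], kind="mergesort"
    ).reset_index(drop=True)
    accepted: list[int] = []
    accepted_ids: list[str] = []
    for idx, snp in enumerate(ranked["snp"]):
        if all(ld.r2(snp, kept) <= r2_threshold for kept in accepted_ids):
            accepted.append(idx)
            accepted_ids.append(snp)
    return ranked.loc[accepted].reset_index(drop=True)


@dataclass
class SelectionThresholds:
    """Instrument-selection thresholds (defaults: genome-wide significance,
    near-total LD independence, conventional weak-instrument cutoff,
    100 kb cis window)."""

    p: float = 5e-8
    r2: float = 0.001
    f: float = 10.0
    window_bp: int | None = None  # None -> use the target's own window


@dataclass
class SelectionReport:
    gene: str
    counts: dict[str, int] = field(default_factory=dict)


def select_instruments(
    exposure: pd.DataFrame,
    target: GeneTarget,
    ld: LDMatrix,
    thresholds: SelectionThresholds | None = None,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Full selection cascade for one target: cis -> significance -> F -> clump.

    Raises :class:`NoInstrumentsError` naming the first stage that empties
    the set; otherwise returns the surviving records and a per-stage count
    report (counts are monotone non-increasing).
    """
    th = thresholds or SelectionThresholds()
    if th.window_bp is not None:
        target = GeneTarget(
            target.gene_symbol, target.drug_class, target.chrom,
            target.start, target.end, th.window_bp, target.trait,
        )
    report = SelectionReport(gene=target.gene_symbol, counts={"input": len(exposure)})

    stages = (
        ("cis", lambda df: cis_filter(df, target)),
        ("significance", lambda df: significance_filter(df, th.p)),
        ("f_stat", lambda df: f_filter(df, th.f)),
        ("ld_clump", lambda df: ld_clump(df, ld, th.r2)),
    )
    current = exposure
    for stage, fn in stages:
        current = fn(current)
        report.counts[stage] = len(current)
        if current.empty:
            raise NoInstrumentsError(target.gene_symbol, stage)
    return current, report
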