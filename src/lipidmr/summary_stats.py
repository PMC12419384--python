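"""GWAS summary statistics: reading, validation, and two-sample harmonization.

Summary statistics are held as pandas DataFrames with the standard columns

    snp, chrom, pos, effect_allele, other_allele, eaf, beta, se, pvalue, n

``eaf`` and ``n`` may be missing (NaN). One row is one biallelic SNP's
association with one trait: ``beta`` is the per-effect-allele effect in SD
units of the trait (log-odds for binary traits) with standard error ``se``.

Harmonization aligns an exposure and an outcome table onto a shared effect
allele per SNP so that the ratio beta_out / beta_exp is meaningful; it is the
plumbing every two-sample MR estimator sits on.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STANDARD_COLUMNS = (
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
)
REQUIRED_COLUMNS = (
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pvalue",
)

HARMONIZED_COLUMNS = (
    "snp", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "p_exp", "eaf_exp",
    "beta_out", "se_out", "p_out", "eaf_out",
    "action",
)

#: actions whose rows never enter estimation
DROP_ACTIONS = ("dropped_palindromic", "dropped_mismatch")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


class SummaryStatsError(ValueError):
    """Malformed summary-statistics input."""


class ConfigurationError(ValueError):
    """Invalid configuration (missing column, bad threshold, ...)."""


class NoOverlapError(SummaryStatsError):
    """Exposure and outcome share no SNP identifiers."""


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
    max_reject_fraction: float = 0.10,
) -> pd.DataFrame:
    """Read a delimited summary-statistics table into standard form.

    Parameters
    ----------
    path
        TSV or CSV file. The delimiter is sniffed from the extension unless
        given explicitly.
    column_map
        Maps standard names (keys of :data:`STANDARD_COLUMNS`) to the file's
        column names, e.g. ``{"snp": "rsid", "pvalue": "P"}``. Unmapped
        standard names are assumed to match literally; ``eaf`` and ``n`` are
        optional.
    max_reject_fraction
        Abort if more than this fraction of rows fails validation.

    Returns
    -------
    DataFrame with :data:`STANDARD_COLUMNS`; rows violating the record
    invariants (non-ACGT or identical alleles, se <= 0, pvalue outside (0, 1],
    pos < 1, unparseable numerics) are dropped. The rejection tally is logged
    and stored in ``df.attrs["read_report"]``.
    """
    column_map = dict(column_map or {})
    if delimiter is None:
        delimiter = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")

    rename = {}
    for std in STANDARD_COLUMNS:
        src = column_map.get(std, std)
        if src in raw.columns:
            rename[src] = std
        elif std in REQUIRED_COLUMNS:
            raise ConfigurationError(
                f"required column {std!r} (file column {src!r}) not found in {path}"
            )
    df = raw.rename(columns=rename)
    for optional in ("eaf", "n"):
        if optional not in df.columns:
            df[optional] = np.nan
    df = df[list(STANDARD_COLUMNS)].copy()

    n_input = len(df)
    report: dict[str, int] = {"n_input": n_input}

    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    bad_numeric = df[["pos", "beta", "se", "pvalue"]].isna().any(axis=1)
    bad_allele = (
        ~df["effect_allele"].isin(_VALID_ALLELES)
        | ~df["other_allele"].isin(_VALID_ALLELES)
        | (df["effect_allele"] == df["other_allele"])
    )
    with np.errstate(invalid="ignore"):
        bad_range = (
            (df["se"] <= 0)
            | (df["pvalue"] <= 0)
            | (df["pvalue"] > 1)
            | (df["pos"] < 1)
            | (df["eaf"] < 0)
            | (df["eaf"] > 1)
        )
    bad_range = bad_range.fillna(False) & ~bad_numeric

    rejected = bad_numeric | bad_allele | bad_range
    report["n_bad_numeric"] = int(bad_numeric.sum())
    report["n_bad_allele"] = int((bad_allele & ~bad_numeric).sum())
    report["n_bad_range"] = int((bad_range & ~bad_allele).sum())
    report["n_rejected"] = int(rejected.sum())

    if n_input and report["n_rejected"] / n_input > max_reject_fraction:
        raise SummaryStatsError(
            f"{report['n_rejected']}/{n_input} rows of {path} failed validation "
            f"(limit {max_reject_fraction:.0%})"
        )
    if report["n_rejected"]:
        logger.warning(
            "%s: rejected %d/%d rows (%d numeric, %d allele, %d range)",
            path, report["n_rejected"], n_input,
            report["n_bad_numeric"], report["n_bad_allele"], report["n_bad_range"],
        )

    out = df.loc[~rejected].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    out["chrom"] = out["chrom"].astype(str)
    out.attrs["read_report"] = report
    return out


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G allele pairs, whose strand is ambiguous."""
    return _COMPLEMENT.get(a1) == a2


def _complement_pair(a1: str, a2: str) -> tuple[str, str]:
    return _COMPLEMENT[a1], _COMPLEMENT[a2]


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_limit: float = 0.42,
) -> pd.DataFrame:
    """Align outcome effects onto the exposure's effect allele, per SNP.

    Joins on ``snp``. For each shared SNP:

    * outcome alleles equal the exposure's  -> ``as_is``;
    * outcome alleles swapped               -> outcome beta negated and
      eaf_out replaced by 1 - eaf_out (``flipped``);
    * alleles match only after strand complement (A<->T, C<->G) -> translate,
      then apply the two rules above;
    * palindromic SNPs (A/T or C/G) are kept only when both allele
      frequencies are known, both fall outside
      ``[palindromic_eaf_limit, 1 - palindromic_eaf_limit]`` and agree in
      direction after alignment; otherwise ``dropped_palindromic``;
    * anything else -> ``dropped_mismatch``.

    Returns the full audit table (one row per shared SNP, ``action`` column);
    use :func:`retained` to get the rows that enter estimation.
    """
    merged = exposure.merge(
        outcome, on="snp", how="inner", suffixes=("_exp", "_out"), validate="1:1"
    )
    if merged.empty:
        raise NoOverlapError("no overlapping instruments between exposure and outcome")

    lo, hi = palindromic_eaf_limit, 1.0 - palindromic_eaf_limit
    rows = []
    for rec in merged.itertuples(index=False):
        e1, e2 = rec.effect_allele_exp, rec.other_allele_exp
        o1, o2 = rec.effect_allele_out, rec.other_allele_out
        beta_out, eaf_out = rec.beta_out, rec.eaf_out
        action = "dropped_mismatch"

        if is_palindromic(e1, e2):
            if {o1, o2} == {e1, e2}:
                if o1 != e1:  # align nominal orientation first
                    beta_out = -beta_out
                    eaf_out = 1.0 - eaf_out if pd.notna(eaf_out) else np.nan
                eaf_exp = rec.eaf_exp
                if (
                    pd.notna(eaf_exp)
                    and pd.notna(eaf_out)
                    and ((eaf_exp < lo and eaf_out < lo) or (eaf_exp > hi and eaf_out > hi))
                ):
                    action = "as_is" if o1 == e1 else "flipped"
                else:
                    action = "dropped_palindromic"
        else:
            if {o1, o2} != {e1, e2} and {o1, o2} == set(_complement_pair(e1, e2)):
                o1, o2 = _complement_pair(o1, o2)  # strand flip, eaf unchanged
            if (o1, o2) == (e1, e2):
                action = "as_is"
            elif (o1, o2) == (e2, e1):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out if pd.notna(eaf_out) else np.nan
                action = "flipped"

        rows.append(
            {
                "snp": rec.snp,
                "effect_allele": e1,
                "other_allele": e2,
                "beta_exp": rec.beta_exp,
                "se_exp": rec.se_exp,
                "p_exp": rec.pvalue_exp,
                "eaf_exp": rec.eaf_exp,
                "beta_out": beta_out,
                "se_out": rec.se_out,
                "p_out": rec.pvalue_out,
                "eaf_out": eaf_out,
                "action": action,
            }
        )

    harmonized = pd.DataFrame(rows, columns=list(HARMONIZED_COLUMNS))
    n_dropped = int(harmonized["action"].str.startswith("dropped").sum())
    if n_dropped:
        logger.info("harmonize: dropped %d/%d SNPs", n_dropped, len(harmonized))
    return harmonized


def retained(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonized table that enter estimation (not dropped)."""
    return harmonized.loc[~harmonized["action"].str.startswith("dropped")].reset_index(
        drop=True
    )


def write_harmonized(harmonized: pd.DataFrame, path) -> None:
    """Write the harmonized audit table as TSV, action column included."""
    harmonized.to_csv(path, sep="\t", index=False)
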