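"""Spontaneous-report disproportionality analysis.

Adverse-event reports arrive as one row per (report, drug) pair with a
boolean flag for the event of interest. For a target drug the 2×2 table is

                    event     no event
    target drug       a          b
    other drugs       c          d

and the signal statistics are the reporting odds ratio ROR = ad/bc with a
Woolf (log-scale) confidence interval, the proportional reporting ratio
PRR = [a/(a+b)] / [c/(c+d)], and the Pearson chi-square. A drug is a signal
when PRR >= 2, chi-square >= 4 and the lower 95% ROR bound exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import Z95


class UndefinedStatisticError(ValueError):
    """A disproportionality statistic is undefined for this table."""


class DrugNotFoundError(KeyError):
    def __init__(self, drug: str):
        super().__init__(f"drug {drug!r} absent from the report table")
        self.drug = drug


@dataclass
class ContingencyTable:
    """Drug-by-event 2×2 report counts."""

    a: int  # target drug, target event
    b: int  # target drug, other events
    c: int  # other drugs, target event
    d: int  # other drugs, other events

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SignalResult:
    drug: str
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    chi2_uncorrected: float
    is_signal: bool
    n_reports: int  # reports (or report-drug pairs) naming the drug


def build_contingency(
    reports: pd.DataFrame,
    drug: str,
    event_col: str = "event_flag",
    unit: str = "pair",
) -> ContingencyTable:
    """Count the 2×2 cells for one drug.

    ``unit="pair"`` counts report-drug pairs (rows); ``unit="report"`` counts
    unique report ids, a report being exposed if any of its rows names the
    drug and an event if any row carries the flag. The two differ whenever
    reports mention several drugs.
    """
    if drug not in set(reports["drug"]):
        raise DrugNotFoundError(drug)
    flag = reports[event_col].astype(bool)
    on_drug = reports["drug"] == drug

    if unit == "pair":
        a = int((on_drug & flag).sum())
        b = int((on_drug & ~flag).sum())
        c = int((~on_drug & flag).sum())
        d = int((~on_drug & ~flag).sum())
    elif unit == "report":
        per_report = (
            reports.assign(_flag=flag, _on=on_drug)
            .groupby("report_id")[["_flag", "_on"]]
            .any()
        )
        a = int((per_report["_on"] & per_report["_flag"]).sum())
        b = int((per_report["_on"] & ~per_report["_flag"]).sum())
        c = int((~per_report["_on"] & per_report["_flag"]).sum())
        d = int((~per_report["_on"] & ~per_report["_flag"]).sum())
    else:
        raise ValueError(f"unknown counting unit {unit!r}")
    return ContingencyTable(a, b, c, d)


def ror(t: ContingencyTable, continuity: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% CI.

    ROR = ad/bc; CI = exp(ln ROR ± 1.959964·sqrt(1/a + 1/b + 1/c + 1/d)).
    Zero cells raise unless ``continuity`` enables the Haldane–Anscombe
    correction (0.5 added to every cell).
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if continuity and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        raise UndefinedStatisticError(
            "ROR undefined with a zero cell (enable continuity correction)"
        )
    estimate = (a * d) / (b * c)
    half_width = Z95 * np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        float(estimate),
        float(estimate * np.exp(-half_width)),
        float(estimate * np.exp(half_width)),
    )


def prr(t: ContingencyTable) -> float:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)]."""
    if t.a + t.b == 0 or t.c + t.d == 0 or t.c == 0:
        raise UndefinedStatisticError("PRR undefined: zero denominator")
    return (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))


def chi2(t: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square on the 2×2, with Yates continuity correction by
    default."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise UndefinedStatisticError("chi-square undefined: zero margin")
    dev = abs(a * d - b * c)
    if yates:
        dev = max(0.0, dev - n / 2.0)
    return float(n * dev**2 / margins)


def signal_rule(prr_value: float, chi2_value: float, ror_ci_low: float) -> bool:
    """The disproportionality signal criterion: PRR >= 2 AND chi-square >= 4
    AND lower 95% ROR bound > 1 (boundary inclusive on PRR and chi-square,
    strict on the CI bound)."""
    return prr_value >= 2.0 and chi2_value >= 4.0 and ror_ci_low > 1.0


def evaluate_drug(
    reports: pd.DataFrame,
    drug: str,
    event_col: str = "event_flag",
    unit: str = "pair",
    yates: bool = True,
    continuity: bool = False,
) -> SignalResult:
    """Full signal assessment of one drug against all others in the table."""
    t = build_contingency(reports, drug, event_col=event_col, unit=unit)
    ror_est, lo, hi = ror(t, continuity=continuity)
    prr_val = prr(t)
    chi_default = chi2(t, yates=yates)
    chi_plain = chi2(t, yates=False)
    return SignalResult(
        drug=drug, ror=ror_est, ror_ci_low=lo, ror_ci_high=hi,
        prr=prr_val, chi2=chi_default, chi2_uncorrected=chi_plain,
        is_signal=signal_rule(prr_val, chi_default, lo),
        n_reports=t.a + t.b,
    )


def signal_table(
    reports: pd.DataFrame,
    drugs: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Per-drug SignalResult table, sorted by ROR descending."""
    if drugs is None:
        drugs = sorted(reports["drug"].unique())
    rows = [vars(evaluate_drug(reports, d, **kwargs)) for d in drugs]
    return (
        pd.DataFrame(rows)
        .sort_values("ror", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


def event_rate_summary(
    reports: pd.DataFrame, event_col: str = "event_flag", unit: str = "report"
) -> tuple[int, int, float]:
    """(n_total, n_event, percent) with percent = 100·n_event/n_total rounded
    to 3 decimals. Counts unique reports by default."""
    if unit == "report":
        per_report = reports.groupby("report_id")[event_col].any()
        n_total = int(per_report.size)
        n_event = int(per_report.sum())
    else:
        n_total = len(reports)
        n_event = int(reports[event_col].astype(bool).sum())
    if n_total == 0:
        raise UndefinedStatisticError("no reports")
    return n_total, n_event, round(100.0 * n_event / n_total, 3)


def event_rate_percent(n_total: int, n_event: int) -> float:
    """Percentage of event reports, rounded to 3 decimals."""
    if n_total == 0:
        raise UndefinedStatisticError("no reports")
    return round(100.0 * n_event / n_total, 3)
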