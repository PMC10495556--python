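"""Historical operational-log handling and projection-vs-actual evaluation.

A log is a CSV time series with one row per review period and the header
``period_start,shown,flagged,contacted``: how many patients' data were shown
to reviewers, how many the flagging algorithm marked for review, and how
many were actually contacted.  From such a log this module computes the
period-level contacted/flagged ratio statistics, fits simulator calibration
parameters, and compares model projections against actual counts.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LogValidationError, NoValidPeriodsError
from .model import Scenario, project_population

__all__ = [
    "LOG_HEADER",
    "PeriodRecord",
    "RatioStatistics",
    "CalibrationFit",
    "ComparisonResult",
    "load_log",
    "write_log",
    "ratio_statistics",
    "projection_vs_actual",
    "fit_calibration",
]

LOG_HEADER = ("period_start", "shown", "flagged", "contacted")


@dataclass(frozen=True)
class PeriodRecord:
    """One review period's operational counts.

    Dates are period labels only; no calendar arithmetic is performed on
    them (gap weeks are the caller's responsibility).
    """

    period_start: date
    shown: int
    flagged: int
    contacted: int

    def __post_init__(self):
        if not 0 <= self.contacted <= self.flagged <= self.shown:
            raise LogValidationError(
                f"{self.period_start}: counts must satisfy "
                f"0 <= contacted <= flagged <= shown "
                f"(got {self.shown}/{self.flagged}/{self.contacted})"
            )


@dataclass(frozen=True)
class RatioStatistics:
    """Per-period contacted/flagged ratio statistics, in percent.

    Periods with flagged = 0 are excluded (the ratio is undefined there);
    ``n_excluded`` counts them.  ``sd_ratio`` is the sample (n-1) standard
    deviation, 0.0 when only one valid period exists.  Both statistics are
    reported to one decimal place.
    """

    n_periods: int
    n_excluded: int
    mean_ratio: float
    sd_ratio: float


def _parse_count(value: str, name: str, line: int) -> int:
    try:
        n = int(value)
    except ValueError:
        raise LogValidationError(f"{name} is not an integer: {value!r}", line=line)
    if n < 0:
        raise LogValidationError(f"{name} must be >= 0 (got {n})", line=line)
    return n


def load_log(path: str | Path) -> list[PeriodRecord]:
    """Read and validate a historical-log CSV.

    Enforces the exact header, integer counts with
    contacted <= flagged <= shown, ISO-8601 dates in strictly increasing
    order; errors name the offending line.  An empty body yields an empty
    list.
    """
    records: list[PeriodRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LogValidationError("empty file: missing header", line=1)
        if tuple(h.strip() for h in header) != LOG_HEADER:
            raise LogValidationError(
                f"bad header {header!r}; expected {','.join(LOG_HEADER)}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 4:
                raise LogValidationError(
                    f"expected 4 fields, got {len(row)}", line=lineno
                )
            try:
                when = date.fromisoformat(row[0].strip())
            except ValueError:
                raise LogValidationError(
                    f"period_start is not an ISO-8601 date: {row[0]!r}", line=lineno
                )
            shown = _parse_count(row[1], "shown", lineno)
            flagged = _parse_count(row[2], "flagged", lineno)
            contacted = _parse_count(row[3], "contacted", lineno)
            if not contacted <= flagged <= shown:
                raise LogValidationError(
                    "counts must satisfy contacted <= flagged <= shown "
                    f"(got {shown}/{flagged}/{contacted})",
                    line=lineno,
                )
            if records and when <= records[-1].period_start:
                raise LogValidationError(
                    f"period_start {when} not after previous "
                    f"{records[-1].period_start}",
                    line=lineno,
                )
            records.append(PeriodRecord(when, shown, flagged, contacted))
    return records


def write_log(records: list[PeriodRecord], path: str | Path) -> None:
    """Write a historical-log CSV (exact inverse of :func:`load_log`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LOG_HEADER)
        for r in records:
            writer.writerow([r.period_start.isoformat(), r.shown, r.flagged, r.contacted])


def ratio_statistics(records: list[PeriodRecord]) -> RatioStatistics:
    """Mean and sample SD of the per-period contacted/flagged ratio, in %."""
    ratios = [r.contacted / r.flagged for r in records if r.flagged > 0]
    n_excluded = len(records) - len(ratios)
    if not ratios:
        raise NoValidPeriodsError(
            "no period with flagged > 0; the contacted/flagged ratio is undefined"
        )
    arr = np.asarray(ratios)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return RatioStatistics(
        n_periods=len(arr),
        n_excluded=n_excluded,
        mean_ratio=round(100.0 * float(arr.mean()), 1),
        sd_ratio=round(100.0 * sd, 1),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Projection-versus-actual comparison.

    ``table`` has one row per log period; ``mape`` is the mean absolute
    percentage error of projected versus actual contacts over periods with
    actual contacts > 0.
    """

    table: pd.DataFrame
    mape: float


def projection_vs_actual(
    records: list[PeriodRecord],
    scenario: Scenario,
    flag_probability: float | None = None,
) -> ComparisonResult:
    """Compare the model's projected contacts with a log's actual contacts.

    Projects the population over the log's horizon with the enrol/graduate
    recurrence and computes projected contacts per period as
    sum_i f_i * p_i * (N_i(k) + A_i).  When ``flag_probability`` is given,
    projected flagged counts (f_i * (N_i + A_i) * flag_probability) are
    compared as well.
    """
    if not records:
        raise NoValidPeriodsError("log is empty")
    horizon = len(records)
    trajectory = project_population(scenario.cohorts, horizon)
    projected = np.zeros(horizon)
    projected_reviews = np.zeros(horizon)
    for c in scenario.cohorts:
        pop = trajectory.counts[c.name].to_numpy() + c.new_per_period
        projected += c.review_frequency * c.contact_fraction * pop
        projected_reviews += c.review_frequency * pop
    actual = np.array([r.contacted for r in records], dtype=float)
    table = pd.DataFrame(
        {
            "period_start": [r.period_start for r in records],
            "actual_contacted": actual.astype(int),
            "projected_contacted": projected,
            "error": projected - actual,
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["pct_error"] = np.where(
            actual > 0, 100.0 * (projected - actual) / actual, np.nan
        )
    if flag_probability is not None:
        actual_flagged = np.array([r.flagged for r in records], dtype=float)
        proj_flagged = projected_reviews * flag_probability
        table["actual_flagged"] = actual_flagged.astype(int)
        table["projected_flagged"] = proj_flagged
        table["flagged_pct_error"] = np.where(
            actual_flagged > 0,
            100.0 * (proj_flagged - actual_flagged) / actual_flagged,
            np.nan,
        )
    valid = table["pct_error"].dropna()
    mape = float(valid.abs().mean()) if len(valid) else float("nan")
    return ComparisonResult(table=table, mape=mape)


@dataclass(frozen=True)
class CalibrationFit:
    """Simulator calibration fitted from a historical log (fractions, not %)."""

    contact_ratio_mean: float
    contact_ratio_sd: float
    flag_probability: float
    n_periods_ratio: int
    n_periods_flag: int


def fit_calibration(records: list[PeriodRecord]) -> CalibrationFit:
    """Fit simulator parameters from a log.

    Contact-ratio mean/SD come from :func:`ratio_statistics`;
    ``flag_probability`` is the mean per-period flagged/shown over periods
    with shown > 0.  Excluded periods trigger a warning.
    """
    stats_ = ratio_statistics(records)
    flag_ratios = [r.flagged / r.shown for r in records if r.shown > 0]
    n_skipped = len(records) - len(flag_ratios)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} period(s) with shown=0 excluded from flag-probability fit",
            stacklevel=2,
        )
    if not flag_ratios:
        raise NoValidPeriodsError("no period with shown > 0")
    return CalibrationFit(
        contact_ratio_mean=stats_.mean_ratio / 100.0,
        contact_ratio_sd=stats_.sd_ratio / 100.0,
        flag_probability=float(np.mean(flag_ratios)),
        n_periods_ratio=stats_.n_periods,
        n_periods_flag=len(flag_ratios),
    )
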