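"""Cohort-level fragility analysis: batch FI/FQ, summary statistics, I/O.

Applies the fragility computation to a set of trials — the built-in fixture
of six phase-3 hepatocellular-carcinoma trials, or any CSV in the documented
schema — and aggregates median/IQR of the fragility indices and sample
sizes.  Quantiles use (n+1)-position linear interpolation (Hyndman & Fan
type 6), the convention that reproduces the cohort's published quartiles.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .contingency import ContingencyTable
from .fragility import FragilityConfig, FragilityResult, format_fq_percent, fragility_index

__all__ = [
    "EndpointRank",
    "TrialRecord",
    "CohortSummary",
    "CsvSchemaError",
    "NonOneToOneError",
    "CSV_COLUMNS",
    "builtin_table1",
    "quantile",
    "summarize_cohort",
    "load_trials_csv",
    "write_trials_csv",
    "write_summary",
]

CSV_COLUMNS = (
    "study_label",
    "registry_id",
    "comparison",
    "endpoint_label",
    "endpoint_rank",
    "exp_total",
    "exp_events",
    "ctrl_total",
    "ctrl_events",
    "reported_p",
    "allocation_ratio",
)


class EndpointRank(str, enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"


class CsvSchemaError(ValueError):
    """Malformed trial CSV: missing columns or an invalid row."""


class NonOneToOneError(ValueError):
    """A trial without 1:1 allocation; the FI method is undefined for it."""


@dataclass(frozen=True)
class TrialRecord:
    """One trial's metadata and 2x2 outcome table.

    ``reported_p`` is the p-value the trial itself published (often a
    stratified log-rank on time-to-event data, not a Fisher p).  It is
    carried as metadata only and never enters any computation here.
    """

    study_label: str
    registry_id: str
    comparison: str
    endpoint_label: str
    endpoint_rank: EndpointRank
    table: ContingencyTable
    reported_p: float | None = None
    allocation_ratio: str = "1:1"


@dataclass(frozen=True)
class CohortSummary:
    per_trial: tuple[tuple[TrialRecord, FragilityResult], ...]
    median_fi: float
    fi_iqr: tuple[float, float]
    median_n: float
    n_iqr: tuple[float, float]
    n_fi_zero_primary: int
    n_trials: int


def builtin_table1() -> list[TrialRecord]:
    """The six 1:1-randomized phase-3 HCC trials shipped with the package.

    Loaded from the packaged ``data/table1.csv`` fixture; arm sizes and
    event counts are the published end-of-study dichotomous outcomes.
    """
    with resources.files("trialfragility.data").joinpath("table1.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return _parse_trials(fh, source="builtin table1.csv")


def quantile(values: Sequence[float], q: float) -> float:
    """Order statistic at position (n+1)q with linear interpolation.

    Positions below 1 or above n clamp to the sample extremes.  This is the
    Hyndman & Fan type-6 ("Weibull") definition; for six sorted values the
    quartiles interpolate at positions 1.75 and 5.25.
    """
    if len(values) == 0:
        raise ValueError("quantile of an empty sequence is undefined")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    return float(np.quantile(np.asarray(values, dtype=float), q, method="weibull"))


def summarize_cohort(
    records: Sequence[TrialRecord], config: FragilityConfig | None = None
) -> CohortSummary:
    """Run the FI computation on every trial and aggregate the cohort.

    Raises :class:`NonOneToOneError` for any record whose allocation ratio
    is not 1:1, naming the offending trial: the FI method as used here is
    defined only for equal-allocation two-arm designs.
    """
    if not records:
        raise ValueError("cohort must contain at least one trial")
    for rec in records:
        if rec.allocation_ratio.replace(" ", "") != "1:1":
            raise NonOneToOneError(
                f"trial {rec.study_label!r} ({rec.registry_id}) has allocation "
                f"{rec.allocation_ratio!r}; FI requires 1:1 randomization"
            )
    if config is None:
        config = FragilityConfig()

    per_trial = tuple((rec, fragility_index(rec.table, config)) for rec in records)
    fis = [res.fragility_index for _, res in per_trial]
    ns = [rec.table.grand_total for rec, _ in per_trial]
    n_fi_zero_primary = sum(
        1
        for rec, res in per_trial
        if rec.endpoint_rank is EndpointRank.PRIMARY and res.fragility_index == 0
    )
    return CohortSummary(
        per_trial=per_trial,
        median_fi=quantile(fis, 0.5),
        fi_iqr=(quantile(fis, 0.25), quantile(fis, 0.75)),
        median_n=quantile(ns, 0.5),
        n_iqr=(quantile(ns, 0.25), quantile(ns, 0.75)),
        n_fi_zero_primary=n_fi_zero_primary,
        n_trials=len(per_trial),
    )


def _parse_trials(fh: Iterable[str], source: str) -> list[TrialRecord]:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise CsvSchemaError(f"{source}: empty file, header row required")
    missing = set(CSV_COLUMNS) - set(reader.fieldnames)
    if missing:
        raise CsvSchemaError(f"{source}: missing required columns {sorted(missing)}")
    records: list[TrialRecord] = []
    for row in reader:
        line = reader.line_num
        try:
            table = ContingencyTable.from_counts(
                int(row["exp_events"]),
                int(row["exp_total"]),
                int(row["ctrl_events"]),
                int(row["ctrl_total"]),
            )
            reported = row["reported_p"].strip()
            records.append(
                TrialRecord(
                    study_label=row["study_label"],
                    registry_id=row["registry_id"],
                    comparison=row["comparison"],
                    endpoint_label=row["endpoint_label"],
                    endpoint_rank=EndpointRank(row["endpoint_rank"].strip().lower()),
                    table=table,
                    reported_p=float(reported) if reported else None,
                    allocation_ratio=row["allocation_ratio"].strip(),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise CsvSchemaError(f"{source}: invalid row at line {line}: {exc}") from exc
    return records


def load_trials_csv(path: str | Path) -> list[TrialRecord]:
    """Load trial records from a CSV in the documented schema.

    Required header: ``study_label, registry_id, comparison, endpoint_label,
    endpoint_rank, exp_total, exp_events, ctrl_total, ctrl_events,
    reported_p, allocation_ratio``.  ``reported_p`` may be empty.  A
    malformed row raises :class:`CsvSchemaError` naming the line.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        return _parse_trials(fh, source=str(path))


def write_trials_csv(records: Sequence[TrialRecord], path: str | Path) -> None:
    """Write records in the input schema; ``load_trials_csv`` round-trips them."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.study_label,
                    rec.registry_id,
                    rec.comparison,
                    rec.endpoint_label,
                    rec.endpoint_rank.value,
                    rec.table.experimental.total,
                    rec.table.experimental.events,
                    rec.table.control.total,
                    rec.table.control.events,
                    "" if rec.reported_p is None else repr(rec.reported_p),
                    rec.allocation_ratio,
                ]
            )


def _per_trial_rows(summary: CohortSummary) -> list[dict]:
    rows = []
    for rec, res in summary.per_trial:
        rows.append(
            {
                "study_label": rec.study_label,
                "registry_id": rec.registry_id,
                "endpoint_label": rec.endpoint_label,
                "endpoint_rank": rec.endpoint_rank.value,
                "exp_total": rec.table.experimental.total,
                "exp_events": rec.table.experimental.events,
                "ctrl_total": rec.table.control.total,
                "ctrl_events": rec.table.control.events,
                "total_n": rec.table.grand_total,
                "fi": res.fragility_index,
                "fq_percent": format_fq_percent(res.fragility_quotient_percent),
                "baseline_p": res.baseline_p,
                "converged": res.converged,
            }
        )
    return rows


def summary_as_dict(summary: CohortSummary) -> dict:
    """JSON-ready view of a cohort summary (per-trial rows plus aggregates)."""
    return {
        "n_trials": summary.n_trials,
        "median_fi": summary.median_fi,
        "fi_iqr": list(summary.fi_iqr),
        "median_n": summary.median_n,
        "n_iqr": list(summary.n_iqr),
        "n_fi_zero_primary": summary.n_fi_zero_primary,
        "per_trial": _per_trial_rows(summary),
    }


def write_summary(summary: CohortSummary, path: str | Path, format: str = "csv") -> None:
    """Write a cohort summary as per-trial CSV or a JSON document."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(summary_as_dict(summary), indent=2) + "\n")
    elif format == "csv":
        rows = _per_trial_rows(summary)
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown summary format {format!r}; use 'csv' or 'json'")
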