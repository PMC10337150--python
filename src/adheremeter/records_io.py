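"""Reading, validating and writing prescription-record tables.

The expected input is one CSV row per *dispensed* prescription, carrying the
fields routinely available in linked prescribing/dispensing data: a
pseudo-anonymised patient identifier, prescription and dispensing dates,
medication name, BNF item code, formulation, prescribed and dispensed
quantities, and the free-text dose directions.  Column names are remappable
through a schema configuration so files from different sources can be read
without renaming columns upstream.

All downstream supply arithmetic uses the dispensing date as the event date:
only collected prescriptions enter the analysis, and collection is when the
medication becomes available to the patient.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: canonical column names, in output order
CANONICAL_COLUMNS = (
    "patient_id",
    "prescription_date",
    "dispensing_date",
    "medication_name",
    "bnf_code",
    "formulation",
    "prescribed_quantity",
    "dispensed_quantity",
    "dose_text",
)

_MANDATORY = ("patient_id", "dispensing_date", "dispensed_quantity")


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensed prescription event with its raw dose directions."""

    patient_id: str
    prescription_date: dt.date | None
    dispensing_date: dt.date
    medication_name: str = ""
    bnf_code: str = ""
    formulation: str = ""
    prescribed_quantity: float | None = None
    dispensed_quantity: float = 0.0
    dose_text: str = ""


@dataclass(frozen=True)
class ObservationPeriod:
    """Closed per-patient date interval over which adherence is assessed."""

    patient_id: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError(
                f"observation period for {self.patient_id!r} ends "
                f"({self.end_date}) before it starts ({self.start_date})"
            )

    @property
    def duration_days(self) -> int:
        """Number of days in the closed interval (end - start + 1)."""
        return (self.end_date - self.start_date).days + 1


@dataclass
class RowIssue:
    """One row rejected (or repaired) during validation."""

    row: int  # 0-based position in the input file, excluding the header
    reason: str


@dataclass
class ValidationReport:
    n_read: int = 0
    n_kept: int = 0
    issues: list[RowIssue] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_read - self.n_kept


class SchemaError(ValueError):
    """A mandatory column is missing from the input file."""


def load_schema_config(path: str | Path) -> dict[str, str]:
    """Load a ``canonical name -> file column name`` mapping from YAML/JSON."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise SchemaError(f"schema config {path} must be a mapping")
    unknown = set(mapping) - set(CANONICAL_COLUMNS)
    if unknown:
        raise SchemaError(f"schema config maps unknown fields: {sorted(unknown)}")
    return dict(mapping)


def _parse_date(value, dayfirst: bool) -> dt.date | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    text = str(value).strip()
    if not text:
        return None
    ts = pd.to_datetime(text, dayfirst=dayfirst, errors="coerce")
    if pd.isna(ts):
        raise ValueError(f"unparseable date {text!r}")
    return ts.date()


def read_records(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
    *,
    dayfirst: bool = False,
) -> tuple[list[PrescriptionRecord], ValidationReport]:
    """Read and validate a prescription CSV.

    Rows failing a validation rule (unparseable date, dispensing before
    prescription, non-positive dispensed quantity) are excluded and reported
    with their row number; validation never mutates passing rows.  Dates are
    parsed as ISO-8601 by default; set ``dayfirst=True`` for d/m/y files.

    Returns the surviving records sorted by (patient_id, dispensing_date,
    prescription_date) together with a :class:`ValidationReport`.
    """
    mapping = dict(schema_config or {})
    rename = {v: k for k, v in mapping.items()}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.rename(columns=rename)

    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"mandatory column(s) missing from {path}: {missing}")

    report = ValidationReport(n_read=len(df))
    records: list[PrescriptionRecord] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        data = dict(zip(df.columns, row))
        try:
            dispensing = _parse_date(data.get("dispensing_date"), dayfirst)
            prescription = _parse_date(data.get("prescription_date"), dayfirst)
        except ValueError as exc:
            report.issues.append(RowIssue(row_idx, str(exc)))
            continue
        if dispensing is None:
            report.issues.append(RowIssue(row_idx, "missing dispensing_date"))
            continue
        if prescription is not None and dispensing < prescription:
            report.issues.append(
                RowIssue(row_idx, "dispensing_date before prescription_date")
            )
            continue
        qty_text = str(data.get("dispensed_quantity", "")).strip()
        try:
            quantity = float(qty_text) if qty_text else float("nan")
        except ValueError:
            report.issues.append(
                RowIssue(row_idx, f"unparseable dispensed_quantity {qty_text!r}")
            )
            continue
        if not quantity > 0:
            report.issues.append(
                RowIssue(row_idx, "dispensed_quantity missing or not positive")
            )
            continue

        def _num(key: str) -> float | None:
            text = str(data.get(key, "")).strip()
            try:
                return float(text) if text else None
            except ValueError:
                return None

        records.append(
            PrescriptionRecord(
                patient_id=str(data["patient_id"]),
                prescription_date=prescription,
                dispensing_date=dispensing,
                medication_name=str(data.get("medication_name", "")),
                bnf_code=str(data.get("bnf_code", "")),
                formulation=str(data.get("formulation", "")),
                prescribed_quantity=_num("prescribed_quantity"),
                dispensed_quantity=quantity,
                dose_text=str(data.get("dose_text", "")),
            )
        )

    records.sort(
        key=lambda r: (r.patient_id, r.dispensing_date, r.prescription_date or r.dispensing_date)
    )
    report.n_kept = len(records)
    if report.n_excluded:
        logger.info(
            "read_records(%s): %d rows read, %d excluded", path, report.n_read, report.n_excluded
        )
    return records, report


def records_to_frame(records: Iterable[PrescriptionRecord]) -> pd.DataFrame:
    """Canonical-schema DataFrame view of a record collection."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "prescription_date": r.prescription_date.isoformat() if r.prescription_date else "",
                "dispensing_date": r.dispensing_date.isoformat(),
                "medication_name": r.medication_name,
                "bnf_code": r.bnf_code,
                "formulation": r.formulation,
                "prescribed_quantity": r.prescribed_quantity,
                "dispensed_quantity": r.dispensed_quantity,
                "dose_text": r.dose_text,
            }
            for r in records
        ],
        columns=list(CANONICAL_COLUMNS),
    )


def write_records(records: Iterable[PrescriptionRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_periods(path: str | Path, *, dayfirst: bool = False) -> dict[str, ObservationPeriod]:
    """Read a companion table of per-patient observation periods.

    Expected columns: patient_id, start_date, end_date.
    """
    df = pd.read_csv(path, dtype=str)
    missing = {"patient_id", "start_date", "end_date"} - set(df.columns)
    if missing:
        raise SchemaError(f"period table missing column(s): {sorted(missing)}")
    periods: dict[str, ObservationPeriod] = {}
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        periods[pid] = ObservationPeriod(
            patient_id=pid,
            start_date=_parse_date(row.start_date, dayfirst),
            end_date=_parse_date(row.end_date, dayfirst),
        )
    return periods


def write_periods(periods: Mapping[str, ObservationPeriod] | Iterable[ObservationPeriod],
                  path: str | Path) -> None:
    values = periods.values() if isinstance(periods, Mapping) else periods
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "start_date": p.start_date.isoformat(),
                "end_date": p.end_date.isoformat(),
            }
            for p in values
        ],
        columns=["patient_id", "start_date", "end_date"],
    ).to_csv(path, index=False)


def default_periods(
    records: Sequence[PrescriptionRecord], study_end: dt.date
) -> dict[str, ObservationPeriod]:
    """Default observation periods: [first dispensing date, study end].

    Used when no companion period table is supplied; the per-patient window
    opens at the first observed collection and closes at a common study end
    date.
    """
    firsts: dict[str, dt.date] = {}
    for r in records:
        prev = firsts.get(r.patient_id)
        if prev is None or r.dispensing_date < prev:
            firsts[r.patient_id] = r.dispensing_date
    return {
        pid: ObservationPeriod(pid, start, max(start, study_end))
        for pid, start in firsts.items()
    }


# ---------------------------------------------------------------------------
# estimate serialisation

ESTIMATE_COLUMNS = ("patient_id", "interval_label", "measure", "policy", "value", "n_prescriptions")


def write_estimates(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format estimate table to CSV.

    Non-calculable values (NaN) and not-applicable policies are serialised as
    empty fields.
    """
    out = table.copy()
    for col in ESTIMATE_COLUMNS:
        if col not in out.columns:
            raise ValueError(f"estimate table missing column {col!r}")
    out = out[list(ESTIMATE_COLUMNS)]
    out.to_csv(path, index=False, na_rep="")


def read_estimates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "patient_id": str,
            "interval_label": str,
            "measure": str,
            "policy": str,
            "n_prescriptions": "Int64",
        },
    )
    df["policy"] = df["policy"].fillna("")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df
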