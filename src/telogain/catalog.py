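"""Catalog of study-level summaries from longitudinal leukocyte telomere length (LTL) studies.

Each :class:`StudyRecord` holds one published study's summary row: mean
telomere length (TL) at baseline and follow-up, the mean attrition rate, the
assay's inter-assay coefficient of variation (CV) and replicate scheme. The
packaged catalog transcribes the summary table of published longitudinal LTL
studies spanning 0.5 to 13.1 years of follow-up, measured by Southern blot
(SB, absolute units) or quantitative PCR (qPCR, relative T/S units).

Unit conventions
----------------
``units`` names the unit of the *level* columns (``baseline_tl``,
``followup_tl``):

* ``bp`` — levels in base pairs, ``attrition_rate`` in bp/yr;
* ``kb`` — levels in kilobases, ``attrition_rate`` in bp/yr (the convention
  used by the published table, where a 7.33 kb baseline shortens at
  25.2 bp/yr);
* ``TS`` — levels and rate in T/S ratio units (relative; no conversion to
  bp is possible without external calibration).

:func:`to_base_units` normalises everything to bp (or flags T/S records as
relative) before any prediction is made.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Optional

__all__ = [
    "StudyRecord",
    "CatalogSchemaError",
    "CatalogParseError",
    "load_catalog",
    "write_catalog",
    "builtin_table1",
    "to_base_units",
]

VALID_UNITS = frozenset({"bp", "kb", "TS"})
VALID_METHODS = frozenset({"SB", "qPCR"})

#: CSV column order; also the documented schema.
CSV_COLUMNS = (
    "study_id",
    "year",
    "n",
    "followup_years",
    "baseline_tl",
    "followup_tl",
    "attrition_rate",
    "units",
    "method",
    "cv",
    "replicates",
    "observed_gainers_pct",
    "observed_ci_low",
    "observed_ci_high",
    "maintainer_band_pct",
    "notes",
)

MANDATORY_COLUMNS = (
    "study_id",
    "year",
    "n",
    "followup_years",
    "units",
    "method",
)

#: Fields that a gainer-percentage prediction needs (replicates defaults to 1).
PREDICTION_FIELDS = ("baseline_tl", "followup_tl", "attrition_rate", "cv")


class CatalogSchemaError(ValueError):
    """The file does not conform to the documented catalog schema."""


class CatalogParseError(ValueError):
    """A catalog cell could not be parsed; the message names the row."""


@dataclass
class StudyRecord:
    """One longitudinal study's summary row.

    Attributes
    ----------
    study_id : str
        Short label, e.g. ``"kark2012"``.
    year : int
        Publication year.
    n : int
        Number of participants.
    followup_years : float
        Follow-up duration in years (> 0).
    baseline_tl, followup_tl : float, optional
        Mean TL at baseline / follow-up, in ``units``.
    attrition_rate : float, optional
        Mean TL loss per year (bp/yr for bp- and kb-unit records, T/S
        units/yr for T/S records). Derivable as
        ``(baseline - followup) / followup_years`` when absent.
    units : str
        One of ``bp``, ``kb``, ``TS`` (see module docstring).
    method : str
        ``SB`` (Southern blot) or ``qPCR``.
    cv : float, optional
        Inter-assay coefficient of variation as a *fraction* (0.015 = 1.5%).
    replicates : int
        Inter-assay replicates per time point; 1 when a study does not
        report a replicate scheme.
    observed_gainers_pct : float, optional
        The study's reported percentage of apparent TL gainers.
    observed_ci : (float, float), optional
        Reported 95% CI for the observed percentage, in percent.
    maintainer_band_pct : float, optional
        Half-width of the study's "unchanged TL" band, in percent of
        baseline (e.g. 15 for a ±15% band).
    relative_units : bool
        Set by :func:`to_base_units` for T/S records, which stay in
        relative units.
    """

    study_id: str
    year: int
    n: int
    followup_years: float
    baseline_tl: Optional[float] = None
    followup_tl: Optional[float] = None
    attrition_rate: Optional[float] = None
    units: str = "bp"
    method: str = "SB"
    cv: Optional[float] = None
    replicates: int = 1
    observed_gainers_pct: Optional[float] = None
    observed_ci: Optional[tuple[float, float]] = None
    maintainer_band_pct: Optional[float] = None
    notes: str = ""
    relative_units: bool = False

    def __post_init__(self) -> None:
        if self.units not in VALID_UNITS:
            raise CatalogSchemaError(
                f"{self.study_id}: unknown units {self.units!r}; expected one of {sorted(VALID_UNITS)}"
            )
        if self.method not in VALID_METHODS:
            raise CatalogSchemaError(
                f"{self.study_id}: unknown method {self.method!r}; expected one of {sorted(VALID_METHODS)}"
            )
        if not self.followup_years > 0:
            raise CatalogSchemaError(f"{self.study_id}: followup_years must be > 0")
        if self.cv is not None and self.cv < 0:
            raise CatalogSchemaError(f"{self.study_id}: cv must be >= 0")
        if self.replicates < 1:
            raise CatalogSchemaError(f"{self.study_id}: replicates must be >= 1")
        if self.n < 1:
            raise CatalogSchemaError(f"{self.study_id}: n must be a positive integer")
        # Published tables round levels and rates independently, so a
        # positive reported rate can disagree with the level difference;
        # warn rather than fail.
        if (
            self.baseline_tl is not None
            and self.followup_tl is not None
            and self.attrition_rate is not None
            and self.attrition_rate >= 0
            and self.baseline_tl < self.followup_tl
        ):
            warnings.warn(
                f"{self.study_id}: baseline_tl < followup_tl despite a non-negative "
                "attrition_rate (likely a rounding mismatch in the source table)",
                stacklevel=2,
            )

    @property
    def incomplete_for_prediction(self) -> Optional[str]:
        """Reason string if the record lacks a field the prediction needs, else None."""
        missing = [f for f in PREDICTION_FIELDS if getattr(self, f) is None]
        if not missing:
            return None
        return "cannot predict: missing " + ", ".join(missing)


# ---------------------------------------------------------------------------
# serialisation helpers

_INT_FIELDS = {"year", "n", "replicates"}
_FLOAT_FIELDS = {
    "followup_years",
    "baseline_tl",
    "followup_tl",
    "attrition_rate",
    "cv",
    "observed_gainers_pct",
    "observed_ci_low",
    "observed_ci_high",
    "maintainer_band_pct",
}


def _parse_cell(column: str, raw: str, row_index: int):
    raw = raw.strip()
    if raw == "":
        return None
    try:
        if column in _INT_FIELDS:
            return int(raw)
        if column in _FLOAT_FIELDS:
            return float(raw)
    except ValueError as exc:
        raise CatalogParseError(
            f"row {row_index}: non-numeric value {raw!r} in column {column!r}"
        ) from exc
    return raw


def _record_from_mapping(cells: dict, row_index: int) -> StudyRecord:
    for col in MANDATORY_COLUMNS:
        if cells.get(col) in (None, ""):
            raise CatalogSchemaError(
                f"row {row_index}: missing mandatory column {col!r}"
            )
    ci_low = cells.pop("observed_ci_low", None)
    ci_high = cells.pop("observed_ci_high", None)
    observed_ci = None if ci_low is None or ci_high is None else (ci_low, ci_high)
    if cells.get("replicates") is None:
        cells["replicates"] = 1
    if cells.get("notes") is None:
        cells["notes"] = ""
    known = {f.name for f in fields(StudyRecord)}
    cells = {k: v for k, v in cells.items() if k in known}
    return StudyRecord(observed_ci=observed_ci, **cells)


def _record_to_row(rec: StudyRecord) -> dict:
    row: dict[str, str] = {}
    for col in CSV_COLUMNS:
        if col == "observed_ci_low":
            val = rec.observed_ci[0] if rec.observed_ci else None
        elif col == "observed_ci_high":
            val = rec.observed_ci[1] if rec.observed_ci else None
        else:
            val = getattr(rec, col)
        row[col] = "" if val is None else (repr(val) if isinstance(val, float) else str(val))
    return row


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    return "json" if path.suffix.lower() == ".json" else "csv"


def load_catalog(path, format: Optional[str] = None) -> list[StudyRecord]:
    """Read a study catalog from CSV or JSON.

    Parameters
    ----------
    path : path-like
        File to read.
    format : {"csv", "json"}, optional
        Inferred from the file suffix when omitted.

    Raises
    ------
    CatalogSchemaError
        When a mandatory column is absent, naming the column.
    CatalogParseError
        When a cell cannot be parsed, naming the row index.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        raw_rows = json.loads(path.read_text())
        records = []
        for i, row in enumerate(raw_rows):
            cells = {
                k: _parse_cell(k, str(v), i) if not isinstance(v, (int, float, type(None))) else v
                for k, v in row.items()
            }
            records.append(_record_from_mapping(cells, i))
        return records
    if fmt != "csv":
        raise ValueError(f"unknown catalog format {fmt!r}")

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        header = set(reader.fieldnames)
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise CatalogSchemaError(f"missing mandatory column {col!r}")
        records = []
        for i, row in enumerate(reader):
            cells = {k: _parse_cell(k, v or "", i) for k, v in row.items() if k is not None}
            records.append(_record_from_mapping(cells, i))
    return records


def write_catalog(records: list[StudyRecord], path, format: Optional[str] = None) -> None:
    """Write a catalog; the inverse of :func:`load_catalog` (exact round-trip)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        rows = []
        for rec in records:
            row = _record_to_row(rec)
            typed = {
                k: _parse_cell(k, v, 0) if v != "" else None for k, v in row.items()
            }
            rows.append(typed)
        path.write_text(json.dumps(rows, indent=1))
        return
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for rec in records:
            writer.writerow(_record_to_row(rec))


def builtin_table1() -> list[StudyRecord]:
    """The packaged catalog of published longitudinal LTL studies (15 rows).

    Transcribes the summary table of studies with follow-up from 0.5 to
    13.1 years, including three sub-studies of the Bogalusa Heart Study
    cohort measured at different intervals and two Martin-Ruiz sub-cohorts.
    Rows lacking the inputs a prediction needs (missing TL levels, change,
    or CV) are retained and flagged via
    :attr:`StudyRecord.incomplete_for_prediction`.
    """
    ref = resources.files("telogain").joinpath("data/table1.csv")
    with resources.as_file(ref) as p:
        return load_catalog(p, format="csv")


def to_base_units(record: StudyRecord) -> StudyRecord:
    """Normalise a record's TL columns to base pairs.

    kb levels are multiplied by 1000 (the attrition rate of kb records is
    already bp/yr by the table convention and is left unchanged); bp records
    pass through; T/S records stay in relative units with
    ``relative_units=True``.
    """
    if record.units == "bp":
        return replace(record)
    if record.units == "kb":
        return replace(
            record,
            baseline_tl=None if record.baseline_tl is None else record.baseline_tl * 1000.0,
            followup_tl=None if record.followup_tl is None else record.followup_tl * 1000.0,
            units="bp",
        )
    if record.units == "TS":
        return replace(record, relative_units=True)
    raise CatalogSchemaError(f"unknown units {record.units!r}")
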