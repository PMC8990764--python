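"""Read and write tidy plot tables and the run configuration.

Plot tables are delimited text (tab by default), one row per plot x species,
with repeated NGLA assessments as date/value column pairs (``ngla_date_1``,
``ngla_value_1``, ...) folded into :class:`~mixtrial.model.AssessmentSeries`
at read time, and foot-disease class counts as ``fd_<pathogen>_<class>``
columns.  Missing values are encoded as empty fields.  ``"-"`` as a path means
stdin/stdout.
"""

from __future__ import annotations

import datetime as dt
import io as _io
import re
import sys
from typing import Iterable, Optional

import pandas as pd
import yaml

from .model import (
    FOOT_PATHOGENS,
    AssessmentSeries,
    PlotRecord,
    SchemaError,
    TrialDesign,
    ValidationError,
)

MANDATORY_COLUMNS = (
    "season", "block", "main_plot_id", "system", "entry", "species",
)

SCALAR_COLUMNS = (
    "grain_yield", "raw_moisture", "total_biomass", "ears_per_m2",
    "kernels_per_ear", "tgw", "protein", "gluten", "water_content",
    "sedimentation", "hectoliter_weight", "weed_cover", "lodging",
    "emergence_count", "survival_count",
)

DATE_COLUMNS = ("sowing_date", "heading_date")

_NGLA_DATE_RE = re.compile(r"^ngla_date_(\d+)$")


def _ngla_columns(n: int) -> list[str]:
    cols: list[str] = []
    for i in range(1, n + 1):
        cols += [f"ngla_date_{i}", f"ngla_value_{i}", f"ngla_cause_{i}"]
    return cols


def _fd_columns() -> list[str]:
    return [f"fd_{p}_{c}" for p in FOOT_PATHOGENS for c in range(4)]


def table_columns(n_ngla: int = 2) -> list[str]:
    """Stable column order of the plot table."""
    return (list(MANDATORY_COLUMNS) + list(SCALAR_COLUMNS)
            + list(DATE_COLUMNS) + _ngla_columns(n_ngla) + _fd_columns())


def _fmt(value) -> str:
    if value is None:
        return ""
    # str() of a float is the shortest exactly round-tripping representation
    return str(value)


def record_to_row(rec: PlotRecord, n_ngla: int) -> dict:
    row = {
        "season": rec.season,
        "block": str(rec.block),
        "main_plot_id": rec.main_plot_id,
        "system": rec.system,
        "entry": rec.entry or "",
        "species": rec.species,
    }
    for c in SCALAR_COLUMNS:
        row[c] = _fmt(getattr(rec, c))
    for c in DATE_COLUMNS:
        v = getattr(rec, c)
        row[c] = v.isoformat() if v is not None else ""
    series = rec.ngla_series
    for i in range(1, n_ngla + 1):
        if series is not None and i <= len(series):
            row[f"ngla_date_{i}"] = series.dates[i - 1].isoformat()
            row[f"ngla_value_{i}"] = _fmt(series.values[i - 1])
            row[f"ngla_cause_{i}"] = (
                series.causes[i - 1] if series.causes else ""
            )
        else:
            row[f"ngla_date_{i}"] = row[f"ngla_value_{i}"] = ""
            row[f"ngla_cause_{i}"] = ""
    fd = rec.foot_disease_counts or {}
    for p in FOOT_PATHOGENS:
        counts = fd.get(p)
        for c in range(4):
            row[f"fd_{p}_{c}"] = "" if counts is None else str(int(counts[c]))
    return row


def _parse_float(text: str, column: str, line: int) -> Optional[float]:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(
            f"row {line}: column {column!r}: {text!r} is not a number"
        ) from exc


def _parse_date(text: str, column: str, line: int) -> Optional[dt.date]:
    if text == "":
        return None
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise ValidationError(
            f"row {line}: column {column!r}: {text!r} is not an ISO date"
        ) from exc


def row_to_record(row: dict, line: int) -> PlotRecord:
    try:
        block = int(row["block"])
    except ValueError as exc:
        raise ValidationError(
            f"row {line}: block {row['block']!r} is not an integer"
        ) from exc
    kwargs = {
        "season": row["season"],
        "block": block,
        "main_plot_id": row["main_plot_id"],
        "system": row["system"],
        "entry": row["entry"] or None,
        "species": row["species"],
    }
    for c in SCALAR_COLUMNS:
        kwargs[c] = _parse_float(row.get(c, ""), c, line)
    for c in DATE_COLUMNS:
        kwargs[c] = _parse_date(row.get(c, ""), c, line)

    dates, values, causes = [], [], []
    i = 1
    while f"ngla_date_{i}" in row:
        d = _parse_date(row[f"ngla_date_{i}"], f"ngla_date_{i}", line)
        v = _parse_float(row.get(f"ngla_value_{i}", ""), f"ngla_value_{i}",
                         line)
        if d is not None and v is not None:
            dates.append(d)
            values.append(v)
            causes.append(row.get(f"ngla_cause_{i}", ""))
        i += 1
    if dates:
        kwargs["ngla_series"] = AssessmentSeries(
            tuple(dates), tuple(values),
            tuple(causes) if any(causes) else None,
        )

    fd = {}
    for p in FOOT_PATHOGENS:
        cells = [row.get(f"fd_{p}_{c}", "") for c in range(4)]
        if all(cell != "" for cell in cells):
            fd[p] = tuple(int(float(cell)) for cell in cells)
    if fd:
        kwargs["foot_disease_counts"] = fd
    return PlotRecord(**kwargs)


def write_plot_table(records: Iterable[PlotRecord], path, sep: str = "\t"):
    """Write records as delimited text; returns the path."""
    records = list(records)
    n_ngla = max(
        (len(r.ngla_series) for r in records if r.ngla_series is not None),
        default=2,
    )
    cols = table_columns(n_ngla)
    rows = [record_to_row(r, n_ngla) for r in records]
    frame = pd.DataFrame(rows, columns=cols, dtype=str)
    if path == "-":
        frame.to_csv(sys.stdout, sep=sep, index=False)
    else:
        frame.to_csv(path, sep=sep, index=False)
    return path


def read_plot_table(path, design: Optional[TrialDesign] = None,
                    sep: str = "\t") -> list[PlotRecord]:
    """Read and validate a plot table.

    Every row is validated against the record invariants and, when a design is
    given, against its factor levels; errors carry the offending row number
    (header = line 1, first data row = line 2).
    """
    source = sys.stdin if path == "-" else path
    frame = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"plot table is missing mandatory column(s): {', '.join(missing)}"
        )
    records = []
    for idx, row in enumerate(frame.to_dict(orient="records")):
        line = idx + 2
        rec = row_to_record(row, line)
        try:
            rec.validate(design)
        except ValidationError as exc:
            raise ValidationError(f"row {line}: {exc}") from exc
        records.append(rec)
    return records


def records_to_frame(records: Iterable[PlotRecord]) -> pd.DataFrame:
    """Flat DataFrame view (scalar fields only) for quick inspection."""
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in MANDATORY_COLUMNS + SCALAR_COLUMNS}
        rows.append(d)
    return pd.DataFrame(rows)


def read_config(path) -> dict:
    """Load the YAML run configuration (densities, CI level, thresholds, seeds)."""
    if path == "-":
        return yaml.safe_load(sys.stdin) or {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config(config: dict, path) -> None:
    text = yaml.safe_dump(config, sort_keys=False)
    if path == "-":
        sys.stdout.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
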