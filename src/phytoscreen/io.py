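"""Plate data model and CSV readers/writers.

The pipeline exchanges three long-format (tidy) CSV dialects, all UTF-8,
comma-separated, dot-decimal:

``plate_map.csv``
    ``plate_id,row,col,role,standard_conc,sample_id`` — one row per well.
    ``role`` is one of blank, standard, untreated_control, stress_control,
    positive_control, treatment. ``standard_conc`` is present exactly when
    the role is standard (mg/L for gallic acid, µmol/L for Trolox);
    ``sample_id`` exactly when the role is treatment or positive_control.

``measurements.csv``
    ``plate_id,row,col,assay,time_min,value`` — one row per reading.
    ``time_min`` is required for kinetic assays (frap, ros_dcf) and empty
    for endpoint assays.

``results.csv``
    One row per extract with the fixed column order of
    :data:`RESULT_COLUMNS`; missing optional values are empty strings,
    never sentinel numbers.

Wells are identified by plate id, row letter A–H and column number 1–12
(96-well convention); there is no 0-based indexing anywhere.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    DuplicateWellError,
    FormatError,
    OrphanWellError,
    ScheduleError,
)

ROLES = frozenset(
    {
        "blank",
        "standard",
        "untreated_control",
        "stress_control",
        "positive_control",
        "treatment",
    }
)
ASSAYS = frozenset({"tpc", "frap", "ros_dcf", "no_griess", "viability"})
#: Assays whose wells carry a time course rather than a single read.
KINETIC_ASSAYS = frozenset({"frap", "ros_dcf"})

ROWS = "ABCDEFGH"

#: Fixed column order of results.csv.
RESULT_COLUMNS = (
    "extract_id",
    "tpc_gae_mg_L",
    "frap_te_umol_L",
    "ros_pct",
    "ros_sd",
    "no_pct",
    "no_sd",
    "viability_caco2_pct",
    "viability_raw_pct",
    "excluded_ros",
    "excluded_no",
    "sig_ros",
    "sig_no",
    "reduction30_ros",
    "reduction30_no",
    "selectivity",
)

SELECTIVITY_CLASSES = frozenset(
    {"dual", "no_selective", "ros_selective", "unclassified", "excluded"}
)


@dataclass(frozen=True, order=True)
class WellAddress:
    """A single well on a named 96-well plate (row A–H, column 1–12)."""

    plate_id: str
    row: str
    col: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise FormatError(f"well row must be one of {ROWS!r}, got {self.row!r}")
        if not (1 <= int(self.col) <= 12):
            raise FormatError(f"well column must be 1-12, got {self.col!r}")

    def __str__(self) -> str:  # e.g. "P1:A1"
        return f"{self.plate_id}:{self.row}{self.col}"


@dataclass(frozen=True)
class WellRole:
    """What a well contains: its role plus the conditionally required fields."""

    role: str
    standard_conc: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FormatError(f"unknown well role {self.role!r}")
        if self.role == "standard":
            if self.standard_conc is None:
                raise FormatError("standard wells require standard_conc")
            if self.standard_conc < 0:
                raise FormatError("standard_conc must be non-negative")
        elif self.standard_conc is not None:
            raise FormatError(f"standard_conc given for role {self.role!r}")
        needs_sample = self.role in ("treatment", "positive_control")
        if needs_sample and not self.sample_id:
            raise FormatError(f"role {self.role!r} requires sample_id")
        if not needs_sample and self.sample_id:
            raise FormatError(f"sample_id given for role {self.role!r}")


@dataclass(frozen=True)
class WellMeasurement:
    """One plate-reader reading joined to its well role."""

    address: WellAddress
    role: WellRole
    assay: str
    value: float
    time_min: float | None = None


@dataclass
class MeasurementTable:
    """All readings of one assay, canonically sorted, with run metadata.

    ``frame`` holds one row per reading with columns
    ``plate_id,row,col,role,standard_conc,sample_id,assay,time_min,value``,
    sorted by plate, row, column, time so that parsing is order-independent.
    """

    frame: pd.DataFrame
    assay: str
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def wells(self) -> list[WellMeasurement]:
        out = []
        for r in self.frame.itertuples(index=False):
            addr = WellAddress(r.plate_id, r.row, int(r.col))
            conc = None if pd.isna(r.standard_conc) else float(r.standard_conc)
            sid = None if pd.isna(r.sample_id) else str(r.sample_id)
            role = WellRole(r.role, conc, sid)
            t = None if pd.isna(r.time_min) else float(r.time_min)
            out.append(WellMeasurement(addr, role, self.assay, float(r.value), t))
        return out


def _parse_float(text: str, *, where: str) -> float:
    try:
        v = float(text)
    except ValueError as exc:
        raise FormatError(f"non-numeric value {text!r} at {where}") from exc
    if not math.isfinite(v):
        raise FormatError(f"non-finite value {text!r} at {where}")
    return v


def read_plate_map(path) -> dict[WellAddress, WellRole]:
    """Read a plate-map CSV into a mapping of well address to role.

    Raises
    ------
    FormatError
        On a missing header, unknown role or malformed field (the message
        names the offending row number).
    DuplicateWellError
        If the same address appears twice.
    """
    expected = ["plate_id", "row", "col", "role", "standard_conc", "sample_id"]
    mapping: dict[WellAddress, WellRole] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != expected:
            raise FormatError(
                f"plate map header must be {','.join(expected)}, got {header!r}"
            )
        for lineno, rec in enumerate(reader, start=2):
            if not rec or all(not f.strip() for f in rec):
                continue
            if len(rec) != 6:
                raise FormatError(f"line {lineno}: expected 6 fields, got {len(rec)}")
            plate_id, row, col, role, conc, sample = (f.strip() for f in rec)
            try:
                address = WellAddress(plate_id, row, int(col))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad column {col!r}") from exc
            try:
                wr = WellRole(
                    role,
                    _parse_float(conc, where=f"line {lineno}") if conc else None,
                    sample or None,
                )
            except FormatError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            if address in mapping:
                raise DuplicateWellError(
                    f"line {lineno}: duplicate well address {address}"
                )
            mapping[address] = wr
    return mapping


def read_measurements(
    path,
    plate_map: Mapping[WellAddress, WellRole],
    *,
    read_schedule: Sequence[float] = (0, 15, 30, 60, 90),
    metadata: dict | None = None,
) -> MeasurementTable:
    """Read a long-format measurement CSV and join each reading to its role.

    Kinetic ``ros_dcf`` wells are verified against ``read_schedule``: the
    set of time points per well must equal the schedule exactly.

    Raises
    ------
    OrphanWellError
        For an address not covered by the plate map.
    FormatError
        Non-numeric values, mixed assays in one file, bad header.
    ScheduleError
        A ros_dcf well with missing/extra scheduled time points.
    """
    expected = ["plate_id", "row", "col", "assay", "time_min", "value"]
    records: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != expected:
            raise FormatError(
                f"measurements header must be {','.join(expected)}, got {header!r}"
            )
        for lineno, rec in enumerate(reader, start=2):
            if not rec or all(not f.strip() for f in rec):
                continue
            if len(rec) != 6:
                raise FormatError(f"line {lineno}: expected 6 fields, got {len(rec)}")
            plate_id, row, col, assay, time_min, value = (f.strip() for f in rec)
            if assay not in ASSAYS:
                raise FormatError(f"line {lineno}: unknown assay {assay!r}")
            try:
                address = WellAddress(plate_id, row, int(col))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"line {lineno}: bad address: {exc}") from exc
            if address not in plate_map:
                raise OrphanWellError(
                    f"line {lineno}: well {address} absent from plate map"
                )
            role = plate_map[address]
            records.append(
                {
                    "plate_id": plate_id,
                    "row": row,
                    "col": int(col),
                    "role": role.role,
                    "standard_conc": role.standard_conc,
                    "sample_id": role.sample_id,
                    "assay": assay,
                    "time_min": _parse_float(time_min, where=f"line {lineno}")
                    if time_min
                    else None,
                    "value": _parse_float(value, where=f"line {lineno}"),
                }
            )

    frame = pd.DataFrame(
        records,
        columns=[
            "plate_id",
            "row",
            "col",
            "role",
            "standard_conc",
            "sample_id",
            "assay",
            "time_min",
            "value",
        ],
    )
    if frame.empty:
        return MeasurementTable(frame, assay="", metadata=metadata or {})
    assays = frame["assay"].unique()
    if len(assays) > 1:
        raise FormatError(f"one assay per file required, found {sorted(assays)}")
    assay = assays[0]
    if assay == "ros_dcf":
        want = set(float(t) for t in read_schedule)
        for (pid, row, col), grp in frame.groupby(["plate_id", "row", "col"]):
            got = set(grp["time_min"].astype(float))
            if got != want:
                missing = sorted(want - got)
                extra = sorted(got - want)
                raise ScheduleError(
                    f"well {pid}:{row}{col} times {sorted(got)} do not match "
                    f"schedule {sorted(want)} (missing {missing}, extra {extra})"
                )
    frame = frame.sort_values(
        ["plate_id", "row", "col", "time_min"], kind="mergesort"
    ).reset_index(drop=True)
    meta = dict(metadata or {})
    meta.setdefault("read_schedule", list(read_schedule))
    return MeasurementTable(frame, assay=assay, metadata=meta)


@dataclass
class ExtractResult:
    """Per-extract summary across all five assays (one results.csv row)."""

    extract_id: str
    tpc_gae_mg_L: float | None = None
    frap_te_umol_L: float | None = None
    ros_pct: float | None = None
    ros_sd: float | None = None
    no_pct: float | None = None
    no_sd: float | None = None
    viability_caco2_pct: float | None = None
    viability_raw_pct: float | None = None
    excluded_ros: bool | None = None
    excluded_no: bool | None = None
    sig_ros: str | None = None  # decrease / increase / none
    sig_no: str | None = None
    reduction30_ros: bool | None = None
    reduction30_no: bool | None = None
    selectivity: str | None = None


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # repr round-trips exactly
    return str(value)


def _parse_opt_float(text: str) -> float | None:
    return None if text == "" else float(text)


def _parse_opt_bool(text: str) -> bool | None:
    if text == "":
        return None
    if text not in ("true", "false"):
        raise FormatError(f"expected true/false, got {text!r}")
    return text == "true"


def write_results(results: Iterable[ExtractResult], path) -> None:
    """Write extract results as CSV in the fixed documented column order.

    Floats are written with ``repr`` so that re-reading reproduces every
    numeric value bit-for-bit; missing values are empty strings.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for res in results:
            if res.selectivity is not None and res.selectivity not in SELECTIVITY_CLASSES:
                raise FormatError(f"invalid selectivity class {res.selectivity!r}")
            writer.writerow([_fmt(getattr(res, c)) for c in RESULT_COLUMNS])


def read_results(path) -> list[ExtractResult]:
    """Inverse of :func:`write_results`."""
    floats = {
        "tpc_gae_mg_L",
        "frap_te_umol_L",
        "ros_pct",
        "ros_sd",
        "no_pct",
        "no_sd",
        "viability_caco2_pct",
        "viability_raw_pct",
    }
    bools = {"excluded_ros", "excluded_no", "reduction30_ros", "reduction30_no"}
    out: list[ExtractResult] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != list(RESULT_COLUMNS):
            raise FormatError(f"unexpected results header {reader.fieldnames!r}")
        for rec in reader:
            kwargs: dict = {"extract_id": rec["extract_id"]}
            for col in RESULT_COLUMNS[1:]:
                text = rec[col]
                if col in floats:
                    kwargs[col] = _parse_opt_float(text)
                elif col in bools:
                    kwargs[col] = _parse_opt_bool(text)
                else:
                    kwargs[col] = text or None
            out.append(ExtractResult(**kwargs))
    return out
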