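"""Domain types for admission episodes and patient-day records, with CSV I/O.

The interchange dialect is fixed: UTF-8, comma-delimited, one header row,
ISO-8601 dates, empty string = missing. Missing vitals are carried as ``None``
on the dataclasses (``NaN`` in DataFrame form) and are never silently coerced
to zero — zero-filling is a preprocessing decision, not a parsing one.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DISEASE_CATEGORIES = ("CVA", "Dementia", "Cancer", "Others")

EPISODE_COLUMNS = [
    "patient_id", "admission_date", "discharge_date", "disease_category",
    "is_psychiatric", "is_demo", "is_reh", "hhc_label", "hhc_date",
]
# `age` is an optional trailing column (episode-level demographic used as a
# model feature); readers accept files with or without it.
EPISODE_COLUMNS_WITH_AGE = EPISODE_COLUMNS + ["age"]

DAY_COLUMNS = [
    "patient_id", "date", "respiratory_rate", "spo2", "oxygen_prescription",
    "body_temperature", "systolic_bp", "heart_rate", "cs_eye", "cs_vocal",
    "cs_motion", "pain", "bsrs", "nutrition", "cci_raw",
]

#: physiological vitals: missing values are linearly interpolated, never zero-filled
VITAL_FIELDS = ("respiratory_rate", "spo2", "body_temperature", "systolic_bp", "heart_rate")
#: consciousness sub-scales: interpolated then rounded back onto their integer scales
COMA_FIELDS = ("cs_eye", "cs_vocal", "cs_motion")
#: care-team / comorbidity indices: empty cells default to 0
ASSESSMENT_FIELDS = ("pain", "bsrs", "nutrition", "cci_raw")

_COMA_BOUNDS = {"cs_eye": (1, 4), "cs_vocal": (1, 5), "cs_motion": (1, 6)}
_INDEX_BOUNDS = {"pain": (0, 10), "bsrs": (0, 10), "nutrition": (0, 6)}


class SchemaError(ValueError):
    """Raised when a table violates the declared schema."""


class ValidationError(ValueError):
    """Raised when a parsed value is outside its declared domain."""


@dataclass
class AdmissionEpisode:
    """One hospital stay with disease category, flags and the HHC outcome."""

    patient_id: str
    admission_date: dt.date
    discharge_date: dt.date | None
    disease_category: str
    is_psychiatric: bool = False
    is_demo: bool = False
    is_reh: bool = False
    hhc_label: bool = False
    hhc_date: dt.date | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if self.disease_category not in DISEASE_CATEGORIES:
            raise SchemaError(
                f"unknown disease_category {self.disease_category!r}; "
                f"expected one of {DISEASE_CATEGORIES}"
            )
        if self.discharge_date is not None and self.discharge_date < self.admission_date:
            raise ValidationError(
                f"episode {self.patient_id}: discharge_date {self.discharge_date} "
                f"before admission_date {self.admission_date}"
            )
        if self.hhc_label != (self.hhc_date is not None):
            raise ValidationError(
                f"episode {self.patient_id}: hhc_date must be present iff hhc_label is set"
            )
        if self.hhc_date is not None:
            hi = self.discharge_date
            if self.hhc_date < self.admission_date or (hi is not None and self.hhc_date > hi):
                raise ValidationError(
                    f"episode {self.patient_id}: hhc_date {self.hhc_date} outside stay"
                )


@dataclass
class PatientDayRecord:
    """One patient-day of vitals, coma sub-scales and care-team indices.

    Any vital field may be ``None`` (missing) before preprocessing.
    """

    patient_id: str
    date: dt.date
    respiratory_rate: float | None = None
    spo2: float | None = None
    oxygen_prescription: bool | None = None
    body_temperature: float | None = None
    systolic_bp: float | None = None
    heart_rate: float | None = None
    cs_eye: int | None = None
    cs_vocal: int | None = None
    cs_motion: int | None = None
    pain: float | None = None
    bsrs: float | None = None
    nutrition: float | None = None
    cci_raw: float | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in _COMA_BOUNDS.items():
            v = getattr(self, name)
            if v is not None and not lo <= v <= hi:
                raise ValidationError(
                    f"{self.patient_id}@{self.date}: {name}={v} outside [{lo},{hi}]"
                )
        for name, (lo, hi) in _INDEX_BOUNDS.items():
            v = getattr(self, name)
            if v is not None and not lo <= v <= hi:
                raise ValidationError(
                    f"{self.patient_id}@{self.date}: {name}={v} outside [{lo},{hi}]"
                )
        if self.cci_raw is not None and self.cci_raw < 0:
            raise ValidationError(f"{self.patient_id}@{self.date}: cci_raw must be >= 0")


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_date(cell: str, row: int, col: str) -> dt.date | None:
    if cell == "":
        return None
    try:
        return dt.date.fromisoformat(cell)
    except ValueError:
        raise SchemaError(f"row {row}: malformed date {cell!r} in column {col}") from None


def _parse_flag(cell: str, row: int, col: str) -> bool:
    if cell not in ("0", "1"):
        raise SchemaError(f"row {row}: flag column {col} must be 0 or 1, got {cell!r}")
    return cell == "1"


def _parse_opt_float(cell: str) -> float | None:
    return None if cell == "" else float(cell)


def _parse_opt_int(cell: str, row: int, col: str) -> int | None:
    if cell == "":
        return None
    f = float(cell)
    if f != int(f):
        raise ValidationError(f"row {row}: column {col} must be an integer, got {cell!r}")
    return int(f)


def _read_table(path, expected: Sequence[str], optional_tail: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols != list(expected) and cols != list(expected) + list(optional_tail):
        raise SchemaError(f"{path}: header {cols} does not match declared schema {list(expected)}")
    return df


# ---------------------------------------------------------------------------
# episodes

def read_episodes(path) -> list[AdmissionEpisode]:
    """Read episodes.csv; one :class:`AdmissionEpisode` per row."""
    df = _read_table(path, EPISODE_COLUMNS, optional_tail=["age"])
    has_age = "age" in df.columns
    episodes: list[AdmissionEpisode] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pid = row.patient_id
        if pid in seen:
            raise SchemaError(f"row {i}: duplicate patient_id {pid!r}")
        seen.add(pid)
        episodes.append(
            AdmissionEpisode(
                patient_id=pid,
                admission_date=_parse_date(row.admission_date, i, "admission_date"),
                discharge_date=_parse_date(row.discharge_date, i, "discharge_date"),
                disease_category=row.disease_category,
                is_psychiatric=_parse_flag(row.is_psychiatric, i, "is_psychiatric"),
                is_demo=_parse_flag(row.is_demo, i, "is_demo"),
                is_reh=_parse_flag(row.is_reh, i, "is_reh"),
                hhc_label=_parse_flag(row.hhc_label, i, "hhc_label"),
                hhc_date=_parse_date(row.hhc_date, i, "hhc_date"),
                age=_parse_opt_float(row.age) if has_age else None,
            )
        )
    return episodes


def write_episodes(episodes: Iterable[AdmissionEpisode], path) -> None:
    rows = []
    for e in episodes:
        rows.append({
            "patient_id": e.patient_id,
            "admission_date": e.admission_date.isoformat(),
            "discharge_date": "" if e.discharge_date is None else e.discharge_date.isoformat(),
            "disease_category": e.disease_category,
            "is_psychiatric": int(e.is_psychiatric),
            "is_demo": int(e.is_demo),
            "is_reh": int(e.is_reh),
            "hhc_label": int(e.hhc_label),
            "hhc_date": "" if e.hhc_date is None else e.hhc_date.isoformat(),
            "age": "" if e.age is None else _fmt_num(e.age),
        })
    pd.DataFrame(rows, columns=EPISODE_COLUMNS_WITH_AGE).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# day records

def read_day_records(path) -> list[PatientDayRecord]:
    """Read days.csv; empty cells become ``None`` (missing), never zero."""
    df = _read_table(path, DAY_COLUMNS)
    records: list[PatientDayRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                PatientDayRecord(
                    patient_id=row.patient_id,
                    date=_parse_date(row.date, i, "date"),
                    respiratory_rate=_parse_opt_float(row.respiratory_rate),
                    spo2=_parse_opt_float(row.spo2),
                    oxygen_prescription=(
                        None if row.oxygen_prescription == ""
                        else _parse_flag(row.oxygen_prescription, i, "oxygen_prescription")
                    ),
                    body_temperature=_parse_opt_float(row.body_temperature),
                    systolic_bp=_parse_opt_float(row.systolic_bp),
                    heart_rate=_parse_opt_float(row.heart_rate),
                    cs_eye=_parse_opt_int(row.cs_eye, i, "cs_eye"),
                    cs_vocal=_parse_opt_int(row.cs_vocal, i, "cs_vocal"),
                    cs_motion=_parse_opt_int(row.cs_motion, i, "cs_motion"),
                    pain=_parse_opt_float(row.pain),
                    bsrs=_parse_opt_float(row.bsrs),
                    nutrition=_parse_opt_float(row.nutrition),
                    cci_raw=_parse_opt_float(row.cci_raw),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def _fmt_num(v) -> str:
    if v is None:
        return ""
    f = float(v)
    return str(int(f)) if f == int(f) else repr(f)


def write_day_records(records: Iterable[PatientDayRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "date": r.date.isoformat(),
            "respiratory_rate": _fmt_num(r.respiratory_rate),
            "spo2": _fmt_num(r.spo2),
            "oxygen_prescription": "" if r.oxygen_prescription is None else int(r.oxygen_prescription),
            "body_temperature": _fmt_num(r.body_temperature),
            "systolic_bp": _fmt_num(r.systolic_bp),
            "heart_rate": _fmt_num(r.heart_rate),
            "cs_eye": _fmt_num(r.cs_eye),
            "cs_vocal": _fmt_num(r.cs_vocal),
            "cs_motion": _fmt_num(r.cs_motion),
            "pain": _fmt_num(r.pain),
            "bsrs": _fmt_num(r.bsrs),
            "nutrition": _fmt_num(r.nutrition),
            "cci_raw": _fmt_num(r.cci_raw),
        })
    pd.DataFrame(rows, columns=DAY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DataFrame bridges (the pipeline's vectorized in-memory form)

def episodes_to_frame(episodes: Sequence[AdmissionEpisode]) -> pd.DataFrame:
    df = pd.DataFrame({
        "patient_id": [e.patient_id for e in episodes],
        "admission_date": [e.admission_date for e in episodes],
        "discharge_date": [e.discharge_date for e in episodes],
        "disease_category": [e.disease_category for e in episodes],
        "is_psychiatric": [e.is_psychiatric for e in episodes],
        "is_demo": [e.is_demo for e in episodes],
        "is_reh": [e.is_reh for e in episodes],
        "hhc_label": [e.hhc_label for e in episodes],
        "hhc_date": [e.hhc_date for e in episodes],
        "age": [np.nan if e.age is None else e.age for e in episodes],
    })
    return df


def frame_to_episodes(df: pd.DataFrame) -> list[AdmissionEpisode]:
    out = []
    for row in df.itertuples(index=False):
        age = getattr(row, "age", None)
        out.append(AdmissionEpisode(
            patient_id=row.patient_id,
            admission_date=_as_date(row.admission_date),
            discharge_date=_as_date(row.discharge_date),
            disease_category=row.disease_category,
            is_psychiatric=bool(row.is_psychiatric),
            is_demo=bool(row.is_demo),
            is_reh=bool(row.is_reh),
            hhc_label=bool(row.hhc_label),
            hhc_date=_as_date(row.hhc_date),
            age=None if age is None or (isinstance(age, float) and np.isnan(age)) else float(age),
        ))
    return out


def days_to_frame(records: Sequence[PatientDayRecord]) -> pd.DataFrame:
    cols: dict[str, list] = {c: [] for c in DAY_COLUMNS}
    for r in records:
        for c in DAY_COLUMNS:
            v = getattr(r, c)
            cols[c].append(v)
    df = pd.DataFrame(cols)
    for c in VITAL_FIELDS + COMA_FIELDS + ASSESSMENT_FIELDS:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["oxygen_prescription"] = df["oxygen_prescription"].map(
        lambda v: np.nan if v is None else float(bool(v))
    )
    return df


def frame_to_days(df: pd.DataFrame) -> list[PatientDayRecord]:
    def opt(v):
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    out = []
    for row in df.itertuples(index=False):
        o2 = opt(row.oxygen_prescription)
        out.append(PatientDayRecord(
            patient_id=row.patient_id,
            date=_as_date(row.date),
            respiratory_rate=opt(row.respiratory_rate),
            spo2=opt(row.spo2),
            oxygen_prescription=None if o2 is None else bool(o2),
            body_temperature=opt(row.body_temperature),
            systolic_bp=opt(row.systolic_bp),
            heart_rate=opt(row.heart_rate),
            cs_eye=None if opt(row.cs_eye) is None else int(row.cs_eye),
            cs_vocal=None if opt(row.cs_vocal) is None else int(row.cs_vocal),
            cs_motion=None if opt(row.cs_motion) is None else int(row.cs_motion),
            pain=opt(row.pain),
            bsrs=opt(row.bsrs),
            nutrition=opt(row.nutrition),
            cci_raw=opt(row.cci_raw),
        ))
    return out


def _as_date(v) -> dt.date | None:
    if v is None:
        return None
    if isinstance(v, float) and np.isnan(v):
        return None
    if isinstance(v, pd.Timestamp):
        return v.date()
    if isinstance(v, dt.datetime):
        return v.date()
    if isinstance(v, dt.date):
        return v
    if pd.isna(v):
        return None
    return dt.date.fromisoformat(str(v))
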