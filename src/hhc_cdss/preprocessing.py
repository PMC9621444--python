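"""Cleaning of daily medical records before scoring and feature encoding.

Three repairs run in a fixed single pass, per patient stay:

1. ``fill_null_fields`` — assessment/comorbidity fields (pain, BSRS, nutrition,
   CCI) default to 0 when empty; an empty oxygen-prescription flag becomes
   False.  Physiological vitals are never zero-filled: a temperature of 0 is a
   corruption, not a measurement.
2. ``interpolate_series`` — missing vitals are estimated by linear
   interpolation between the nearest recorded neighbours; gaps at the edges of
   a stay extend the nearest recorded value; an all-missing series falls back
   to the cohort mean of the field.
3. ``replace_outliers`` — a value deviating from the cohort field mean by more
   than two population standard deviations is treated as a recording error,
   blanked, and re-interpolated.  Field statistics are computed once, cohort
   wide, before any replacement (no iteration to a fixpoint).

Coma sub-scales interpolate like vitals but are rounded back onto their
integer scales; the two-SD rule applies to the continuous vitals only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records_io import ASSESSMENT_FIELDS, COMA_FIELDS, VITAL_FIELDS

_COMA_HI = {"cs_eye": 4, "cs_vocal": 5, "cs_motion": 6}


class StatisticsError(ValueError):
    """Raised when a field has too few observed cells for statistics."""


class InterpolationError(ValueError):
    """Raised when a series has no observed value to interpolate from."""


@dataclass(frozen=True)
class FieldStats:
    """Cohort-wide mean and population SD of one vital field."""

    field: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise StatisticsError(f"field {self.field!r}: need >= 2 observed cells, have {self.n}")


def compute_field_stats(days: pd.DataFrame,
                        fields: Sequence[str] = VITAL_FIELDS) -> dict[str, FieldStats]:
    """Mean and population SD over all non-missing cells of each vital column."""
    out: dict[str, FieldStats] = {}
    for f in fields:
        col = days[f].to_numpy(dtype=float)
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise StatisticsError(f"field {f!r} has no observed values")
        if obs.size < 2:
            raise StatisticsError(f"field {f!r}: need >= 2 observed cells, have {obs.size}")
        out[f] = FieldStats(field=f, mean=float(obs.mean()), sd=float(obs.std(ddof=0)), n=int(obs.size))
    return out


def interpolate_series(values: Sequence[float | None]) -> list[float]:
    """Fill missing entries of a daily series.

    Interior gaps take the straight line between the nearest observed
    neighbours; leading/trailing gaps extend the nearest observed value.
    """
    arr = np.array([np.nan if v is None else float(v) for v in values], dtype=float)
    mask = ~np.isnan(arr)
    if not mask.any():
        raise InterpolationError("cannot interpolate an all-missing series")
    idx = np.arange(arr.size)
    # np.interp clamps outside the observed range == nearest-value extension
    filled = np.interp(idx, idx[mask], arr[mask])
    return [float(v) for v in filled]


def replace_outliers(series: Sequence[float], stats: FieldStats) -> tuple[list[float], int]:
    """Blank values more than 2 population SDs from the field mean and re-fill.

    The deviation test is two-sided and strict (``|x - mean| > 2*sd``), so a
    zero-SD field flags any value that deviates at all.  Returns the repaired
    series and the replacement count.
    """
    arr = np.asarray(series, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("replace_outliers expects a complete series; interpolate first")
    flagged = np.abs(arr - stats.mean) > 2.0 * stats.sd
    n = int(flagged.sum())
    if n == 0:
        return [float(v) for v in arr], 0
    kept = arr.astype(object)
    for i in np.nonzero(flagged)[0]:
        kept[i] = None
    try:
        repaired = interpolate_series(list(kept))
    except InterpolationError:
        repaired = [stats.mean] * arr.size  # every value flagged: field mean fallback
    return repaired, n


def fill_null_fields(days: pd.DataFrame) -> pd.DataFrame:
    """Default empty assessment fields to 0 and empty oxygen flags to False."""
    out = days.copy()
    for f in ASSESSMENT_FIELDS:
        out[f] = out[f].fillna(0.0)
    out["oxygen_prescription"] = out["oxygen_prescription"].fillna(0.0)
    return out


def preprocess_cohort(days: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Run the full cleaning pass over a cohort day-record frame.

    Order: null fill -> per-stay interpolation of vitals and coma sub-scales ->
    cohort field statistics -> two-SD outlier replacement on continuous vitals.
    Returns the repaired frame (sorted by patient and date, no missing cells)
    and a report of per-field interpolation/replacement counts.
    """
    out = fill_null_fields(days)
    out = out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)

    series_fields = VITAL_FIELDS + COMA_FIELDS
    report = {
        "interpolated": {f: int(out[f].isna().sum()) for f in series_fields},
        "outliers_replaced": {},
        "mean_fallback": {f: 0 for f in series_fields},
    }

    cohort_means = {f: float(np.nanmean(out[f].to_numpy(float))) for f in series_fields}
    if any(math.isnan(m) for m in cohort_means.values()):
        empty = [f for f, m in cohort_means.items() if math.isnan(m)]
        raise StatisticsError(f"fields with no observed values: {empty}")

    groups = out.groupby("patient_id", sort=False).indices
    for f in series_fields:
        col = out[f].to_numpy(dtype=float)
        if not np.isnan(col).any():
            continue
        for pid, idx in groups.items():
            seg = col[idx]
            if not np.isnan(seg).any():
                continue
            if np.isnan(seg).all():
                col[idx] = cohort_means[f]
                report["mean_fallback"][f] += len(idx)
                continue
            pos = np.arange(seg.size)
            obs = ~np.isnan(seg)
            col[idx] = np.interp(pos, pos[obs], seg[obs])
        out[f] = col

    stats = compute_field_stats(out, VITAL_FIELDS)
    for f in VITAL_FIELDS:
        st = stats[f]
        col = out[f].to_numpy(dtype=float)
        flagged = np.abs(col - st.mean) > 2.0 * st.sd
        n_flagged = int(flagged.sum())
        report["outliers_replaced"][f] = n_flagged
        if n_flagged == 0:
            continue
        col[flagged] = np.nan
        for pid, idx in groups.items():
            seg = col[idx]
            if not np.isnan(seg).any():
                continue
            if np.isnan(seg).all():
                col[idx] = st.mean
            else:
                pos = np.arange(seg.size)
                obs = ~np.isnan(seg)
                col[idx] = np.interp(pos, pos[obs], seg[obs])
        out[f] = col

    for f in COMA_FIELDS:  # back onto the integer scale after interpolation
        out[f] = np.clip(np.round(out[f].to_numpy(float)), 1, _COMA_HI[f])

    report["field_stats"] = {
        f: {"mean": stats[f].mean, "sd": stats[f].sd, "n": stats[f].n} for f in VITAL_FIELDS
    }
    return out, report
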