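"""Feature construction for the sequence classifier.

Each patient-day becomes a fixed-length numeric vector:

* continuous block, min-max scaled to [0,1] with parameters fitted on the
  training split only: age, health score, body temperature, heart rate,
  respiratory rate, SpO2, systolic blood pressure;
* discrete block, raw: hospitalization days (``D_delta = DD - ED``, floored at
  1, using the running date while in stay), EWS, Coma Status, oxygen
  prescription as 0/1;
* categorical block: the disease category one-hot encoded over the closed
  vocabulary (CVA, Dementia, Cancer, Others).

Patient identifiers and admission timestamps are keys and window anchors, not
model inputs.  Windows are 8 consecutive in-stay days (the current day plus
the past 7); a window is labelled positive when the stay ends in an HHC
decision at most ``hhc_horizon`` days (default 14) after the window's end.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records_io import DISEASE_CATEGORIES, ValidationError

CONTINUOUS_FEATURES = ("age", "health_score", "body_temperature", "heart_rate",
                       "respiratory_rate", "spo2", "systolic_bp")
DISCRETE_FEATURES = ("d_delta", "ews", "cs_all", "oxygen_prescription")
FEATURE_NAMES = CONTINUOUS_FEATURES + DISCRETE_FEATURES + tuple(
    f"disease_{c}" for c in DISEASE_CATEGORIES)

WINDOW_LENGTH = 8


class EncodingError(ValueError):
    pass


class GapError(ValueError):
    """Raised when an episode's day records are not consecutive."""


@dataclass
class ScalingParams:
    """Per-feature (min, max) learned once from the training split."""

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def fit(cls, frame: pd.DataFrame,
            features: Sequence[str] = CONTINUOUS_FEATURES) -> "ScalingParams":
        ranges = {}
        for f in features:
            col = frame[f].to_numpy(dtype=float)
            ranges[f] = (float(np.min(col)), float(np.max(col)))
        return cls(ranges)

    def to_json(self) -> str:
        return json.dumps({k: list(v) for k, v in self.ranges.items()})

    @classmethod
    def from_json(cls, text: str) -> "ScalingParams":
        return cls({k: (float(v[0]), float(v[1])) for k, v in json.loads(text).items()})


def min_max_scale(x: float, params: tuple[float, float]) -> float:
    """``(x - min)/(max - min)``, clipped to [0,1]; degenerate range maps to 0."""
    lo, hi = params
    if hi < lo:
        raise ValueError(f"invalid scaling range ({lo}, {hi})")
    if hi == lo:
        return 0.0
    return float(np.clip((x - lo) / (hi - lo), 0.0, 1.0))


def hospitalization_days(admission_date: dt.date, current_or_discharge_date: dt.date) -> int:
    """Whole days since admission, floored at 1."""
    if current_or_discharge_date < admission_date:
        raise ValidationError(
            f"date {current_or_discharge_date} precedes admission {admission_date}")
    return max(1, (current_or_discharge_date - admission_date).days)


def encode_categorical(value: str, vocabulary: Sequence[str]) -> str:
    """One-hot bit string over *vocabulary* in order, e.g. ``'0010'``."""
    if value not in vocabulary:
        raise EncodingError(f"value {value!r} not in vocabulary {list(vocabulary)}")
    return "".join("1" if v == value else "0" for v in vocabulary)


@dataclass
class FeatureWindow:
    """8 consecutive encoded day-vectors with the window's HHC label."""

    patient_id: str
    end_date: dt.date
    x: np.ndarray  # (8, n_features)
    label: int

    def __post_init__(self) -> None:
        if self.x.shape[0] != WINDOW_LENGTH:
            raise ValueError(f"window must have {WINDOW_LENGTH} steps, got {self.x.shape[0]}")


def encode_day_features(days: pd.DataFrame, scores: pd.DataFrame,
                        episodes: pd.DataFrame,
                        scaling: ScalingParams | None) -> pd.DataFrame:
    """One encoded feature row per patient-day (days and scores row-aligned).

    With ``scaling=None`` the continuous block is left on its raw scale —
    the form :meth:`ScalingParams.fit` consumes when learning the training
    split's ranges.
    """
    epi = episodes.set_index("patient_id")
    out = pd.DataFrame({
        "patient_id": days["patient_id"].to_numpy(),
        "date": days["date"].to_numpy(),
    })
    raw = {
        "age": out["patient_id"].map(epi["age"]).to_numpy(float),
        "health_score": scores["health_score"].to_numpy(float),
        "body_temperature": days["body_temperature"].to_numpy(float),
        "heart_rate": days["heart_rate"].to_numpy(float),
        "respiratory_rate": days["respiratory_rate"].to_numpy(float),
        "spo2": days["spo2"].to_numpy(float),
        "systolic_bp": days["systolic_bp"].to_numpy(float),
    }
    for f in CONTINUOUS_FEATURES:
        col = raw[f]
        if scaling is None:
            out[f] = col
            continue
        lo, hi = scaling.ranges[f]
        out[f] = 0.0 if hi == lo else np.clip((col - lo) / (hi - lo), 0.0, 1.0)

    admission = out["patient_id"].map(epi["admission_date"])
    d_delta = (pd.to_datetime(out["date"]) - pd.to_datetime(admission)).dt.days
    out["d_delta"] = np.maximum(1, d_delta.to_numpy())
    out["ews"] = scores["ews"].to_numpy(float)
    out["cs_all"] = scores["cs_all"].to_numpy(float)
    out["oxygen_prescription"] = days["oxygen_prescription"].to_numpy(float)

    disease = out["patient_id"].map(epi["disease_category"]).to_numpy()
    for c in DISEASE_CATEGORIES:
        out[f"disease_{c}"] = (disease == c).astype(float)
    return out


def build_windows(day_features: pd.DataFrame, episode,
                  hhc_horizon: int = 14) -> list[FeatureWindow]:
    """Assemble the 8-day windows of one episode.

    One window per in-stay day with at least 7 preceding in-stay days; for HHC
    episodes no window extends past the HHC date, and a window is positive iff
    it ends within *hhc_horizon* days before the HHC decision.
    """
    feats = day_features.sort_values("date", kind="stable")
    dates = [_date(d) for d in feats["date"]]
    for prev, cur in zip(dates, dates[1:]):
        if (cur - prev).days != 1:
            raise GapError(f"{episode.patient_id}: non-consecutive day records at {cur}")
    x = feats[list(FEATURE_NAMES)].to_numpy(dtype=float)

    hhc_date = episode.hhc_date if episode.hhc_label else None
    windows: list[FeatureWindow] = []
    for end in range(WINDOW_LENGTH - 1, len(dates)):
        end_date = dates[end]
        if hhc_date is not None and end_date > hhc_date:
            break
        if hhc_date is not None:
            delta = (hhc_date - end_date).days
            label = int(0 <= delta <= hhc_horizon)
        else:
            label = 0
        windows.append(FeatureWindow(
            patient_id=episode.patient_id, end_date=end_date,
            x=x[end - WINDOW_LENGTH + 1: end + 1].copy(), label=label))
    return windows


def build_cohort_windows(day_features: pd.DataFrame, episodes: pd.DataFrame,
                         hhc_horizon: int = 14) -> list[FeatureWindow]:
    """Windows for every episode of a cohort (episodes without 8 days yield none)."""
    from .records_io import frame_to_episodes

    by_pid = {pid: grp for pid, grp in day_features.groupby("patient_id", sort=False)}
    windows: list[FeatureWindow] = []
    for ep in frame_to_episodes(episodes):
        grp = by_pid.get(ep.patient_id)
        if grp is None or len(grp) < WINDOW_LENGTH:
            continue
        windows.extend(build_windows(grp, ep, hhc_horizon))
    return windows


def windows_to_frame(windows: Sequence[FeatureWindow]) -> pd.DataFrame:
    """Flatten windows to one row per (patient_id, end_date) for CSV export."""
    cols = {}
    for t in range(WINDOW_LENGTH):
        for j, f in enumerate(FEATURE_NAMES):
            cols[f"t{t - WINDOW_LENGTH + 1}_{f}"] = [w.x[t, j] for w in windows]
    return pd.DataFrame({
        "patient_id": [w.patient_id for w in windows],
        "end_date": [w.end_date for w in windows],
        **cols,
        "label": [w.label for w in windows],
    })


def schema_json() -> str:
    """Feature order and categorical vocabulary, for interchange."""
    return json.dumps({
        "window_length": WINDOW_LENGTH,
        "features": list(FEATURE_NAMES),
        "disease_vocabulary": list(DISEASE_CATEGORIES),
    }, indent=2)


def _date(v) -> dt.date:
    if isinstance(v, pd.Timestamp):
        return v.date()
    if isinstance(v, dt.datetime):
        return v.date()
    return v
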