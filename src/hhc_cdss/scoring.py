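"""Daily health-status scoring.

Four quantities are computed per patient-day, post-preprocessing:

* **Coma Status** ``cs_all = cs_eye + cs_vocal + cs_motion`` — the Glasgow-style
  consciousness sum, 15 = fully conscious.
* **Early Warning Score (EWS)** — an integer 0–20 summing seven bin scores over
  routine bedside measurements (respiration, SpO2, oxygen prescription,
  temperature, systolic blood pressure, heart rate, Coma Status).
* **TeamEval** — the care team's wellness composite
  ``pain*R_pain + bsrs*R_bsrs + nutrition*R_nutrition``.
* **HealthScore** — the disease-weighted combination
  ``TeamEval*W_TeamEval + min(B,20)*R_cci*W_CCI + min(C,20)*R_ews*W_EWS``
  where B is the Charlson Comorbidity Index and C the EWS.

Continuous bins are closed at the recording precision: integer parameters use
gap-free integer ranges; temperature bins close on tenths of a degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .records_io import DISEASE_CATEGORIES, ValidationError

#: default disease weight triples (w_teameval, w_cci, w_ews).
#: The Dementia row sums to 0.99 as published; no sum-to-one constraint applies.
DEFAULT_WEIGHTS = {
    "CVA": (0.37, 0.34, 0.29),
    "Dementia": (0.7, 0.19, 0.10),
    "Cancer": (0.61, 0.19, 0.20),
    "Others": (0.10, 0.80, 0.10),
}

# EWS bin edges, one row per physiological parameter.  Each entry is
# (upper_bound_inclusive, score); bounds scanned in order, last is +inf.
# Integer parameters are binned on the nearest integer; temperature on the
# nearest tenth of a degree.
_EWS_BINS = {
    "respiratory_rate": [(8, 3), (11, 1), (20, 0), (24, 2), (np.inf, 3)],
    "spo2": [(91, 3), (93, 2), (95, 1), (np.inf, 0)],
    "body_temperature": [(35.0, 3), (36.0, 1), (38.0, 0), (39.0, 1), (np.inf, 2)],
    "systolic_bp": [(90, 3), (100, 2), (110, 1), (219, 0), (np.inf, 3)],
    "heart_rate": [(40, 3), (50, 1), (90, 0), (110, 1), (130, 2), (np.inf, 3)],
    "coma_status": [(14, 3), (np.inf, 0)],
}
_INTEGER_PARAMS = ("respiratory_rate", "spo2", "systolic_bp", "heart_rate", "coma_status")
EWS_PARAMETERS = tuple(_EWS_BINS) + ("oxygen_prescription",)

EWS_MAX = 20  # per-row maxima 3+3+2+3+3+3+3


@dataclass
class ScoringConfig:
    """All scoring constants: index ratios, the cap, disease weights, EWS bins."""

    r_pain: float = 5.0
    r_bsrs: float = 5.0
    r_nutrition: float = 30.0
    r_cci: float = 5.0
    r_ews: float = 5.0
    cap: float = 20.0
    weights: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )

    def __post_init__(self) -> None:
        for r in (self.r_pain, self.r_bsrs, self.r_nutrition, self.r_cci, self.r_ews):
            if r < 0:
                raise ValueError("scoring ratios must be non-negative")
        for cat, triple in self.weights.items():
            if len(triple) != 3 or any(w < 0 for w in triple):
                raise ValueError(f"weight triple for {cat!r} must be 3 non-negative numbers")

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "r_pain": self.r_pain, "r_bsrs": self.r_bsrs, "r_nutrition": self.r_nutrition,
            "r_cci": self.r_cci, "r_ews": self.r_ews, "cap": self.cap,
            "weights": {k: list(v) for k, v in self.weights.items()},
        }, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScoringConfig":
        raw = yaml.safe_load(text) or {}
        if "weights" in raw:
            raw["weights"] = {k: tuple(v) for k, v in raw["weights"].items()}
        return cls(**raw)


def coma_status(cs_eye: int, cs_vocal: int, cs_motion: int) -> int:
    """Sum the eye/vocal/motion consciousness sub-scales (range 3–15)."""
    for name, v, hi in (("cs_eye", cs_eye, 4), ("cs_vocal", cs_vocal, 5), ("cs_motion", cs_motion, 6)):
        if not 1 <= v <= hi:
            raise ValidationError(f"{name}={v} outside [1,{hi}]")
    return int(cs_eye) + int(cs_vocal) + int(cs_motion)


def ews_component(parameter: str, value) -> int:
    """Score one physiological parameter on its 0–3 early-warning bin."""
    if parameter == "oxygen_prescription":
        return 2 if bool(value) else 0
    if parameter not in _EWS_BINS:
        raise KeyError(f"unknown EWS parameter {parameter!r}")
    x = float(value)
    if parameter in _INTEGER_PARAMS:
        x = round(x)
    else:  # temperature recorded to a tenth of a degree
        x = round(x, 1)
    for upper, score in _EWS_BINS[parameter]:
        if x <= upper:
            return score
    raise AssertionError("unreachable: final bin is unbounded")


def early_warning_score(
    respiratory_rate: float, spo2: float, oxygen_prescription: bool,
    body_temperature: float, systolic_bp: float, heart_rate: float,
    cs_all: int,
) -> int:
    """Sum the seven early-warning components for one patient-day (0–20)."""
    return (
        ews_component("respiratory_rate", respiratory_rate)
        + ews_component("spo2", spo2)
        + ews_component("oxygen_prescription", oxygen_prescription)
        + ews_component("body_temperature", body_temperature)
        + ews_component("systolic_bp", systolic_bp)
        + ews_component("heart_rate", heart_rate)
        + ews_component("coma_status", cs_all)
    )


def team_eval(pain: float, bsrs: float, nutrition: float,
              config: ScoringConfig | None = None) -> float:
    """Care-team wellness composite: pain, distress and nutrition with fixed ratios."""
    config = config or ScoringConfig()
    if not 0 <= pain <= 10 or not 0 <= bsrs <= 10 or not 0 <= nutrition <= 6:
        raise ValidationError(
            f"team_eval indices out of bounds: pain={pain}, bsrs={bsrs}, nutrition={nutrition}"
        )
    return pain * config.r_pain + bsrs * config.r_bsrs + nutrition * config.r_nutrition


def health_score(team_eval_score: float, cci_raw: float, ews: float,
                 disease_category: str, config: ScoringConfig | None = None) -> float:
    """Disease-weighted health score from TeamEval, capped CCI and capped EWS."""
    config = config or ScoringConfig()
    if team_eval_score < 0 or cci_raw < 0 or ews < 0:
        raise ValidationError("health_score inputs must be non-negative")
    try:
        w_te, w_cci, w_ews = config.weights[disease_category]
    except KeyError:
        raise KeyError(f"no weight triple for disease {disease_category!r}") from None
    return (
        team_eval_score * w_te
        + min(cci_raw, config.cap) * config.r_cci * w_cci
        + min(ews, config.cap) * config.r_ews * w_ews
    )


# ---------------------------------------------------------------------------
# vectorized cohort scoring

def _ews_column(parameter: str, values: np.ndarray) -> np.ndarray:
    bins = _EWS_BINS[parameter]
    x = np.round(values) if parameter in _INTEGER_PARAMS else np.round(values, 1)
    out = np.full(x.shape, bins[-1][1], dtype=np.int64)
    for upper, score in reversed(bins[:-1]):
        out = np.where(x <= upper, score, out)
    return out


def score_days(days: pd.DataFrame, episodes: pd.DataFrame,
               config: ScoringConfig | None = None) -> pd.DataFrame:
    """Score every patient-day of a preprocessed cohort.

    Returns a frame ``patient_id, date, cs_all, ews, team_eval, health_score``
    aligned row-for-row with *days*.
    """
    config = config or ScoringConfig()
    if days[["respiratory_rate", "spo2", "body_temperature", "systolic_bp",
             "heart_rate", "cs_eye", "cs_vocal", "cs_motion"]].isna().any().any():
        raise ValidationError("score_days requires preprocessed (complete) records")

    cs_all = (
        days["cs_eye"].to_numpy(dtype=np.int64)
        + days["cs_vocal"].to_numpy(dtype=np.int64)
        + days["cs_motion"].to_numpy(dtype=np.int64)
    )
    ews = (
        _ews_column("respiratory_rate", days["respiratory_rate"].to_numpy(float))
        + _ews_column("spo2", days["spo2"].to_numpy(float))
        + np.where(days["oxygen_prescription"].to_numpy(float) > 0, 2, 0)
        + _ews_column("body_temperature", days["body_temperature"].to_numpy(float))
        + _ews_column("systolic_bp", days["systolic_bp"].to_numpy(float))
        + _ews_column("heart_rate", days["heart_rate"].to_numpy(float))
        + _ews_column("coma_status", cs_all.astype(float))
    )
    te = (
        days["pain"].to_numpy(float) * config.r_pain
        + days["bsrs"].to_numpy(float) * config.r_bsrs
        + days["nutrition"].to_numpy(float) * config.r_nutrition
    )
    disease = days["patient_id"].map(
        episodes.set_index("patient_id")["disease_category"]
    )
    w = np.array([config.weights[d] for d in disease], dtype=float)
    b = np.minimum(days["cci_raw"].to_numpy(float), config.cap)
    c = np.minimum(ews.astype(float), config.cap)
    hs = te * w[:, 0] + b * config.r_cci * w[:, 1] + c * config.r_ews * w[:, 2]

    return pd.DataFrame({
        "patient_id": days["patient_id"].to_numpy(),
        "date": days["date"].to_numpy(),
        "cs_all": cs_all,
        "ews": ews,
        "team_eval": te,
        "health_score": hs,
    })
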