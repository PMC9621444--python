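"""Synthetic in-patient cohort generator.

No real hospital dataset is distributable, so this module generates admission
episodes and per-patient-day records with the statistical structure the
pipeline assumes: truncated-normal marginals matching the published cohort
characteristics (age 53.79 +/- 24.14 on 0-107, pulse 81.63 +/- 15.79, ...), an
HHC prevalence of ~0.43%, configurable missingness and outlier corruption, and
a deterioration drift applied to the vitals, consciousness sub-scales and
care-team indices of HHC cases over the days leading up to the recorded HHC
decision.  The drift is the learnable signal: it lives in exactly the features
the downstream sequence model consumes.

Only marginal distributions are emulated; inter-vital physiological
correlation and disease-specific trajectories are out of scope.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records_io import DAY_COLUMNS, DISEASE_CATEGORIES, VITAL_FIELDS


class ConfigurationError(ValueError):
    """Raised for invalid cohort-spec fields."""


#: (mean, sd, lo, hi) truncated-normal parameters per field — the published
#: cohort marginals.  Integer-scaled fields are rounded after sampling.
DEFAULT_FIELD_DISTS: dict[str, tuple[float, float, float, float]] = {
    "age": (53.79, 24.14, 0, 107),
    "respiratory_rate": (18.08, 2.34, 0, 50),
    "spo2": (96.91, 2.27, 80, 100),
    "systolic_bp": (128.46, 21.06, 0, 203),
    "heart_rate": (81.63, 15.79, 0, 133),
    "body_temperature": (36.41, 0.59, 32.0, 42.5),
    "nutrition": (1.72, 0.85, 1, 6),
    "bsrs": (1.83, 1.01, 1, 10),
    "pain": (1.93, 1.02, 1, 10),
    "cci_raw": (4.69, 2.37, 0, 19),
    "cs_eye": (3.88, 0.46, 1, 4),
    "cs_vocal": (4.36, 1.33, 1, 5),
    "cs_motion": (5.74, 0.79, 1, 6),
}

_INT_FIELDS = ("respiratory_rate", "spo2", "systolic_bp", "heart_rate",
               "nutrition", "bsrs", "pain", "cci_raw", "cs_eye", "cs_vocal", "cs_motion")

#: per-day worsening applied to HHC cases; sign encodes direction (SpO2 and
#: blood pressure fall, respiration/pulse/temperature and distress rise,
#: consciousness declines).  Magnitudes accumulate linearly over lead_days.
DEFAULT_DRIFT: dict[str, float] = {
    "respiratory_rate": 1.2,
    "spo2": -0.7,
    "systolic_bp": -4.0,
    "heart_rate": 5.0,
    "body_temperature": 0.22,
    "cs_eye": -0.25,
    "cs_vocal": -0.35,
    "cs_motion": -0.40,
    # deterioration is predominantly physiological; the care-team indices
    # move only mildly, so threshold rules on them miss most cases
    "pain": 0.10,
    "bsrs": 0.10,
    "nutrition": 0.05,
}


#: fraction of each field's marginal SD attributed to day-to-day fluctuation
#: (the rest is a stable patient-level baseline)
_WITHIN_DAY_SD_SHARE = {
    "respiratory_rate": 0.7, "spo2": 0.7, "systolic_bp": 0.7,
    "heart_rate": 0.7, "body_temperature": 0.7,
    "cs_eye": 0.3, "cs_vocal": 0.3, "cs_motion": 0.3,
    "pain": 0.3, "bsrs": 0.3, "nutrition": 0.3,
}


@dataclass
class Deterioration:
    """Pre-HHC worsening: per-day drift magnitudes over the final lead_days."""

    lead_days: int = 7
    drift: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the published dataset characteristics; the deterioration
    block and corruption rates are configuration, not constants.
    """

    n_patients: int = 1000
    hhc_prevalence: float = 0.0043
    stay_length_dist: tuple[float, float, float, float] = (7.89, 11.59, 1, 60)
    field_dists: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FIELD_DISTS))
    missing_rate: float = 0.02
    outlier_rate: float = 0.005
    deterioration: Deterioration = field(default_factory=Deterioration)
    disease_mix: Mapping[str, float] = field(
        default_factory=lambda: {"CVA": 0.05, "Dementia": 0.05, "Cancer": 0.20, "Others": 0.70})
    psychiatric_rate: float = 0.02
    demo_rate: float = 0.005
    reh_rate: float = 0.03
    o2_base_rate: float = 0.05
    o2_deteriorated_rate: float = 0.45
    hhc_extra_cci: float = 2.0
    start_date: dt.date = dt.date(2017, 1, 1)
    calendar_span_days: int = 730
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name, p in (("hhc_prevalence", self.hhc_prevalence),
                        ("psychiatric_rate", self.psychiatric_rate),
                        ("demo_rate", self.demo_rate), ("reh_rate", self.reh_rate),
                        ("o2_base_rate", self.o2_base_rate),
                        ("o2_deteriorated_rate", self.o2_deteriorated_rate)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {p}")
        for name, r in (("missing_rate", self.missing_rate), ("outlier_rate", self.outlier_rate)):
            if not 0.0 <= r < 1.0:
                raise ConfigurationError(f"{name} must be in [0,1), got {r}")
        if set(self.disease_mix) != set(DISEASE_CATEGORIES):
            raise ConfigurationError(f"disease_mix must cover exactly {DISEASE_CATEGORIES}")
        if any(p < 0 for p in self.disease_mix.values()) or \
                abs(sum(self.disease_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("disease_mix must be non-negative and sum to 1")
        for f, (m, s, lo, hi) in self.field_dists.items():
            if s < 0 or hi < lo:
                raise ConfigurationError(f"field_dists[{f!r}]: sd >= 0 and hi >= lo required")
        if self.deterioration.lead_days < 1:
            raise ConfigurationError("deterioration.lead_days must be >= 1")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort; returns (episodes, day_records) DataFrames.

    One episode per patient; one day record per in-stay calendar day.  HHC
    onset is placed at least 7 days after admission so generated positives
    survive the evaluation-cohort filters.  Deterministic given spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    pid = np.array([f"P{i:07d}" for i in range(1, n + 1)])

    age = np.round(_truncnorm(rng, *spec.field_dists["age"], n))
    categories = list(DISEASE_CATEGORIES)
    disease = rng.choice(categories, size=n, p=[spec.disease_mix[c] for c in categories])
    is_psy = rng.random(n) < spec.psychiatric_rate
    is_demo = rng.random(n) < spec.demo_rate
    is_reh = rng.random(n) < spec.reh_rate
    hhc = rng.random(n) < spec.hhc_prevalence

    mean, sd, lo, hi = spec.stay_length_dist
    stay = np.round(_truncnorm(rng, mean, sd, lo, hi, n)).astype(int)
    stay = np.clip(stay, max(1, int(lo)), int(hi))
    stay[hhc] = np.maximum(stay[hhc], 8)  # room for onset >= day 7

    adm_offset = rng.integers(0, spec.calendar_span_days, size=n)
    start = np.datetime64(spec.start_date)
    admission = start + adm_offset.astype("timedelta64[D]")
    discharge = admission + (stay - 1).astype("timedelta64[D]")

    hhc_off = np.full(n, -1)
    idx_hhc = np.nonzero(hhc)[0]
    for i in idx_hhc:
        hhc_off[i] = rng.integers(7, stay[i])
    hhc_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    hhc_date[idx_hhc] = admission[idx_hhc] + hhc_off[idx_hhc].astype("timedelta64[D]")

    episodes = pd.DataFrame({
        "patient_id": pid,
        "admission_date": [d.astype(dt.date) for d in admission],
        "discharge_date": [d.astype(dt.date) for d in discharge],
        "disease_category": disease,
        "is_psychiatric": is_psy,
        "is_demo": is_demo,
        "is_reh": is_reh,
        "hhc_label": hhc,
        "hhc_date": [None if np.isnat(d) else d.astype(dt.date) for d in hhc_date],
        "age": age,
    })

    # --- day-level table -------------------------------------------------
    total = int(stay.sum())
    rep = np.repeat(np.arange(n), stay)
    day_off = np.concatenate([np.arange(s) for s in stay])
    dates = admission[rep] + day_off.astype("timedelta64[D]")

    det = spec.deterioration
    # severity in "accumulated drift days": 0 away from onset, ramping to
    # lead_days at the HHC date and staying saturated afterwards
    days_until = np.where(hhc[rep], hhc_off[rep] - day_off, np.inf)
    severity = np.clip(det.lead_days - days_until, 0, det.lead_days)

    # Each repeated-measure field is split into a stable patient-level
    # baseline plus day-to-day noise, keeping the published marginal SD:
    # sd^2 = sd_between^2 + sd_within^2.  Assessment indices and coma scales
    # are mostly patient-stable; vitals fluctuate more day to day.
    cols: dict[str, np.ndarray] = {}
    for f in VITAL_FIELDS + ("cs_eye", "cs_vocal", "cs_motion", "pain", "bsrs", "nutrition"):
        m, s, flo, fhi = spec.field_dists[f]
        within = _WITHIN_DAY_SD_SHARE[f]
        base = _truncnorm(rng, m, s * np.sqrt(1 - within**2), flo, fhi, n)
        vals = base[rep] + rng.normal(0.0, s * within, total)
        vals = vals + det.drift.get(f, 0.0) * severity
        vals = np.clip(vals, flo, fhi)
        cols[f] = vals

    m, s, flo, fhi = spec.field_dists["cci_raw"]
    cci = _truncnorm(rng, m, s, flo, fhi, n)
    cci[hhc] = np.clip(cci[hhc] + spec.hhc_extra_cci, flo, fhi)
    cols["cci_raw"] = cci[rep]  # comorbidity burden is stable within a stay

    p_o2 = np.where(severity > 0,
                    spec.o2_base_rate + (spec.o2_deteriorated_rate - spec.o2_base_rate)
                    * severity / det.lead_days,
                    spec.o2_base_rate)
    cols["oxygen_prescription"] = (rng.random(total) < p_o2).astype(float)

    for f in _INT_FIELDS:
        if f in cols:
            cols[f] = np.round(cols[f])
    cols["body_temperature"] = np.round(cols["body_temperature"], 1)

    days = pd.DataFrame({"patient_id": pid[rep],
                         "date": [d.astype(dt.date) for d in dates],
                         **{c: cols[c] for c in DAY_COLUMNS[2:]}})

    if spec.missing_rate > 0 or spec.outlier_rate > 0:
        days, _ = inject_missing_and_outliers(
            days, spec.missing_rate, spec.outlier_rate,
            seed=int(rng.integers(0, 2**31)), field_dists=spec.field_dists)
    return episodes, days


def inject_missing_and_outliers(
    days: pd.DataFrame, missing_rate: float, outlier_rate: float, seed: int,
    field_dists: Mapping[str, tuple[float, float, float, float]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Corrupt vital cells: blank exactly ``floor(missing_rate * n_cells)`` and
    replace ``floor(outlier_rate * n_cells)`` others with >2-SD excursions.

    Cells are drawn without replacement over (row, vital-field) positions, the
    two corruption sets disjoint.  Returns the corrupted frame and a manifest
    of positions for test assertions.
    """
    for name, r in (("missing_rate", missing_rate), ("outlier_rate", outlier_rate)):
        if not 0.0 <= r < 1.0:
            raise ConfigurationError(f"{name} must be in [0,1), got {r}")
    field_dists = field_dists or DEFAULT_FIELD_DISTS
    rng = np.random.default_rng(seed)
    out = days.copy()
    n_rows = len(out)
    n_fields = len(VITAL_FIELDS)
    n_cells = n_rows * n_fields
    n_miss = int(missing_rate * n_cells)
    n_out = int(outlier_rate * n_cells)
    manifest: dict = {"missing": [], "outliers": []}
    if n_miss + n_out == 0:
        return out, manifest

    flat = rng.choice(n_cells, size=n_miss + n_out, replace=False)
    for k, cell in enumerate(flat):
        row, fi = int(cell) // n_fields, int(cell) % n_fields
        f = VITAL_FIELDS[fi]
        if k < n_miss:
            manifest["missing"].append([row, f])
            out.iat[row, out.columns.get_loc(f)] = np.nan
        else:
            m, s, _, _ = field_dists[f]
            mag = (2.5 + 1.5 * rng.random()) * s
            injected = m + mag * (1 if rng.random() < 0.5 else -1)
            injected = round(injected, 1) if f == "body_temperature" else round(injected)
            original = out.iat[row, out.columns.get_loc(f)]
            manifest["outliers"].append([row, f, float(original), float(injected)])
            out.iat[row, out.columns.get_loc(f)] = injected
    return out, manifest
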