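"""Rule-based expert comparator and evaluation-cohort filters.

The deployed expert system suggests an HHC consult when any of four rules
holds on a patient-day's scores:

1. ``health_score >= 70``
2. ``health_score >= 50 and nutrition >= 2 and bsrs >= 4``
3. dementia patient with ``health_score >= 40``, rehabilitation stays excluded
4. ``nutrition >= 2 and bsrs >= 4 and pain >= 3``

The rehabilitation exclusion is local to rule 3 (it is stated inside that
rule).  An episode is rule-flagged if any in-stay day fires; the earliest
firing day is the forecast date.

The evaluation-cohort filter drops, in order: (a) psychiatric in-patients,
(b) demo cases, (c) stays shorter than 7 days, (d) episodes whose HHC decision
came within 7 days of admission — (c) and (d) because such stays carry too
little history to judge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records_io import ValidationError


@dataclass(frozen=True)
class RuleInputs:
    """One patient-day's inputs to the expert rules."""

    health_score: float
    nutrition: float
    bsrs: float
    pain: float
    disease_category: str
    is_reh: bool = False

    def __post_init__(self) -> None:
        if self.health_score < 0:
            raise ValidationError("health_score must be >= 0")
        if not 0 <= self.nutrition <= 6 or not 0 <= self.bsrs <= 10 or not 0 <= self.pain <= 10:
            raise ValidationError("nutrition/bsrs/pain outside scoring bounds")


def rule_decision(inputs: RuleInputs) -> tuple[bool, frozenset[int]]:
    """Evaluate the four expert rules; returns (flag, set of fired rule ids)."""
    fired = set()
    if inputs.health_score >= 70:
        fired.add(1)
    if inputs.health_score >= 50 and inputs.nutrition >= 2 and inputs.bsrs >= 4:
        fired.add(2)
    if (inputs.disease_category == "Dementia" and inputs.health_score >= 40
            and not inputs.is_reh):
        fired.add(3)
    if inputs.nutrition >= 2 and inputs.bsrs >= 4 and inputs.pain >= 3:
        fired.add(4)
    return bool(fired), frozenset(fired)


def rule_decisions_frame(days: pd.DataFrame, scores: pd.DataFrame,
                         episodes: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-day rule evaluation over a scored cohort.

    Returns ``patient_id, date, flag, fired_rules`` aligned with *scores*.
    """
    epi = episodes.set_index("patient_id")
    disease = scores["patient_id"].map(epi["disease_category"]).to_numpy()
    is_reh = scores["patient_id"].map(epi["is_reh"]).to_numpy(dtype=bool)
    hs = scores["health_score"].to_numpy(float)
    nut = days["nutrition"].to_numpy(float)
    bsrs = days["bsrs"].to_numpy(float)
    pain = days["pain"].to_numpy(float)

    r1 = hs >= 70
    r2 = (hs >= 50) & (nut >= 2) & (bsrs >= 4)
    r3 = (disease == "Dementia") & (hs >= 40) & ~is_reh
    r4 = (nut >= 2) & (bsrs >= 4) & (pain >= 3)
    flag = r1 | r2 | r3 | r4
    fired = [
        "".join(str(i + 1) for i, on in enumerate(row) if on)
        for row in np.column_stack([r1, r2, r3, r4])
    ]
    return pd.DataFrame({
        "patient_id": scores["patient_id"].to_numpy(),
        "date": scores["date"].to_numpy(),
        "flag": flag,
        "fired_rules": fired,
    })


def episode_rule_predictions(decisions: pd.DataFrame, episodes: pd.DataFrame) -> pd.DataFrame:
    """Aggregate day-level rule firings to episode level.

    An episode is flagged if any of its days fires; the earliest firing date
    becomes the forecast date.  Returns one row per episode:
    ``patient_id, flag, forecast_date``.
    """
    firing = decisions[decisions["flag"]]
    first = firing.groupby("patient_id")["date"].min()
    out = pd.DataFrame({"patient_id": episodes["patient_id"].to_numpy()})
    out["flag"] = out["patient_id"].isin(first.index)
    out["forecast_date"] = out["patient_id"].map(first)
    return out


_EXCLUSION_ORDER = ("psychiatric", "demo", "short_stay", "early_hhc")


def filter_evaluation_cohort(episodes: pd.DataFrame,
                             min_stay_days: int = 7) -> tuple[pd.DataFrame, dict]:
    """Apply the four evaluation-cohort exclusions.

    Episodes satisfying several criteria are attributed to the first matching
    one, in the order psychiatric -> demo -> short stay -> early HHC.  A stay
    of fewer than *min_stay_days* days (discharge minus admission) is short.
    """
    if episodes["discharge_date"].isna().any():
        bad = episodes.loc[episodes["discharge_date"].isna(), "patient_id"].iloc[0]
        raise ValidationError(f"episode {bad}: completed stay without discharge_date")

    stay = (pd.to_datetime(episodes["discharge_date"])
            - pd.to_datetime(episodes["admission_date"])).dt.days
    hhc_delay = (pd.to_datetime(episodes["hhc_date"])
                 - pd.to_datetime(episodes["admission_date"])).dt.days

    crit = {
        "psychiatric": episodes["is_psychiatric"].to_numpy(dtype=bool),
        "demo": episodes["is_demo"].to_numpy(dtype=bool),
        "short_stay": (stay < min_stay_days).to_numpy(),
        "early_hhc": (hhc_delay < min_stay_days).fillna(False).to_numpy(),
    }
    dropped = np.zeros(len(episodes), dtype=bool)
    report = {}
    for name in _EXCLUSION_ORDER:
        hit = crit[name] & ~dropped
        report[name] = int(hit.sum())
        dropped |= crit[name]
    report["n_input"] = int(len(episodes))
    report["n_dropped"] = int(dropped.sum())
    report["n_kept"] = int((~dropped).sum())
    kept = episodes.loc[~dropped].reset_index(drop=True)
    return kept, report
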