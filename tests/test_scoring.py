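import numpy as np
import pandas as pd
import pytest

from hhc_cdss.records_io import ValidationError
from hhc_cdss.scoring import (EWS_MAX, ScoringConfig, coma_status, early_warning_score,
                              ews_component, health_score, score_days, team_eval)

# ---------------------------------------------------------------------------
# Independent early-warning oracle: a literal transcription of the published
# bin table as closed integer intervals (temperature in tenths of a degree).
# Kept deliberately separate from the implementation's representation.

ORACLE_INTERVALS = {
    "respiratory_rate": [((-10**9, 8), 3), ((9, 11), 1), ((12, 20), 0),
                         ((21, 24), 2), ((25, 10**9), 3)],
    "spo2": [((-10**9, 91), 3), ((92, 93), 2), ((94, 95), 1), ((96, 10**9), 0)],
    "body_temperature_tenths": [((-10**9, 350), 3), ((351, 360), 1), ((361, 380), 0),
                                ((381, 390), 1), ((391, 10**9), 2)],
    "systolic_bp": [((-10**9, 90), 3), ((91, 100), 2), ((101, 110), 1),
                    ((111, 219), 0), ((220, 10**9), 3)],
    "heart_rate": [((-10**9, 40), 3), ((41, 50), 1), ((51, 90), 0),
                   ((91, 110), 1), ((111, 130), 2), ((131, 10**9), 3)],
    "coma_status": [((1, 14), 3), ((15, 10**9), 0)],
}


def oracle_component(parameter, value):
    key = parameter
    if parameter == "oxygen_prescription":
        return 2 if value else 0
    if parameter == "body_temperature":
        key, value = "body_temperature_tenths", int(round(value * 10))
    for (lo, hi), score in ORACLE_INTERVALS[key]:
        if lo <= value <= hi:
            return score
    raise AssertionError(f"{parameter}={value} not covered")


ORACLE_GRIDS = {
    "respiratory_rate": np.arange(0, 61),
    "spo2": np.arange(80, 101),
    "systolic_bp": np.arange(0, 251),
    "heart_rate": np.arange(0, 201),
    "body_temperature": np.round(np.arange(32.0, 42.51, 0.1), 1),
    "coma_status": np.arange(3, 16),
}


# ---------------------------------------------------------------------------

def test_default_config_matches_published_constants():
    cfg = ScoringConfig()
    assert (cfg.r_pain, cfg.r_bsrs, cfg.r_nutrition) == (5, 5, 30)
    assert (cfg.r_cci, cfg.r_ews, cfg.cap) == (5, 5, 20)
    assert cfg.weights["CVA"] == (0.37, 0.34, 0.29)
    assert cfg.weights["Dementia"] == (0.7, 0.19, 0.10)
    assert cfg.weights["Cancer"] == (0.61, 0.19, 0.20)
    assert cfg.weights["Others"] == (0.10, 0.80, 0.10)
    assert sum(cfg.weights["Dementia"]) == pytest.approx(0.99)  # as published


def test_config_yaml_round_trip():
    cfg = ScoringConfig(r_pain=7, weights={**ScoringConfig().weights, "CVA": (0.5, 0.3, 0.2)})
    assert ScoringConfig.from_yaml(cfg.to_yaml()) == cfg


@pytest.mark.parametrize("scales,expected", [((4, 5, 6), 15), ((1, 1, 1), 3), ((3, 4, 5), 12)])
def test_coma_status(scales, expected):
    assert coma_status(*scales) == expected


def test_coma_status_bounds():
    with pytest.raises(ValidationError):
        coma_status(5, 5, 6)
    with pytest.raises(ValidationError):
        coma_status(4, 0, 6)


@pytest.mark.parametrize("param,value,expected", [
    ("respiratory_rate", 18, 0),
    ("spo2", 92, 2),
    ("body_temperature", 38.5, 1),
    ("coma_status", 14, 3),
    ("coma_status", 15, 0),
    ("oxygen_prescription", True, 2),
    ("oxygen_prescription", False, 0),
])
def test_ews_component_examples(param, value, expected):
    assert ews_component(param, value) == expected


def test_ews_component_unknown_parameter():
    with pytest.raises(KeyError):
        ews_component("glucose", 5)


@pytest.mark.parametrize("args,expected", [
    ((16, 98, False, 37.0, 120, 70, 15), 0),
    ((22, 93, True, 38.5, 95, 115, 10), 14),
    ((8, 91, True, 34.9, 88, 135, 5), 20),
])
def test_early_warning_score_examples(args, expected):
    assert early_warning_score(*args) == expected


def test_ews_component_equals_oracle_on_full_grids():
    for param, grid in ORACLE_GRIDS.items():
        for v in grid:
            assert ews_component(param, v) == oracle_component(param, v), (param, v)


def test_ews_maximum_is_attained_and_bounded():
    assert early_warning_score(8, 91, True, 34.9, 88, 135, 5) == EWS_MAX
    rng = np.random.default_rng(1)
    for _ in range(500):
        args = (rng.integers(0, 61), rng.integers(80, 101), bool(rng.integers(2)),
                round(rng.uniform(32, 42.5), 1), rng.integers(0, 251),
                rng.integers(0, 201), rng.integers(3, 16))
        assert 0 <= early_warning_score(*args) <= EWS_MAX


@pytest.mark.parametrize("args,expected", [
    ((0, 0, 0), 0.0),
    ((3, 4, 2), 95.0),
    ((10, 10, 6), 280.0),
])
def test_team_eval(args, expected):
    assert team_eval(*args) == expected


def test_team_eval_bounds():
    with pytest.raises(ValidationError):
        team_eval(11, 0, 0)


@pytest.mark.parametrize("args,expected", [
    ((0, 0, 0, "Others"), 0.0),
    ((95, 4, 3, "Dementia"), 71.8),
    ((95, 4, 3, "Others"), 27.0),
    ((0, 25, 0, "Others"), 80.0),  # exercises the min(B, 20) cap
])
def test_health_score_worked_values(args, expected):
    assert health_score(*args) == pytest.approx(expected, abs=1e-12)


def test_health_score_unknown_disease():
    with pytest.raises(KeyError):
        health_score(0, 0, 0, "Flu")


def test_health_score_monotone_in_each_argument():
    rng = np.random.default_rng(7)
    for _ in range(300):
        te, b, c = rng.uniform(0, 300), rng.uniform(0, 30), rng.uniform(0, 25)
        disease = rng.choice(["CVA", "Dementia", "Cancer", "Others"])
        base = health_score(te, b, c, disease)
        assert health_score(te + 1, b, c, disease) >= base
        assert health_score(te, b + 1, c, disease) >= base
        assert health_score(te, b, c + 1, disease) >= base


def test_scores_linear_below_caps():
    cfg = ScoringConfig()
    for a in (0.25, 0.5, 2.0):
        assert team_eval(4 * a, 2 * a, 1 * a) == pytest.approx(a * team_eval(4, 2, 1))
        assert health_score(50 * a, 0, 0, "Cancer") == pytest.approx(
            a * health_score(50, 0, 0, "Cancer"))
    assert health_score(0, 10 * 2, 0, "Others", cfg) == pytest.approx(
        2 * health_score(0, 10, 0, "Others", cfg))


def test_vectorized_cohort_scoring_matches_scalar_path():
    rng = np.random.default_rng(5)
    n = 300
    days = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "date": pd.date_range("2019-01-01", periods=n).date,
        "respiratory_rate": rng.integers(0, 61, n).astype(float),
        "spo2": rng.integers(80, 101, n).astype(float),
        "oxygen_prescription": rng.integers(0, 2, n).astype(float),
        "body_temperature": np.round(rng.uniform(32, 42.5, n), 1),
        "systolic_bp": rng.integers(0, 251, n).astype(float),
        "heart_rate": rng.integers(0, 201, n).astype(float),
        "cs_eye": rng.integers(1, 5, n).astype(float),
        "cs_vocal": rng.integers(1, 6, n).astype(float),
        "cs_motion": rng.integers(1, 7, n).astype(float),
        "pain": rng.integers(0, 11, n).astype(float),
        "bsrs": rng.integers(0, 11, n).astype(float),
        "nutrition": rng.integers(0, 7, n).astype(float),
        "cci_raw": rng.integers(0, 20, n).astype(float),
    })
    episodes = pd.DataFrame({
        "patient_id": days["patient_id"],
        "disease_category": rng.choice(["CVA", "Dementia", "Cancer", "Others"], n),
    })
    scores = score_days(days, episodes)
    for i in rng.choice(n, size=50, replace=False):
        r = days.iloc[i]
        cs = coma_status(int(r.cs_eye), int(r.cs_vocal), int(r.cs_motion))
        ews = early_warning_score(r.respiratory_rate, r.spo2, bool(r.oxygen_prescription),
                                  r.body_temperature, r.systolic_bp, r.heart_rate, cs)
        te = team_eval(r.pain, r.bsrs, r.nutrition)
        hs = health_score(te, r.cci_raw, ews,
                          episodes.iloc[i]["disease_category"])
        assert scores.iloc[i]["cs_all"] == cs
        assert scores.iloc[i]["ews"] == ews
        assert scores.iloc[i]["team_eval"] == pytest.approx(te)
        assert scores.iloc[i]["health_score"] == pytest.approx(hs)
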