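"""End-to-end orchestration: simulate -> preprocess -> score -> filter ->
split -> encode -> undersample -> train -> rule engine -> evaluate.

One root seed governs every stochastic stage through named sub-streams, so
individual stages are reproducible and two runs of the same config produce
byte-identical outputs on a single thread.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, feature_encoding, preprocessing, rule_engine, scoring
from . import sequence_model as sm
from .records_io import DAY_COLUMNS, EPISODE_COLUMNS_WITH_AGE
from .synthetic_cohort import CohortSpec, Deterioration, generate_cohort

log = logging.getLogger("hhc_cdss")


def sub_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the root seed."""
    return int(np.random.SeedSequence(
        [int(root_seed), zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    episodes_path: str | None = None   # None => simulate
    days_path: str | None = None
    cohort: dict = field(default_factory=dict)      # CohortSpec overrides
    scoring: dict = field(default_factory=dict)     # ScoringConfig overrides
    model: dict = field(default_factory=dict)       # ModelConfig overrides
    validity_days: int = 14
    min_stay_days: int = 7
    skip_train: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        kw = dict(self.cohort)
        det = kw.pop("deterioration", None)
        if det is not None:
            kw["deterioration"] = Deterioration(**det)
        kw.setdefault("seed", sub_seed(self.seed, "simulate"))
        return CohortSpec(**kw)

    def scoring_config(self) -> scoring.ScoringConfig:
        kw = dict(self.scoring)
        if "weights" in kw:
            kw["weights"] = {k: tuple(v) for k, v in kw["weights"].items()}
        return scoring.ScoringConfig(**kw)

    def model_config(self, architecture: str) -> sm.ModelConfig:
        kw = dict(self.model)
        kw["architecture"] = architecture
        kw.setdefault("seed", sub_seed(self.seed, f"train-{architecture}"))
        return sm.ModelConfig(**kw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_simulate(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the synthetic cohort and write episodes.csv / days.csv."""
    spec = config.cohort_spec()
    episodes, days = generate_cohort(spec)
    out = Path(config.out_dir)
    ep_out = episodes[EPISODE_COLUMNS_WITH_AGE].copy()
    for c in ("is_psychiatric", "is_demo", "is_reh", "hhc_label"):
        ep_out[c] = ep_out[c].astype(int)
    _write_csv(ep_out, out / "episodes.csv")
    days_out = days[DAY_COLUMNS].copy()
    days_out["oxygen_prescription"] = days_out["oxygen_prescription"].astype("Int64")
    _write_csv(days_out, out / "days.csv")
    log.info("simulate: %d episodes, %d day records", len(episodes), len(days))
    return episodes, days


def _load_inputs(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.episodes_path and config.days_path:
        from .records_io import (episodes_to_frame, days_to_frame,
                                 read_episodes, read_day_records)
        episodes = episodes_to_frame(read_episodes(config.episodes_path))
        days = days_to_frame(read_day_records(config.days_path))
        return episodes, days
    return run_simulate(config)


def run_full(config: PipelineConfig) -> dict:
    """Execute the whole study and return the comparison report dict."""
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("run-full: config hash %s, seed %d", config.config_hash(), config.seed)

    timings: dict[str, float] = {}

    def tick(stage: str) -> None:
        timings[stage] = round(time.time() - t0 - sum(timings.values()), 3)
        log.info("stage %s done (%.1fs)", stage, timings[stage])

    episodes, days = _load_inputs(config)
    tick("inputs")

    days_pp, pp_report = preprocessing.preprocess_cohort(days)
    tick("preprocess")

    scfg = config.scoring_config()
    scores = scoring.score_days(days_pp, episodes, scfg)
    tick("score")

    kept, exclusion_report = rule_engine.filter_evaluation_cohort(
        episodes, config.min_stay_days)
    kept_ids = set(kept["patient_id"])
    mask = days_pp["patient_id"].isin(kept_ids).to_numpy()
    days_kept = days_pp.loc[mask].reset_index(drop=True)
    scores_kept = scores.loc[mask].reset_index(drop=True)
    log.info("filter: kept %d / %d episodes (%s)", len(kept), len(episodes),
             exclusion_report)
    tick("filter")

    train_epi, test_epi = sm.split_hhc_cases(kept, sub_seed(config.seed, "split"))
    test_ids = set(test_epi["patient_id"])
    tick("split")

    train_mask = days_kept["patient_id"].isin(set(train_epi["patient_id"])).to_numpy()
    raw_train = feature_encoding.encode_day_features(
        days_kept.loc[train_mask].reset_index(drop=True),
        scores_kept.loc[train_mask].reset_index(drop=True), kept, scaling=None)
    scaling = feature_encoding.ScalingParams.fit(raw_train)
    features = feature_encoding.encode_day_features(days_kept, scores_kept, kept, scaling)
    windows_train = feature_encoding.build_cohort_windows(
        features.loc[train_mask].reset_index(drop=True), train_epi,
        hhc_horizon=config.validity_days)
    windows_test = feature_encoding.build_cohort_windows(
        features.loc[~train_mask].reset_index(drop=True), test_epi,
        hhc_horizon=config.validity_days)
    log.info("encode: %d train windows (%d positive), %d test windows",
             len(windows_train), sum(w.label for w in windows_train), len(windows_test))
    tick("encode")

    predictions: dict[str, pd.DataFrame] = {}
    if not config.skip_train:
        for arch in ("lstm", "rnn"):
            mcfg = config.model_config(arch)
            sampled = sm.undersample_training_set(
                windows_train, mcfg.undersample_ratio,
                sub_seed(config.seed, f"undersample-{arch}"))
            log.info("%s: training on %d windows (%d positive)", arch,
                     len(sampled), sum(w.label for w in sampled))
            model = sm.train(sampled, mcfg)
            model.save(out_dir / f"model_{arch}.npz")
            wp = sm.predict(model, windows_test)
            predictions[arch] = sm.predict_episodes(wp, test_epi)
            tick(f"train-{arch}")

    rd = rule_engine.rule_decisions_frame(days_kept, scores_kept, kept)
    test_day_mask = rd["patient_id"].isin(test_ids)
    predictions["rule_based"] = rule_engine.episode_rule_predictions(
        rd.loc[test_day_mask].reset_index(drop=True), test_epi)
    tick("rules")

    reports = evaluation.compare_systems(test_epi, predictions, config.validity_days)
    result = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_test_episodes": int(len(test_epi)),
        "n_test_hhc": int(test_epi["hhc_label"].sum()),
        "exclusion_report": exclusion_report,
        "preprocessing_report": {k: pp_report[k] for k in
                                 ("interpolated", "outliers_replaced")},
        "systems": reports,
    }
    (out_dir / "metrics.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    (out_dir / "summary.txt").write_text(render_summary(reports))
    timings["total"] = round(time.time() - t0, 3)
    log.info("run-full complete: %s", timings)
    return result


_SUMMARY_ROWS = (("accuracy", "Accuracy", True), ("specificity", "Specificity", True),
                 ("sensitivity", "Sensitivity (Recall)", True),
                 ("precision", "Precision (PPV)", True),
                 ("f1", "F1 Score", False), ("auc", "ROC-AUC", False))


def render_summary(reports: dict[str, dict]) -> str:
    """Human-readable side-by-side metric table."""
    systems = list(reports)
    lines = ["\t" + "\t".join(systems)]
    for key, label, pct in _SUMMARY_ROWS:
        cells = []
        for s in systems:
            v = reports[s]["metrics"].get(key)
            if v is None:
                cells.append("-")
            elif pct:
                cells.append(f"{100 * v:.2f}%")
            else:
                cells.append(f"{v:.4f}")
        lines.append(label + "\t" + "\t".join(cells))
    cm_line = []
    for s in systems:
        cm = reports[s]["confusion_matrix"]
        cm_line.append(f"{s}: TP={cm['tp']} FP={cm['fp']} FN={cm['fn']} TN={cm['tn']}")
    lines.append("")
    lines.extend(cm_line)
    return "\n".join(lines) + "\n"
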