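"""Episode-level evaluation: confusion matrices under the two-week validity
rule, the derived classification metrics, and ROC-AUC.

An HHC prediction counts as correct only when the forecast date lies within
``validity_days`` (default 14) of the clinician-recorded HHC date, read
symmetrically.  Metrics with a zero denominator are reported as undefined
(``None``), never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .records_io import ValidationError


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Derived metrics; a ``None`` value marks a zero-denominator metric."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    auc: float | None = None

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "precision": self.precision,
                "f1": self.f1, "auc": self.auc}


def match_episode_predictions(episodes: pd.DataFrame, predictions: pd.DataFrame,
                              validity_days: int = 14) -> ConfusionMatrix:
    """Count episode outcomes under the validity window.

    *predictions* carries one row per episode: ``patient_id, flag,
    forecast_date``.  An HHC episode is a true positive only if it is flagged
    and ``|forecast_date - hhc_date| <= validity_days``.
    """
    merged = episodes.merge(predictions, on="patient_id", how="left", validate="1:1")
    if merged["flag"].isna().any():
        missing = merged.loc[merged["flag"].isna(), "patient_id"].iloc[0]
        raise ValidationError(f"episode {missing} has no prediction")
    flagged = merged["flag"].astype(bool)
    if (flagged & merged["forecast_date"].isna()).any():
        bad = merged.loc[flagged & merged["forecast_date"].isna(), "patient_id"].iloc[0]
        raise ValidationError(f"flagged episode {bad} has no forecast date")
    is_hhc = merged["hhc_label"].astype(bool)
    delta = (pd.to_datetime(merged["forecast_date"])
             - pd.to_datetime(merged["hhc_date"])).dt.days.abs()
    valid_hit = flagged & is_hhc & (delta <= validity_days)

    tp = int(valid_hit.sum())
    fn = int((is_hhc & ~valid_hit).sum())
    fp = int((flagged & ~is_hhc).sum())
    tn = int((~flagged & ~is_hhc).sum())
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 from counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    sens = ratio(cm.tp, cm.tp + cm.fn)
    prec = ratio(cm.tp, cm.tp + cm.fp)
    f1 = None
    if sens is not None and prec is not None and (sens + prec) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=sens,
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        precision=prec,
        f1=f1,
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (rank-sum / trapezoidal; ties get midranks)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for plotting/export."""
    fpr, tpr, thr = roc_curve(np.asarray(labels, dtype=int),
                              np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def compare_systems(episodes: pd.DataFrame,
                    system_predictions: dict[str, pd.DataFrame],
                    validity_days: int = 14) -> dict[str, dict]:
    """Evaluate several systems on the identical episode set.

    *system_predictions* maps system name to a per-episode prediction frame
    (``patient_id, flag, forecast_date`` and optionally ``score`` for AUC).
    Returns per-system ``{"confusion_matrix": ..., "metrics": ...}`` dicts.
    """
    if len(episodes) == 0:
        raise ComparisonError("empty evaluation episode set")
    ref_ids = set(episodes["patient_id"])
    reports: dict[str, dict] = {}
    for name, preds in system_predictions.items():
        if set(preds["patient_id"]) != ref_ids:
            raise ComparisonError(f"system {name!r} evaluated on a different episode set")
        cm = match_episode_predictions(episodes, preds, validity_days)
        auc = None
        if "score" in preds.columns:
            merged = episodes.merge(preds, on="patient_id")
            labels = merged["hhc_label"].astype(int)
            if labels.nunique() == 2:
                auc = roc_auc(merged["score"], labels)
        reports[name] = {
            "confusion_matrix": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "metrics": {**compute_metrics(cm).as_dict(), "auc": auc},
        }
    return reports
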