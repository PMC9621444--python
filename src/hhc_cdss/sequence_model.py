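"""Recurrent sequence classifier over 8-day feature windows.

A compact, dependency-light recurrent network implemented directly in numpy:
an input layer of encoded day-vectors, one (configurable) recurrent layer —
LSTM by default, a simple tanh RNN as baseline — and a single sigmoid output
unit read from the final hidden state.  Training minimizes binary
cross-entropy with Adam, using backpropagation through time.  Everything is
deterministic given (data, config, seed) on a single thread, and trained
models serialize to a self-describing ``.npz`` archive that reloads with
bit-identical predictions.

Class imbalance is handled the way the study protocol prescribes: the
training set is rebalanced by undersampling the majority class to a 1:4
(HHC : non-HHC) window ratio at the episode level, optionally combined with
class-weighted loss.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .feature_encoding import FEATURE_NAMES, WINDOW_LENGTH, FeatureWindow


class TrainingError(ValueError):
    pass


class PredictionError(ValueError):
    pass


@dataclass
class ModelConfig:
    architecture: str = "lstm"          # "lstm" or "rnn"
    window_length: int = WINDOW_LENGTH  # fixed: current day + past 7
    hidden_units: int = 32
    n_recurrent_layers: int = 1
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 64
    decision_threshold: float = 0.5
    undersample_ratio: float = 4.0      # non-HHC windows per HHC window
    cv_folds: int = 10
    class_weighted_loss: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("lstm", "rnn"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.window_length != WINDOW_LENGTH:
            raise ValueError(f"window_length is fixed at {WINDOW_LENGTH}")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0,1)")
        if self.undersample_ratio <= 0:
            raise ValueError("undersample_ratio must be > 0")
        if self.hidden_units < 1 or self.n_recurrent_layers < 1 or self.epochs < 1:
            raise ValueError("hidden_units, n_recurrent_layers and epochs must be >= 1")


# ---------------------------------------------------------------------------
# resampling and splitting

def undersample_training_set(windows: list[FeatureWindow], ratio: float,
                             seed: int) -> list[FeatureWindow]:
    """Rebalance to *ratio* negative windows per positive window.

    All positive windows are kept.  Negative windows are taken episode by
    episode in shuffled order (whole episodes, to avoid splitting
    near-duplicate windows across the balance), truncating the last episode's
    windows to hit the exact target count.  Keeps all negatives with a warning
    when there are too few.
    """
    pos = [w for w in windows if w.label == 1]
    neg = [w for w in windows if w.label == 0]
    if not pos:
        raise TrainingError("undersampling requires at least one positive window")
    target = int(ratio * len(pos))
    if len(neg) <= target:
        if len(neg) < target:
            warnings.warn(
                f"only {len(neg)} negative windows available for a target of {target}; keeping all")
        return pos + neg
    by_episode: dict[str, list[FeatureWindow]] = {}
    for w in neg:
        by_episode.setdefault(w.patient_id, []).append(w)
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(by_episode))
    chosen: list[FeatureWindow] = []
    for pid in order:
        room = target - len(chosen)
        if room <= 0:
            break
        chosen.extend(by_episode[pid][:room])
    return pos + chosen


def split_hhc_cases(episodes: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split episodes 50/50 on the HHC cases, preserving prevalence.

    HHC episodes are shuffled and halved; non-HHC episodes are shuffled and
    split at the same fraction.  Episode-disjoint by construction.
    """
    rng = np.random.default_rng(seed)
    hhc = episodes.loc[episodes["hhc_label"].astype(bool)]
    non = episodes.loc[~episodes["hhc_label"].astype(bool)]
    if len(hhc) < 2:
        raise TrainingError(f"need >= 2 HHC episodes to split, have {len(hhc)}")
    hhc_idx = rng.permutation(len(hhc))
    non_idx = rng.permutation(len(non))
    n_train_pos = len(hhc) // 2
    train_frac = n_train_pos / len(hhc)
    n_train_neg = int(round(train_frac * len(non)))
    train = pd.concat([hhc.iloc[hhc_idx[:n_train_pos]], non.iloc[non_idx[:n_train_neg]]])
    test = pd.concat([hhc.iloc[hhc_idx[n_train_pos:]], non.iloc[non_idx[n_train_neg:]]])
    return train.reset_index(drop=True), test.reset_index(drop=True)


# ---------------------------------------------------------------------------
# network internals

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60))),
                    np.exp(np.clip(x, -60, 60)) / (1.0 + np.exp(np.clip(x, -60, 60))))


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


def _init_params(config: ModelConfig, n_features: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    H = config.hidden_units
    params: dict[str, np.ndarray] = {}
    d_in = n_features
    for l in range(config.n_recurrent_layers):
        if config.architecture == "lstm":
            params[f"Wx{l}"] = _glorot(rng, d_in, 4 * H)
            params[f"Wh{l}"] = _glorot(rng, H, 4 * H)
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias: remember by default
            params[f"b{l}"] = b
        else:
            params[f"Wx{l}"] = _glorot(rng, d_in, H)
            params[f"Wh{l}"] = _glorot(rng, H, H)
            params[f"b{l}"] = np.zeros(H)
        d_in = H
    params["w_out"] = _glorot(rng, H, 1)
    params["b_out"] = np.zeros(1)
    return params


def _forward(params: dict, config: ModelConfig, x: np.ndarray):
    """x: (B, T, D).  Returns probabilities (B,) and per-layer caches."""
    B, T, _ = x.shape
    H = config.hidden_units
    seq = x
    caches = []
    for l in range(config.n_recurrent_layers):
        Wx, Wh, b = params[f"Wx{l}"], params[f"Wh{l}"], params[f"b{l}"]
        h = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        if config.architecture == "lstm":
            c = np.zeros((B, H))
            gates, cells, tanhc = [], [], []
            for t in range(T):
                z = seq[:, t] @ Wx + h @ Wh + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                hs[:, t] = h
                gates.append((i, f, g, o))
                cells.append(c)
                tanhc.append(tc)
            caches.append({"in": seq, "hs": hs, "gates": gates, "cells": cells, "tanhc": tanhc})
        else:
            pres = []
            for t in range(T):
                z = seq[:, t] @ Wx + h @ Wh + b
                h = np.tanh(z)
                hs[:, t] = h
                pres.append(h)
            caches.append({"in": seq, "hs": hs})
        seq = hs
    logits = hs[:, -1] @ params["w_out"] + params["b_out"]
    probs = _sigmoid(logits[:, 0])
    return probs, caches


def _backward(params: dict, config: ModelConfig, caches: list,
              probs: np.ndarray, y: np.ndarray, sample_w: np.ndarray) -> dict:
    B = y.shape[0]
    H = config.hidden_units
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dlogit = (probs - y) * sample_w / B  # (B,)
    top = caches[-1]["hs"][:, -1]
    grads["w_out"] = top.T @ dlogit[:, None]
    grads["b_out"] = np.array([dlogit.sum()])

    T = caches[0]["hs"].shape[1]
    # dh injected into each layer at each timestep from the layer above
    dh_from_above = np.zeros((B, T, H))
    dh_from_above[:, -1] = dlogit[:, None] * params["w_out"][:, 0]

    for l in reversed(range(config.n_recurrent_layers)):
        cache = caches[l]
        Wx, Wh = params[f"Wx{l}"], params[f"Wh{l}"]
        seq = cache["in"]
        d_seq = np.zeros_like(seq)
        dh_next = np.zeros((B, H))
        if config.architecture == "lstm":
            dc_next = np.zeros((B, H))
            for t in reversed(range(T)):
                dh = dh_next + dh_from_above[:, t]
                i, f, g, o = cache["gates"][t]
                c = cache["cells"][t]
                tc = cache["tanhc"][t]
                c_prev = cache["cells"][t - 1] if t > 0 else np.zeros_like(c)
                h_prev = cache["hs"][:, t - 1] if t > 0 else np.zeros((B, H))
                do = dh * tc
                dc = dc_next + dh * o * (1 - tc ** 2)
                di, dg, df = dc * g, dc * i, dc * c_prev
                dz = np.concatenate([
                    di * i * (1 - i), df * f * (1 - f),
                    dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
                grads[f"Wx{l}"] += seq[:, t].T @ dz
                grads[f"Wh{l}"] += h_prev.T @ dz
                grads[f"b{l}"] += dz.sum(axis=0)
                d_seq[:, t] = dz @ Wx.T
                dh_next = dz @ Wh.T
                dc_next = dc * f
        else:
            for t in reversed(range(T)):
                dh = dh_next + dh_from_above[:, t]
                h = cache["hs"][:, t]
                h_prev = cache["hs"][:, t - 1] if t > 0 else np.zeros((B, H))
                dz = dh * (1 - h ** 2)
                grads[f"Wx{l}"] += seq[:, t].T @ dz
                grads[f"Wh{l}"] += h_prev.T @ dz
                grads[f"b{l}"] += dz.sum(axis=0)
                d_seq[:, t] = dz @ Wx.T
                dh_next = dz @ Wh.T
        if l > 0:
            dh_from_above = d_seq
    return grads


@dataclass
class TrainedModel:
    """Fitted recurrent classifier plus everything needed to reapply it."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    feature_names: tuple[str, ...]
    input_lo: np.ndarray   # per-feature training minima (input normalization)
    input_hi: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def save(self, path) -> None:
        meta = json.dumps({"config": asdict(self.config),
                           "feature_names": list(self.feature_names),
                           "metadata": self.metadata})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 input_lo=self.input_lo, input_hi=self.input_hi, **self.params)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path if isinstance(path, io.IOBase) else str(path)) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {k: z[k] for k in z.files
                      if k not in ("__meta__", "input_lo", "input_hi")}
            return cls(params=params, config=ModelConfig(**meta["config"]),
                       feature_names=tuple(meta["feature_names"]),
                       input_lo=z["input_lo"], input_hi=z["input_hi"],
                       metadata=meta["metadata"])


def _stack(windows: list[FeatureWindow]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([w.x for w in windows]).astype(float)
    y = np.array([w.label for w in windows], dtype=float)
    return x, y


def _normalize(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = np.where(hi > lo, hi - lo, 1.0)
    return np.clip((x - lo) / span, 0.0, 1.0)


def _fit_once(x: np.ndarray, y: np.ndarray, config: ModelConfig,
              rng: np.random.Generator) -> dict[str, np.ndarray]:
    n, _, d = x.shape
    params = _init_params(config, d, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(p) for k, p in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    if config.class_weighted_loss:
        n_pos = max(1, int(y.sum()))
        w_pos = (n - n_pos) / n_pos
        sample_w_all = np.where(y == 1, w_pos, 1.0)
    else:
        sample_w_all = np.ones(n)
    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            probs, caches = _forward(params, config, x[idx])
            grads = _backward(params, config, caches, probs, y[idx], sample_w_all[idx])
            step += 1
            lr = config.learning_rate
            for k in params:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                mh = m[k] / (1 - b1 ** step)
                vh = v[k] / (1 - b2 ** step)
                params[k] -= lr * mh / (np.sqrt(vh) + eps)
    return params


def _batched_probs(params: dict, config: ModelConfig, x: np.ndarray,
                   chunk: int = 8192) -> np.ndarray:
    outs = []
    for s in range(0, x.shape[0], chunk):
        p, _ = _forward(params, config, x[s:s + chunk])
        outs.append(p)
    return np.concatenate(outs)


def train(windows: list[FeatureWindow], config: ModelConfig,
          grid: list[dict] | None = None) -> TrainedModel:
    """Fit the recurrent classifier on labelled windows.

    With a hyperparameter *grid* (a list of config-field override dicts), each
    candidate is scored by mean fold sensitivity under stratified k-fold
    cross-validation (``config.cv_folds``) and the best refit on all windows.
    """
    if not windows:
        raise TrainingError("no training windows")
    x, y = _stack(windows)
    if len(np.unique(y)) < 2:
        raise TrainingError("training set contains a single class")

    lo = x.min(axis=(0, 1))
    hi = x.max(axis=(0, 1))
    xn = _normalize(x, lo, hi)

    metadata: dict = {"n_windows": int(len(windows)), "n_positive": int(y.sum()),
                      "seed": config.seed}
    best_cfg = config
    if grid:
        scored = []
        for cand in grid:
            cfg = ModelConfig(**{**asdict(config), **cand})
            folds = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                                    random_state=cfg.seed)
            sens = []
            for fold_i, (tr, va) in enumerate(folds.split(xn, y)):
                rng = np.random.default_rng([cfg.seed, fold_i])
                p = _fit_once(xn[tr], y[tr], cfg, rng)
                probs = _batched_probs(p, cfg, xn[va])
                pred = probs >= cfg.decision_threshold
                tp = int(((y[va] == 1) & pred).sum())
                fn = int(((y[va] == 1) & ~pred).sum())
                sens.append(tp / (tp + fn) if tp + fn else 0.0)
            scored.append((float(np.mean(sens)), cand))
        scored.sort(key=lambda t: -t[0])
        metadata["cv_scores"] = [{"candidate": c, "mean_sensitivity": s} for s, c in scored]
        best_cfg = ModelConfig(**{**asdict(config), **scored[0][1]})

    rng = np.random.default_rng(best_cfg.seed)
    params = _fit_once(xn, y, best_cfg, rng)
    return TrainedModel(params=params, config=best_cfg,
                        feature_names=tuple(FEATURE_NAMES),
                        input_lo=lo, input_hi=hi, metadata=metadata)


def predict(model: TrainedModel, windows: list[FeatureWindow]) -> pd.DataFrame:
    """Per-window probabilities and threshold flags.

    Returns ``patient_id, end_date, probability, flag``; aggregate with
    :func:`predict_episodes` for episode-level decisions.
    """
    if not windows:
        return pd.DataFrame(columns=["patient_id", "end_date", "probability", "flag"])
    x, _ = _stack(windows)
    if x.shape[2] != len(model.feature_names):
        raise PredictionError(
            f"window feature dimension {x.shape[2]} does not match "
            f"training schema ({len(model.feature_names)})")
    xn = _normalize(x, model.input_lo, model.input_hi)
    probs = _batched_probs(model.params, model.config, xn)
    return pd.DataFrame({
        "patient_id": [w.patient_id for w in windows],
        "end_date": [w.end_date for w in windows],
        "probability": probs,
        "flag": probs >= model.config.decision_threshold,
    })


def predict_episodes(window_predictions: pd.DataFrame,
                     episodes: pd.DataFrame) -> pd.DataFrame:
    """Aggregate window predictions to episodes.

    flag = any flagged window; forecast_date = earliest flagged window end;
    score = maximum window probability (for ranking/AUC).
    """
    out = pd.DataFrame({"patient_id": episodes["patient_id"].to_numpy()})
    if len(window_predictions):
        grp = window_predictions.groupby("patient_id")
        max_prob = grp["probability"].max()
        flagged = window_predictions[window_predictions["flag"]]
        first = flagged.groupby("patient_id")["end_date"].min()
    else:
        max_prob = pd.Series(dtype=float)
        first = pd.Series(dtype=object)
    out["score"] = out["patient_id"].map(max_prob).fillna(0.0)
    out["flag"] = out["patient_id"].isin(first.index)
    out["forecast_date"] = out["patient_id"].map(first)
    return out
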