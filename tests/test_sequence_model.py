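import datetime as dt

import numpy as np
import pandas as pd
import pytest

from hhc_cdss.feature_encoding import FEATURE_NAMES, FeatureWindow
from hhc_cdss.sequence_model import (ModelConfig, TrainedModel, TrainingError,
                                     PredictionError, _backward, _forward,
                                     _init_params, predict, predict_episodes,
                                     split_hhc_cases, train,
                                     undersample_training_set)

D = len(FEATURE_NAMES)


def _window(pid, label, level, rng, end_day=10):
    x = np.clip(rng.normal(level, 0.05, size=(8, D)), 0, 1)
    return FeatureWindow(pid, dt.date(2019, 1, end_day), x, label)


def _separable_windows(n_pos=40, n_neg=160, seed=0):
    rng = np.random.default_rng(seed)
    wins = [_window(f"P{i}", 1, 0.8, rng) for i in range(n_pos)]
    wins += [_window(f"N{i}", 0, 0.2, rng) for i in range(n_neg)]
    return wins


class TestGradients:
    @pytest.mark.parametrize("arch", ["lstm", "rnn"])
    def test_backward_matches_numerical_gradient(self, arch):
        cfg = ModelConfig(architecture=arch, hidden_units=4, n_recurrent_layers=2)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 8, 3))
        y = (rng.random(5) < 0.5).astype(float)
        w = np.ones(5)
        params = _init_params(cfg, 3, rng)
        probs, caches = _forward(params, cfg, x)
        grads = _backward(params, cfg, caches, probs, y, w)

        def loss():
            p, _ = _forward(params, cfg, x)
            return float(np.mean(-(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12))))

        for k in params:
            flat = params[k].reshape(-1)
            for i in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[i]
                flat[i] = orig + 1e-5
                lp = loss()
                flat[i] = orig - 1e-5
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / 2e-5
                ana = grads[k].reshape(-1)[i]
                assert abs(num - ana) <= 1e-6 + 1e-3 * (abs(num) + abs(ana)), (arch, k)


class TestUndersampling:
    def test_exact_ratio(self):
        rng = np.random.default_rng(1)
        wins = [_window(f"P{i}", 1, 0.8, rng) for i in range(100)]
        wins += [_window(f"N{i}", 0, 0.2, rng) for i in range(10_000)]
        out = undersample_training_set(wins, 4, seed=0)
        assert len(out) == 500
        assert sum(w.label for w in out) == 100

    def test_clamp_with_warning_when_few_negatives(self):
        rng = np.random.default_rng(1)
        wins = [_window(f"P{i}", 1, 0.8, rng) for i in range(100)]
        wins += [_window(f"N{i}", 0, 0.2, rng) for i in range(200)]
        with pytest.warns(UserWarning, match="keeping all"):
            out = undersample_training_set(wins, 4, seed=0)
        assert len(out) == 300

    def test_deterministic_given_seed(self):
        wins = _separable_windows(50, 1000)
        a = undersample_training_set(wins, 4, seed=3)
        b = undersample_training_set(wins, 4, seed=3)
        assert [(w.patient_id, w.end_date) for w in a] == [(w.patient_id, w.end_date) for w in b]

    def test_requires_positives(self):
        wins = _separable_windows(1, 10)[1:]
        with pytest.raises(TrainingError):
            undersample_training_set(wins, 4, seed=0)


class TestSplit:
    @staticmethod
    def _episodes(n_pos, n_neg):
        return pd.DataFrame({
            "patient_id": [f"E{i}" for i in range(n_pos + n_neg)],
            "hhc_label": [True] * n_pos + [False] * n_neg,
        })

    def test_552_cases_split_evenly(self):
        train_e, test_e = split_hhc_cases(self._episodes(552, 5000), seed=0)
        assert int(train_e["hhc_label"].sum()) == 276
        assert int(test_e["hhc_label"].sum()) == 276
        assert set(train_e["patient_id"]).isdisjoint(test_e["patient_id"])

    def test_odd_count(self):
        train_e, test_e = split_hhc_cases(self._episodes(3, 10), seed=0)
        assert {int(train_e["hhc_label"].sum()), int(test_e["hhc_label"].sum())} == {1, 2}

    def test_prevalence_preserved(self):
        train_e, test_e = split_hhc_cases(self._episodes(100, 9900), seed=1)
        p_train = train_e["hhc_label"].mean()
        p_test = test_e["hhc_label"].mean()
        assert p_train == pytest.approx(p_test, rel=0.1)

    def test_deterministic(self):
        a = split_hhc_cases(self._episodes(10, 100), seed=2)
        b = split_hhc_cases(self._episodes(10, 100), seed=2)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_too_few_positives(self):
        with pytest.raises(TrainingError):
            split_hhc_cases(self._episodes(1, 10), seed=0)


class TestTraining:
    def test_separable_data_reaches_high_training_sensitivity(self):
        wins = _separable_windows()
        cfg = ModelConfig(epochs=15, seed=0)
        model = train(wins, cfg)
        preds = predict(model, wins)
        labels = np.array([w.label for w in wins])
        flagged = preds["flag"].to_numpy()
        sens = (flagged & (labels == 1)).sum() / (labels == 1).sum()
        assert sens >= 0.95

    def test_architectures_have_different_parameter_counts(self):
        wins = _separable_windows(10, 40)
        lstm = train(wins, ModelConfig(architecture="lstm", epochs=1, seed=0))
        rnn = train(wins, ModelConfig(architecture="rnn", epochs=1, seed=0))
        assert lstm.n_parameters != rnn.n_parameters
        assert lstm.n_parameters > rnn.n_parameters  # 4 gate blocks vs 1

    def test_serialization_round_trip_bit_identical(self, tmp_path):
        wins = _separable_windows(20, 80)
        model = train(wins, ModelConfig(epochs=2, seed=1))
        path = tmp_path / "model.npz"
        model.save(path)
        reloaded = TrainedModel.load(path)
        fixed = _separable_windows(50, 50, seed=9)[:100]
        p1 = predict(model, fixed)["probability"].to_numpy()
        p2 = predict(reloaded, fixed)["probability"].to_numpy()
        assert (p1 == p2).all()

    def test_training_deterministic_given_seed(self):
        wins = _separable_windows(20, 80)
        m1 = train(wins, ModelConfig(epochs=3, seed=5))
        m2 = train(wins, ModelConfig(epochs=3, seed=5))
        for k in m1.params:
            assert (m1.params[k] == m2.params[k]).all()

    def test_single_class_training_rejected(self):
        wins = [w for w in _separable_windows() if w.label == 0]
        with pytest.raises(TrainingError):
            train(wins, ModelConfig(epochs=1))

    def test_grid_selection_records_cv_scores(self):
        wins = _separable_windows(40, 160)
        cfg = ModelConfig(epochs=2, cv_folds=3, seed=0)
        model = train(wins, cfg, grid=[{"hidden_units": 4}, {"hidden_units": 8}])
        assert len(model.metadata["cv_scores"]) == 2
        assert model.config.hidden_units in (4, 8)


class TestPrediction:
    def test_probabilities_bounded(self):
        wins = _separable_windows(20, 80)
        model = train(wins, ModelConfig(epochs=2, seed=0))
        rng = np.random.default_rng(0)
        noise = [FeatureWindow("X", dt.date(2019, 1, 1),
                               rng.normal(0.5, 2, size=(8, D)), 0) for _ in range(50)]
        p = predict(model, noise)["probability"].to_numpy()
        assert ((p >= 0) & (p <= 1)).all()

    def test_threshold_domain_validated(self):
        with pytest.raises(ValueError):
            ModelConfig(decision_threshold=1.01)

    def test_raising_threshold_never_increases_flags(self):
        wins = _separable_windows(20, 80)
        model = train(wins, ModelConfig(epochs=2, seed=0))
        counts = []
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            model.config.decision_threshold = thr
            counts.append(int(predict(model, wins)["flag"].sum()))
        assert counts == sorted(counts, reverse=True)

    def test_schema_mismatch_rejected(self):
        wins = _separable_windows(20, 80)
        model = train(wins, ModelConfig(epochs=1, seed=0))
        rng = np.random.default_rng(0)
        bad = [FeatureWindow("X", dt.date(2019, 1, 1), rng.random((8, D + 1)), 0)]
        with pytest.raises(PredictionError):
            predict(model, bad)

    def test_episode_aggregation_uses_earliest_flagged_window(self):
        episodes = pd.DataFrame({"patient_id": ["A", "B"]})
        preds = pd.DataFrame({
            "patient_id": ["A", "A", "B"],
            "end_date": [dt.date(2019, 1, 9), dt.date(2019, 1, 8), dt.date(2019, 1, 8)],
            "probability": [0.9, 0.7, 0.2],
            "flag": [True, True, False],
        })
        out = predict_episodes(preds, episodes)
        a = out[out["patient_id"] == "A"].iloc[0]
        b = out[out["patient_id"] == "B"].iloc[0]
        assert bool(a["flag"]) and a["forecast_date"] == dt.date(2019, 1, 8)
        assert a["score"] == 0.9
        assert not bool(b["flag"]) and b["score"] == 0.2
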