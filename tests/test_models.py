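"""Fold construction, feature regression, numpy CNN, Grad-CAM."""

import numpy as np
import pandas as pd
import pytest

from pulseage import cohort, models as mdl
from pulseage.nn import CNN1D, CNNConfig, TrainConfig, fit, receptive_field


class TestMakeFolds:
    def test_partition_and_sizes_at_study_scale(self):
        ids = [f"p{i:03d}" for i in range(160)]
        folds = mdl.make_folds(ids, k=10, seed=1)
        all_test = [p for f in folds for p in f.test]
        assert sorted(all_test) == sorted(ids)
        for f in folds:
            assert len(f.test) == 16
            assert len(f.val) == 16
            assert len(f.train) == 128
            f.assert_disjoint()

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(40)]
        assert mdl.make_folds(ids, 5, seed=3) == mdl.make_folds(ids, 5, seed=3)
        assert mdl.make_folds(ids, 5, seed=3) != mdl.make_folds(ids, 5, seed=4)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            mdl.make_folds(["a", "b"], k=3, seed=0)


class TestSelectPulses:
    def test_exclusion_below_threshold(self):
        rng = np.random.default_rng(0)
        pulses = {
            "short": rng.random((369, 200)),
            "exact": rng.random((370, 200)),
            "long": rng.random((400, 200)),
        }
        selected, excluded = mdl.select_pulses(pulses, n=370, seed=1)
        assert excluded == ["short"]
        assert selected["exact"].shape == (370, 200)
        assert selected["long"].shape == (370, 200)

    def test_seeds_give_different_subsets_of_same_size(self):
        pulses = {"p": np.arange(50 * 200, dtype=float).reshape(50, 200)}
        a, _ = mdl.select_pulses(pulses, n=20, seed=1)
        b, _ = mdl.select_pulses(pulses, n=20, seed=2)
        assert a["p"].shape == b["p"].shape == (20, 200)
        assert not np.array_equal(a["p"], b["p"])


class TestFeatureRegression:
    def test_exact_recovery_of_linear_target(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame({
            "ct": rng.normal(40, 5, 50),
            "dt": rng.normal(60, 8, 50),
            "ri": rng.normal(0.6, 0.1, 50),
        })
        ages = 2.0 * feats.ct - 0.5 * feats.dt + 30 * feats.ri + 5.0
        reg = mdl.fit_feature_regression(feats, ages.to_numpy())
        pred = reg.predict(feats)
        assert np.max(np.abs(pred - ages)) < 1e-8

    def test_permuted_ages_give_null_cv_correlation(self):
        rng = np.random.default_rng(1)
        n = 160
        ids = [f"p{i:03d}" for i in range(n)]
        feats = pd.DataFrame({
            "participant": ids,
            "ct": rng.normal(40, 5, n),
            "dt": rng.normal(60, 8, n),
            "ri": rng.normal(0.6, 0.1, n),
        })
        ages = 2.0 * feats.ct.to_numpy() + rng.normal(0, 5, n)
        feats["age"] = rng.permutation(ages)  # break the association
        folds = mdl.make_folds(ids, 10, seed=2)
        preds = mdl.regression_cv(feats, folds)
        r = np.corrcoef(preds["age"], preds["predicted"])[0, 1]
        assert abs(r) < 0.2

    def test_too_few_participants_rejected(self):
        feats = pd.DataFrame({"ct": [1, 2, 3], "dt": [1, 2, 3],
                              "ri": [1, 2, 3]})
        with pytest.raises(ValueError):
            mdl.fit_feature_regression(feats, np.array([1.0, 2.0, 3.0]))


class TestCNNConfig:
    @pytest.mark.parametrize(
        "conv,expected",
        [
            (((16, 11), (32, 9)), 19),
            (((4, 7),), 7),
            (((4, 5), (4, 3), (4, 3)), 9),
        ],
    )
    def test_receptive_field(self, conv, expected):
        cfg = CNNConfig(conv=conv, fc=(8,))
        assert receptive_field(cfg) == expected

    def test_kernel_exceeding_input_rejected(self):
        with pytest.raises(ValueError):
            CNNConfig(input_length=8, conv=((4, 11),), fc=(8,))


class TestCNNTraining:
    def _toy_data(self, n=200, seed=0):
        """Pulses whose systolic position encodes age linearly."""
        rng = np.random.default_rng(seed)
        ages = rng.uniform(20, 70, n)
        x = np.linspace(0, 1, 200)
        pulses = np.stack([
            np.exp(-0.5 * ((x - (0.1 + 0.004 * (a - 20))) / 0.05) ** 2)
            for a in ages
        ]).astype(np.float32)
        return pulses, ages.astype(np.float32)

    def test_constant_target_learned(self):
        pulses, _ = self._toy_data(120)
        y = np.full(120, 43.0, dtype=np.float32)
        cfg = CNNConfig(conv=((4, 11), (4, 9)), fc=(16,), dropout=0.0)
        model = CNN1D(cfg, seed=0)
        res = fit(model, pulses[:100], y[:100], pulses[100:], y[100:],
                  TrainConfig(lr=1e-2, batch_size=32, max_epochs=60,
                              patience=60), seed=0)
        pred = model.predict(pulses[100:])
        assert np.all(np.abs(pred - 43.0) < 1.0)

    def test_age_encoded_in_peak_position_is_learned(self):
        pulses, ages = self._toy_data(400, seed=1)
        cfg = CNNConfig(conv=((8, 11), (8, 9)), fc=(32,), dropout=0.0)
        model = CNN1D(cfg, seed=1)
        res = fit(model, pulses[:320], ages[:320], pulses[320:], ages[320:],
                  TrainConfig(lr=1e-3, batch_size=64, max_epochs=80,
                              patience=20), seed=1)
        assert res.best_val_mae < 4.0

    def test_single_point_grid_chosen(self):
        pulses, ages = self._toy_data(60, seed=2)
        tr = {"a": pulses[:20], "b": pulses[20:40]}
        va = {"c": pulses[40:]}
        age_map = {"a": 30.0, "b": 50.0, "c": 40.0}
        grid = [TrainConfig(lr=1e-3, batch_size=16, max_epochs=2, patience=2)]
        out = mdl.train_cnn(tr, va, age_map, grid=grid,
                            cfg=CNNConfig(conv=((2, 11), (2, 9)), fc=(8,)),
                            seed=0)
        assert out.chosen is grid[0]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            mdl.train_cnn({"a": np.zeros((1, 200))}, {"b": np.zeros((1, 200))},
                          {"a": 1.0, "b": 2.0}, grid=[])

    def test_leakage_rejected(self):
        with pytest.raises(AssertionError):
            mdl.train_cnn(
                {"a": np.zeros((1, 200))}, {"a": np.zeros((1, 200))},
                {"a": 30.0}, grid=[TrainConfig()],
            )

    def test_training_reproducible(self):
        pulses, ages = self._toy_data(80, seed=3)
        cfg = CNNConfig(conv=((2, 11), (2, 9)), fc=(8,), dropout=0.2)
        tc = TrainConfig(lr=1e-3, batch_size=16, max_epochs=3, patience=3)
        runs = []
        for _ in range(2):
            model = CNN1D(cfg, seed=5)
            fit(model, pulses[:60], ages[:60], pulses[60:], ages[60:], tc,
                seed=5)
            runs.append(model.predict(pulses[60:]))
        np.testing.assert_array_equal(runs[0], runs[1])


class TestPredictParticipant:
    def test_median_aggregation(self):
        class Fake:
            def __init__(self, vals):
                self.vals = np.asarray(vals, dtype=float)

            def predict(self, x):
                return self.vals

        assert mdl.predict_participant(Fake([7.0, 7.0, 7.0]),
                                       np.zeros((3, 200))) == 7.0
        assert mdl.predict_participant(Fake([30.0, 40.0, 90.0]),
                                       np.zeros((3, 200))) == 40.0

    def test_no_pulses_rejected(self):
        with pytest.raises(ValueError):
            mdl.predict_participant(None, np.zeros((0, 200)))


class TestGradCAM:
    def test_zero_head_gives_zero_map(self):
        cfg = CNNConfig(conv=((4, 11), (4, 9)), fc=(8,), dropout=0.0)
        model = CNN1D(cfg, seed=0)
        model.W[-1][:] = 0.0
        maps = mdl.grad_cam(model, np.random.default_rng(0)
                            .random((10, 200)).astype(np.float32))
        assert maps["all"].shape == (200,)
        np.testing.assert_array_equal(maps["all"], np.zeros(200))

    def test_maps_bounded_and_grouped(self):
        cfg = CNNConfig(conv=((4, 11), (4, 9)), fc=(8,), dropout=0.0)
        model = CNN1D(cfg, seed=1)
        rng = np.random.default_rng(1)
        pulses = rng.random((30, 200)).astype(np.float32)
        ages = rng.uniform(20, 70, 30)
        maps = mdl.grad_cam(model, pulses, ages)
        assert set(maps) == {"all", "20-39", "40-59", ">=60"}
        for m in maps.values():
            assert m.shape == (200,)
            assert m.min() >= 0.0 and m.max() <= 1.0

    def test_relevance_concentrates_on_informative_region(self):
        # age encoded solely in the systolic upstroke position; a
        # trained model's group map must put its mass in that region
        rng = np.random.default_rng(4)
        ages = rng.uniform(20, 70, 300).astype(np.float32)
        x = np.linspace(0, 1, 200)
        pulses = np.stack([
            np.exp(-0.5 * ((x - (0.12 + 0.003 * (a - 20))) / 0.05) ** 2)
            for a in ages
        ]).astype(np.float32)
        cfg = CNNConfig(conv=((8, 11), (8, 9)), fc=(32,), dropout=0.0)
        model = CNN1D(cfg, seed=2)
        fit(model, pulses[:240], ages[:240], pulses[240:], ages[240:],
            TrainConfig(lr=1e-3, batch_size=64, max_epochs=60, patience=15),
            seed=2)
        maps = mdl.grad_cam(model, pulses)
        m = maps["all"]
        # informative region: samples 10..80 covers all upstrokes
        assert m[:90].sum() > m[90:].sum()


class TestCnnCV:
    def test_each_participant_predicted_once(self):
        rng = np.random.default_rng(0)
        ids = [f"p{i}" for i in range(12)]
        ages = {p: float(25 + 3 * i) for i, p in enumerate(ids)}
        pulses = {p: rng.random((6, 200)).astype(np.float32) for p in ids}
        folds = mdl.make_folds(ids, k=3, seed=0)
        grid = [TrainConfig(lr=1e-3, batch_size=8, max_epochs=2, patience=2)]
        preds, outcomes = mdl.cnn_cv(
            pulses, ages, folds, grid=grid,
            cfg=CNNConfig(conv=((2, 11), (2, 9)), fc=(8,)), seed=0)
        assert sorted(preds["participant"]) == sorted(ids)
        assert preds["participant"].is_unique
        assert len(outcomes) == 3
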