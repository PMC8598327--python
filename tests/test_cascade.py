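"""Cascade: stratified folds, out-of-fold layers, growth and persistence."""

import numpy as np
import pytest

from grainrisk import (
    DSNConfig,
    DeepStackingNetwork,
    LayerSpec,
    ScanConfig,
    augment,
    make_roster,
    stratified_folds,
    train_layer,
)

LIGHT_SCAN = ScanConfig(windows=(2, 4), stride=2, n_estimators=5, max_depth=6)


def light_config(**kw):
    base = dict(
        k_folds=3,
        max_layers=2,
        scan=LIGHT_SCAN,
        n_estimators=10,
        gb_max_iter=5,
        lr_max_iter=20,
        epochs=25,
        seed=0,
    )
    base.update(kw)
    return DSNConfig(**base)


class TestStratifiedFolds:
    def test_balanced_classes_split_exactly(self):
        y = np.repeat(np.arange(4), 25)
        folds = stratified_folds(y, 5, seed=0)
        for f in range(5):
            assert (folds == f).sum() == 20
            for c in range(4):
                assert ((folds == f) & (y == c)).sum() == 5

    def test_remainder_distributed_within_one(self):
        y = np.array([0] * 23 + [1] * 25)
        folds = stratified_folds(y, 5, seed=3)
        counts = sorted(np.bincount(folds[y == 0]), reverse=True)
        assert counts == [5, 5, 5, 4, 4]

    def test_deterministic_under_seed(self):
        y = np.repeat(np.arange(3), 20)
        np.testing.assert_array_equal(
            stratified_folds(y, 4, seed=9), stratified_folds(y, 4, seed=9)
        )

    def test_small_class_rejected_by_name(self):
        y = np.array([0] * 20 + [1] * 3)
        with pytest.raises(ValueError, match=r"\[1\]"):
            stratified_folds(y, 5, seed=0)


def separable_problem(n=120, P=3, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, P, n)
    X = rng.normal(scale=0.1, size=(n, 4))
    X[:, 0] += y * 3.0  # widely separated clusters
    return X, y


class TestTrainLayer:
    def spec(self, seed=0, K=4, P=3):
        return LayerSpec(roster=make_roster(seed, light_config()), k_folds=K, seed=seed, n_classes=P)

    def test_oof_matrix_shape_and_normalization(self):
        X, y = separable_problem()
        layer = train_layer(X, y, self.spec())
        assert layer.oof.shape == (120, 3 * 4)  # P * roster size
        np.testing.assert_allclose(layer.oof.reshape(120, 4, 3).sum(axis=2), 1.0, atol=1e-9)

    def test_layer_accuracy_is_mean_of_fold_accuracies(self):
        X, y = separable_problem()
        layer = train_layer(X, y, self.spec())
        assert layer.accuracy == pytest.approx(np.mean(layer.fold_accuracies))
        assert len(layer.fold_accuracies) == 4

    def test_out_of_fold_discipline(self):
        X, y = separable_problem()
        layer = train_layer(X, y, self.spec())
        # sample i's out-of-fold row came from the fold whose training
        # indices exclude i
        for i in range(len(y)):
            fold = layer.fold_of[i]
            assert i not in layer.fold_train_indices[fold]
        # folds partition all indices
        assert np.bincount(layer.fold_of).sum() == len(y)

    def test_separable_data_reaches_high_accuracy(self):
        X, y = separable_problem(n=200)
        layer = train_layer(X, y, self.spec())
        assert layer.accuracy >= 0.95

    def test_non_finite_input_rejected(self):
        X, y = separable_problem()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train_layer(X, y, self.spec())


class TestAugment:
    def test_width_is_original_plus_probability_blocks(self, rng):
        X = rng.random((20, 33))
        out = rng.random((20, 32))  # P=8, roster of 4
        assert augment(X, out).shape == (20, 65)

    def test_original_columns_preserved_bitwise(self, rng):
        X = rng.random((10, 5))
        Z = augment(X, np.full((10, 2), 0.5))
        np.testing.assert_array_equal(Z[:, :5], X)

    def test_next_layer_width_not_cumulative(self, rng):
        # layer 2 consumes original + layer-1 output only
        X = rng.random((15, 20))
        out1 = rng.random((15, 12))
        out2 = rng.random((15, 12))
        z1 = augment(X, out1)
        z2 = augment(X, out2)
        assert z1.shape == z2.shape == (15, 32)

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="row mismatch"):
            augment(rng.random((5, 2)), rng.random((6, 2)))


class TestDeepStackingNetwork:
    def test_infinite_tolerance_retains_one_layer(self, small_split):
        tr, _, ylab, _ = small_split
        model = DeepStackingNetwork(light_config(tol=np.inf, max_layers=3)).fit(tr, ylab)
        assert model.best_depth_ == 1

    def test_trace_matches_layers_and_eq4(self, small_split):
        tr, _, ylab, _ = small_split
        model = DeepStackingNetwork(light_config()).fit(tr, ylab)
        assert len(model.trace_) >= model.best_depth_
        for entry in model.trace_:
            assert entry["E"] == pytest.approx(np.mean(entry["E_i"]))
        best = max(t["E"] for t in model.trace_)
        assert model.trace_[model.best_depth_ - 1]["E"] == pytest.approx(best)

    def test_identical_seeds_identical_predictions(self, small_split):
        tr, te, ylab, _ = small_split
        p1 = DeepStackingNetwork(light_config(seed=5)).fit(tr, ylab).predict_proba(te)
        p2 = DeepStackingNetwork(light_config(seed=5)).fit(tr, ylab).predict_proba(te)
        np.testing.assert_array_equal(p1, p2)

    def test_probabilities_sum_to_one_and_tie_break_lowest(self, small_split):
        tr, te, ylab, _ = small_split
        model = DeepStackingNetwork(light_config()).fit(tr, ylab)
        pred, proba = model.predict(te)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(pred, proba.argmax(axis=1))

    def test_training_reprediction_at_least_oof_accuracy(self, small_split):
        tr, _, ylab, _ = small_split
        model = DeepStackingNetwork(light_config()).fit(tr, ylab)
        from grainrisk import encode_labels

        pred, _ = model.predict(tr)
        final_E = model.trace_[model.best_depth_ - 1]["E"]
        assert (pred == encode_labels(ylab)).mean() >= final_E - 1e-9

    def test_single_class_rejected(self, small_split):
        tr, _, ylab, _ = small_split
        with pytest.raises(ValueError, match="2 classes"):
            DeepStackingNetwork(light_config()).fit(tr, ["I"] * len(tr))

    def test_too_few_samples_rejected(self, small_dataset):
        records, labels = small_dataset
        with pytest.raises(ValueError, match="samples"):
            DeepStackingNetwork(light_config(k_folds=5)).fit(records.head(8), labels.head(8))

    def test_architecture_1_skips_scanning(self, small_split):
        tr, te, ylab, _ = small_split
        model = DeepStackingNetwork(light_config(architecture=1)).fit(tr, ylab)
        assert model.scanner_ is None
        pred, proba = model.predict(te)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_archive_round_trip(self, small_split, tmp_path):
        tr, te, ylab, _ = small_split
        model = DeepStackingNetwork(light_config()).fit(tr, ylab)
        path = tmp_path / "model.dsn"
        model.save(path)
        loaded = DeepStackingNetwork.load(path)
        np.testing.assert_array_equal(loaded.predict_proba(te), model.predict_proba(te))

    def test_archive_version_checked(self, small_split, tmp_path):
        import json
        import zipfile

        tr, _, ylab, _ = small_split
        model = DeepStackingNetwork(light_config()).fit(tr, ylab)
        path = tmp_path / "model.dsn"
        model.save(path)
        # tamper with the manifest version
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            blob = zf.read("learners.joblib")
        manifest["format_version"] = 999
        bad = tmp_path / "bad.dsn"
        with zipfile.ZipFile(bad, "w") as zf:
            zf.writestr("manifest.json", json.dumps(manifest))
            zf.writestr("learners.joblib", blob)
        with pytest.raises(ValueError, match="format"):
            DeepStackingNetwork.load(bad)
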