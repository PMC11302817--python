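import numpy as np
import pytest

from cylqa.dataset import augment, instances_to_arrays, make_split, normalize_pair
from cylqa.model import (BATCH_GRID, EPOCH_GRID, LR_GRID, CNN, CNNConfig,
                         FoldEnsemble, TrainConfig, build_cnn, crossval_train,
                         grid_search, load_ensemble, predict, save_ensemble,
                         train_fold)

TABLE_TRACE = [(16, 21, 66), (16, 10, 33), (32, 10, 33), (32, 5, 16),
               (64, 5, 16), (64,), (128,), (5,)]


class TestBuildCNN:
    def test_activation_trace(self):
        model = build_cnn(seed=0)
        assert model.activation_shapes() == TABLE_TRACE

    def test_softmax_on_zero_input(self):
        model = build_cnn(seed=0)
        out = model.forward_proba(np.zeros((1, 2, 21, 66), dtype=np.float32))
        assert out.shape == (1, 5)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert out.min() >= 0

    def test_same_seed_identical_parameters(self):
        a, b = build_cnn(seed=7), build_cnn(seed=7)
        for la, lb in zip(a.layers, b.layers):
            for k in la.params:
                np.testing.assert_array_equal(la.params[k], lb.params[k])

    def test_different_seed_differs(self):
        a, b = build_cnn(seed=1), build_cnn(seed=2)
        assert not np.array_equal(a.layers[0].params["W"],
                                  b.layers[0].params["W"])

    def test_simplex_on_random_input(self):
        model = build_cnn(seed=3)
        rng = np.random.default_rng(0)
        out = model.forward_proba(
            rng.random((9, 2, 21, 66)).astype(np.float32))
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)
        assert (out >= 0).all()


class TestTrainFold:
    def _separable(self, n=20):
        rng = np.random.default_rng(0)
        x = np.zeros((n, 2, 21, 66), dtype=np.float32)
        y = np.zeros((n, 5), dtype=np.float32)
        for i in range(n):
            cls = i % 5
            x[i] = 0.1 + 0.02 * rng.random((2, 21, 66))
            x[i, :, 4 * cls:4 * cls + 4, 10:30] += 0.5  # class-coded stripe
            y[i, cls] = 1.0
        return x, y

    def test_overfits_separable_toy_data(self):
        x, y = self._separable()
        model = build_cnn(seed=0)
        train_fold(model, x, y, TrainConfig(epochs=200, batch_size=4,
                                            lr=1e-3, seed=0))
        acc = (model.forward_proba(x).argmax(1) == y.argmax(1)).mean()
        assert acc == 1.0

    def test_zero_lr_keeps_parameters(self):
        x, y = self._separable(10)
        model = build_cnn(seed=0)
        before = [lay.params["W"].copy() for lay in model.layers
                  if "W" in lay.params]
        train_fold(model, x, y, TrainConfig(epochs=2, batch_size=4,
                                            lr=0.0, seed=0))
        after = [lay.params["W"] for lay in model.layers if "W" in lay.params]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_loss_decreases(self):
        x, y = self._separable()
        model = build_cnn(seed=1)
        history = train_fold(model, x, y, TrainConfig(epochs=30, batch_size=4,
                                                      lr=1e-3, seed=1))
        assert history["loss"][-1] < history["loss"][0]

    def test_empty_training_set_rejected(self):
        model = build_cnn(seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_fold(model, np.zeros((0, 2, 21, 66)), np.zeros((0, 5)),
                       TrainConfig(epochs=1))


@pytest.fixture(scope="module")
def small_cv_setup():
    from cylqa.simulate import SimConfig, generate_dataset
    ds = generate_dataset(SimConfig(n_per_class=20, noise_sigma=0.0, seed=13))
    split = make_split(ds, seed=0, test_fraction=0.25)
    by_id = {s.plan_id: s for s in ds}
    instances = augment([normalize_pair(by_id[p]) for p in split.train_ids],
                        factor=5, seed=0)
    return instances, split


class TestCrossvalAndPredict:
    def test_fold_sizes(self, small_cv_setup):
        instances, split = small_cv_setup
        fold_of = {p: k for k, f in enumerate(split.folds) for p in f}
        counts = np.bincount([fold_of[i.plan_id] for i in instances],
                             minlength=5)
        # 75 train plans, 15 per fold, x5 augmentation
        assert counts.tolist() == [75, 75, 75, 75, 75]

    def test_ensemble_shape_and_simplex(self, small_cv_setup):
        instances, split = small_cv_setup
        ens = crossval_train(instances, split,
                             TrainConfig(epochs=1, batch_size=8, lr=1e-3))
        assert len(ens.models) == 5
        probs, labels = predict(ens, instances[:7])
        assert probs.shape == (7, 5)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert labels.shape == (7,)

    def test_reproducible(self, small_cv_setup):
        instances, split = small_cv_setup
        cfg = TrainConfig(epochs=1, batch_size=8, lr=1e-3, seed=5)
        p1, _ = predict(crossval_train(instances, split, cfg), instances[:4])
        p2, _ = predict(crossval_train(instances, split, cfg), instances[:4])
        np.testing.assert_array_equal(p1, p2)

    def test_identical_fold_models_equal_single(self, small_cv_setup):
        instances, split = small_cv_setup
        model = build_cnn(seed=0)
        ens = FoldEnsemble(models=[model] * 5, fold_val_accuracy=[1.0] * 5,
                           train_config=TrainConfig())
        x, _, _ = instances_to_arrays(instances[:3])
        np.testing.assert_allclose(ens.predict_proba(x),
                                   model.forward_proba(x), atol=1e-7)

    def test_wrong_member_count_rejected(self):
        with pytest.raises(ValueError, match="5"):
            FoldEnsemble(models=[build_cnn(seed=0)], fold_val_accuracy=[1.0],
                         train_config=TrainConfig())


class TestPredictArithmetic:
    class _Const:
        def __init__(self, vec):
            self.vec = np.asarray(vec, dtype=float)
            self.config = CNNConfig()

        def forward_proba(self, x, train=False):
            return np.tile(self.vec, (len(x), 1))

    def test_averaging(self):
        members = [self._Const([1, 0, 0, 0, 0])] * 4 \
            + [self._Const([0, 1, 0, 0, 0])]
        ens = FoldEnsemble(models=members, fold_val_accuracy=[1.0] * 5,
                           train_config=TrainConfig())
        probs, labels = predict(ens, np.zeros((3, 2, 21, 66)))
        np.testing.assert_allclose(probs[0], [0.8, 0.2, 0, 0, 0])
        assert labels[0] == 0

    def test_tie_breaks_to_lowest_index(self):
        members = [self._Const([0, 0.5, 0, 0.5, 0])] * 5
        ens = FoldEnsemble(models=members, fold_val_accuracy=[1.0] * 5,
                           train_config=TrainConfig())
        _, labels = predict(ens, np.zeros((1, 2, 21, 66)))
        assert labels[0] == 1


class TestGridSearch:
    def test_grid_size_counts(self):
        assert len(EPOCH_GRID) * len(BATCH_GRID) * len(LR_GRID) == 48

    def test_default_config_is_paper_choice(self):
        cfg = TrainConfig()
        assert (cfg.epochs, cfg.batch_size, cfg.lr) == (500, 16, 0.0005)

    def test_singleton_grid(self, small_cv_setup, monkeypatch):
        instances, split = small_cv_setup
        # avoid real 300-epoch training in a unit test
        import cylqa.model as m

        def fake_cv(inst, sp, cfg, cnn_config=CNNConfig()):
            return FoldEnsemble(models=[build_cnn(seed=0)] * 5,
                                fold_val_accuracy=[0.5] * 5,
                                train_config=cfg)

        monkeypatch.setattr(m, "crossval_train", fake_cv)
        best = m.grid_search(instances, split, epochs_grid=[300],
                             batch_grid=[32], lr_grid=[0.001])
        assert (best.epochs, best.batch_size, best.lr) == (300, 32, 0.001)

    def test_off_grid_rejected(self, small_cv_setup):
        instances, split = small_cv_setup
        with pytest.raises(ValueError, match="grid"):
            grid_search(instances, split, epochs_grid=[123])

    def test_empty_grid_rejected(self, small_cv_setup):
        instances, split = small_cv_setup
        with pytest.raises(ValueError, match="empty"):
            grid_search(instances, split, epochs_grid=[])


class TestSerialization:
    def test_save_load_roundtrip(self, small_cv_setup, tmp_path):
        instances, split = small_cv_setup
        ens = crossval_train(instances, split,
                             TrainConfig(epochs=1, batch_size=8, lr=1e-3))
        save_ensemble(ens, tmp_path / "model")
        loaded = load_ensemble(tmp_path / "model")
        x, _, _ = instances_to_arrays(instances[:5])
        np.testing.assert_allclose(loaded.predict_proba(x),
                                   ens.predict_proba(x), atol=1e-7)
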