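"""Classifier: init, forward pass, training, transfer, evaluation, I/O."""

import numpy as np
import pytest

from bowtienet import (
    NetworkSpec, NoiseModel, TrainingConfig,
    evaluate, init_network, load_model, make_prototypes, sample_dataset,
    save_model, train, transfer_train, apply_input_zeroing,
)
from bowtienet.nnet import DivergenceError, ModelFormatError


class TestInit:
    def test_same_seed_gives_identical_weights(self):
        spec = NetworkSpec(12, 8, 5)
        a, b = init_network(spec, 3), init_network(spec, 3)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_softmax_outputs_normalise(self, trained_small):
        X = np.vstack([np.zeros(12), np.random.default_rng(0).normal(size=(5, 12))])
        probs = trained_small.predict_proba(X)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_untrained_accuracy_near_chance(self):
        # balanced validation data => any label-independent predictor sits at 1/C
        protos = make_prototypes(15, 30, rng_seed=20)
        ds = sample_dataset(protos, NoiseModel(20), n_per_class=150, rng_seed=21)
        for seed in range(5):
            model = init_network(NetworkSpec(30, 20, 15), seed)
            acc = evaluate(model, ds, "validation")
            assert 1 / 15 - 0.03 <= acc <= 1 / 15 + 0.10

    def test_invalid_widths_raise(self):
        with pytest.raises(ValueError):
            NetworkSpec(12, 0, 5)
        with pytest.raises(ValueError):
            NetworkSpec(0, 3, 5)


class TestTraining:
    def test_zero_epochs_is_noop(self, small_ds):
        model = init_network(NetworkSpec(12, 8, 5), 4)
        out = train(model, small_ds, TrainingConfig(epochs=0))
        for wa, wb in zip(model.weights, out.weights):
            assert np.array_equal(wa, wb)

    def test_training_is_bitwise_deterministic(self, small_ds, tiny_cfg):
        model = init_network(NetworkSpec(12, 8, 5), 5)
        a = train(model, small_ds, tiny_cfg)
        b = train(model, small_ds, tiny_cfg)
        for wa, wb in zip(a.weights + a.biases, b.weights + b.biases):
            assert np.array_equal(wa, wb)
        assert a.history == b.history

    def test_input_model_not_modified(self, small_ds, tiny_cfg):
        model = init_network(NetworkSpec(12, 8, 5), 6)
        before = [w.copy() for w in model.weights]
        train(model, small_ds, tiny_cfg)
        for w0, w1 in zip(before, model.weights):
            assert np.array_equal(w0, w1)

    def test_separable_classes_are_fit_to_high_accuracy(self):
        protos = make_prototypes(5, 12, rng_seed=22)
        ds = sample_dataset(protos, NoiseModel(1e6), n_per_class=120, rng_seed=23)
        model = init_network(NetworkSpec(12, 8, 5), 24)
        cfg = TrainingConfig(epochs=150, batch_size=64, rng_seed=25)
        trained = train(model, ds, cfg)
        assert evaluate(trained, ds, "train") >= 0.99

    def test_loss_descends_over_training(self, trained_small):
        hist = trained_small.history["loss"]
        assert hist[-1] <= hist[0]
        assert len(hist) == 60

    def test_dimension_mismatch_raises(self, small_ds):
        model = init_network(NetworkSpec(9, 8, 5), 7)
        with pytest.raises(ValueError):
            train(model, small_ds, TrainingConfig(epochs=1))

    def test_batch_larger_than_data_raises(self, small_ds):
        model = init_network(NetworkSpec(12, 8, 5), 8)
        with pytest.raises(ValueError):
            train(model, small_ds, TrainingConfig(epochs=1, batch_size=10_000))

    def test_non_finite_loss_raises_divergence_error(self, small_ds):
        from bowtienet import LabeledDataset
        X = small_ds.X.copy()
        X[:100] = np.inf  # poison enough rows to hit every epoch's batches
        bad = LabeledDataset(X=X, y=small_ds.y, split=small_ds.split,
                             n_per_class=small_ds.n_per_class,
                             validation_fraction=small_ds.validation_fraction)
        model = init_network(NetworkSpec(12, 8, 5), 9)
        cfg = TrainingConfig(epochs=3, batch_size=64)
        with np.errstate(all="ignore"), pytest.raises(DivergenceError, match="epoch"):
            train(model, bad, cfg)


class TestTransfer:
    def test_transfer_continues_history_and_recovers(self, small_ds, tiny_cfg):
        zeroed = apply_input_zeroing(small_ds, 0.5)
        model = init_network(NetworkSpec(12, 8, 5), 11)
        pre = train(model, zeroed, tiny_cfg)
        moved = transfer_train(pre, small_ds, tiny_cfg)
        assert len(moved.history["loss"]) == 2 * len(pre.history["loss"])
        assert evaluate(moved, small_ds) >= evaluate(pre, small_ds) - 0.02

    def test_zero_epoch_transfer_keeps_weights(self, trained_small, small_ds):
        moved = transfer_train(trained_small, small_ds, TrainingConfig(epochs=0))
        for wa, wb in zip(trained_small.weights, moved.weights):
            assert np.array_equal(wa, wb)


class TestEvaluate:
    def test_constant_predictor_scores_chance(self, small_ds):
        model = init_network(NetworkSpec(12, 8, 5), 12)
        for w in model.weights:
            w[:] = 0.0
        model.biases[2][:] = 0.0
        model.biases[2][0] = 5.0  # always predicts class 0
        assert evaluate(model, small_ds, "validation") == pytest.approx(1 / 5)

    def test_invariant_to_row_order(self, trained_small, small_ds):
        rng = np.random.default_rng(13)
        perm = rng.permutation(len(small_ds.y))
        from bowtienet import LabeledDataset
        shuffled = LabeledDataset(X=small_ds.X[perm], y=small_ds.y[perm],
                                  split=small_ds.split[perm],
                                  n_per_class=small_ds.n_per_class,
                                  validation_fraction=small_ds.validation_fraction)
        assert evaluate(trained_small, shuffled) == evaluate(trained_small, small_ds)

    def test_empty_partition_raises(self, trained_small, small_ds):
        from bowtienet import LabeledDataset
        all_train = LabeledDataset(X=small_ds.X, y=small_ds.y,
                                   split=np.full(len(small_ds.y), "train"),
                                   n_per_class=small_ds.n_per_class,
                                   validation_fraction=small_ds.validation_fraction)
        with pytest.raises(ValueError):
            evaluate(trained_small, all_train, "validation")


class TestPersistence:
    def test_round_trip_preserves_everything(self, tmp_path, trained_small, small_ds):
        path = tmp_path / "model.npz"
        save_model(trained_small, path)
        back = load_model(path)
        for wa, wb in zip(trained_small.weights + trained_small.biases,
                          back.weights + back.biases):
            assert np.array_equal(wa, wb)
        assert back.history == trained_small.history
        assert back.rng_seed == trained_small.rng_seed
        assert evaluate(back, small_ds) == evaluate(trained_small, small_ds)

    def test_truncated_file_raises_format_error(self, tmp_path, trained_small):
        path = tmp_path / "model.npz"
        save_model(trained_small, path)
        path.write_bytes(path.read_bytes()[:120])
        with pytest.raises(ModelFormatError):
            load_model(path)


class TestBackendAgreement:
    def test_matches_sklearn_mlp_accuracy(self):
        """Independent cross-check: sklearn's MLP with the same architecture
        and data reaches the same validation accuracy (within 0.02, means
        over 5 replicates)."""
        from sklearn.neural_network import MLPClassifier

        ours, theirs = [], []
        for rep in range(5):
            protos = make_prototypes(6, 12, rng_seed=30 + rep)
            ds = sample_dataset(protos, NoiseModel(20), n_per_class=200,
                                rng_seed=60 + rep)
            Xtr, ytr = ds.partition("train")
            Xv, yv = ds.partition("validation")

            model = init_network(NetworkSpec(12, 15, 6), 90 + rep)
            cfg = TrainingConfig(epochs=120, batch_size=64, rng_seed=120 + rep)
            ours.append(evaluate(train(model, ds, cfg), ds))

            clf = MLPClassifier(hidden_layer_sizes=(12, 15), activation="relu",
                                solver="adam", batch_size=64,
                                learning_rate_init=1e-3, max_iter=120,
                                n_iter_no_change=120, tol=0.0,
                                random_state=rep)
            clf.fit(Xtr, ytr)
            theirs.append(clf.score(Xv, yv))
        assert abs(np.mean(ours) - np.mean(theirs)) < 0.02
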