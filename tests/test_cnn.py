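import numpy as np
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from relclass.cnn import (
    ACTIVATIONS,
    CNNTextClassifier,
    FilterSpec,
    feature_map,
    global_max_pool,
)
from conftest import make_text_dataset, small_cnn


def conv_oracle(x, spec):
    """Explicit all-windows sliding dot-product loop."""
    f = ACTIVATIONS[spec.activation][0]
    n, _ = x.shape
    out = np.zeros((spec.n_maps, n - spec.h + 1))
    for m in range(spec.n_maps):
        for i in range(n - spec.h + 1):
            out[m, i] = f(np.sum(spec.weights[m] * x[i : i + spec.h]) + spec.bias[m])
    return out


class TestFeatureMap:
    def test_output_length_is_n_minus_h_plus_1(self):
        x = np.ones((7, 3))
        spec = FilterSpec(h=3, weights=np.ones((2, 3, 3)), bias=np.zeros(2))
        assert feature_map(x, spec).shape == (2, 5)

    def test_zero_filter_gives_zero_map(self):
        x = np.random.default_rng(0).normal(size=(6, 4))
        spec = FilterSpec(h=2, weights=np.zeros((3, 2, 4)), bias=np.zeros(3))
        np.testing.assert_array_equal(feature_map(x, spec), 0.0)

    def test_hand_set_filter_matches_brute_force(self):
        x = np.arange(8, dtype=float).reshape(4, 2)
        w = np.array([[[1.0, -1.0], [0.5, 2.0]]])
        spec = FilterSpec(h=2, weights=w, bias=np.array([0.1]))
        np.testing.assert_allclose(feature_map(x, spec), conv_oracle(x, spec), atol=1e-12)

    @pytest.mark.parametrize("activation", sorted(ACTIVATIONS))
    def test_random_inputs_match_brute_force(self, activation):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            k = int(rng.integers(1, 5))
            h = int(rng.integers(1, n + 1))
            m = int(rng.integers(1, 4))
            x = rng.normal(size=(n, k))
            spec = FilterSpec(
                h=h, weights=rng.normal(size=(m, h, k)),
                bias=rng.normal(size=m), activation=activation,
            )
            np.testing.assert_allclose(
                feature_map(x, spec), conv_oracle(x, spec), atol=1e-6
            )

    def test_h_exceeding_n_is_shape_error(self):
        x = np.ones((2, 3))
        spec = FilterSpec(h=3, weights=np.ones((1, 3, 3)), bias=np.zeros(1))
        with pytest.raises(ValueError, match="exceeds"):
            feature_map(x, spec)


class TestGlobalMaxPool:
    def test_basic_negative_and_constant(self):
        assert global_max_pool(np.array([3.0, 1.0, 2.0]))[0] == 3.0
        assert global_max_pool(np.array([-5.0, -1.0, -3.0]))[0] == -1.0
        assert global_max_pool(np.full(4, 2.5))[0] == 2.5

    def test_empty_map_is_error(self):
        with pytest.raises(ValueError):
            global_max_pool(np.empty((2, 0)))


class TestFit:
    def test_tiny_separable_set_overfits(self):
        texts, labels = make_text_dataset(n=32, signal=1.0, seed=3, group=1)
        model = small_cnn(texts, max_epochs=30, patience=30)
        model.fit(texts, labels, X_val=texts, y_val=labels)
        assert (model.predict(texts) == labels).mean() == 1.0

    def test_single_class_is_degenerate_error(self, binary_dataset):
        texts, labels = binary_dataset
        keep = labels == labels[0]
        model = small_cnn(texts)
        with pytest.raises(ValueError, match="single class"):
            model.fit([t for t, k in zip(texts, keep) if k], labels[keep])

    def test_early_stopping_halts_on_rising_val_loss(self, binary_dataset, monkeypatch):
        texts, labels = binary_dataset
        losses = iter([1.0, 0.5, 0.6, 0.7, 0.8, 0.9, 1.1, 1.2])
        monkeypatch.setattr(
            CNNTextClassifier, "_eval_loss", lambda self, *a, **k: next(losses)
        )
        model = small_cnn(texts, patience=3, max_epochs=50)
        model.fit(texts, labels)
        assert model.n_epochs_ == 5  # epochs 0..4: best at 1, then 3 rises
        assert model.best_epoch_ == 1

    def test_best_epoch_restoration(self, binary_dataset):
        texts, labels = binary_dataset
        model = small_cnn(texts, max_epochs=8, patience=8)
        model.fit(texts, labels)
        val_losses = [h["val_loss"] for h in model.history_]
        assert model.best_val_loss_ == pytest.approx(min(val_losses))
        assert model.best_epoch_ == int(np.argmin(val_losses))

    def test_identical_seeds_identical_histories(self, binary_dataset):
        texts, labels = binary_dataset
        a = small_cnn(texts, max_epochs=4, dropout=0.0, l2=0.0)
        b = small_cnn(texts, max_epochs=4, dropout=0.0, l2=0.0)
        a.fit(texts, labels)
        b.fit(texts, labels)
        assert a.history_ == b.history_

    def test_full_batch_descent_is_monotone_early(self, binary_dataset):
        texts, labels = binary_dataset
        model = small_cnn(
            texts, optimizer="sgd", learning_rate=0.01,
            batch_size=len(texts), max_epochs=6, patience=10,
        )
        model.fit(texts, labels, X_val=texts, y_val=labels)
        train = [h["train_loss"] for h in model.history_]
        assert all(b <= a + 1e-9 for a, b in zip(train, train[1:]))

    @pytest.mark.parametrize("optimizer", ["adadelta", "adamax", "sgd"])
    def test_all_optimizers_reduce_training_loss(self, binary_dataset, optimizer):
        texts, labels = binary_dataset
        model = small_cnn(texts, optimizer=optimizer, max_epochs=6, patience=10)
        model.fit(texts, labels)
        train = [h["train_loss"] for h in model.history_]
        assert train[-1] < train[0]

    def test_trainable_embeddings_path_runs(self, binary_dataset):
        texts, labels = binary_dataset
        model = small_cnn(texts, trainable_embeddings=True, max_epochs=3)
        model.fit(texts, labels)
        # the embedding table moved away from its initial values
        emb0 = np.asarray(model.embedding.vectors, dtype=np.float64)
        assert not np.allclose(model._params["E"][: emb0.shape[0]], emb0)


class TestPredict:
    def test_rows_sum_to_one(self, binary_dataset):
        texts, labels = binary_dataset
        model = small_cnn(texts, max_epochs=3).fit(texts, labels)
        probs = model.predict_proba(texts[:10])
        assert probs.shape == (10, 2)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_output_layer_gives_uniform(self, binary_dataset):
        texts, labels = binary_dataset
        model = small_cnn(texts, max_epochs=2).fit(texts, labels)
        model._params["Wo"][:] = 0.0
        model._params["bo"][:] = 0.0
        np.testing.assert_allclose(model.predict_proba(texts[:5]), 0.5, atol=1e-12)

    def test_prediction_is_deterministic(self, binary_dataset):
        texts, labels = binary_dataset
        model = small_cnn(texts, dropout=0.5, max_epochs=3).fit(texts, labels)
        a = model.predict_proba(texts)
        b = model.predict_proba(texts)
        np.testing.assert_array_equal(a, b)

    def test_unfitted_raises(self, binary_dataset):
        texts, _ = binary_dataset
        with pytest.raises(NotFittedError):
            small_cnn(texts).predict(texts[:1])


class TestArchitecture:
    def test_pooled_vector_length_is_widths_times_maps(self, binary_dataset):
        texts, labels = binary_dataset
        model = small_cnn(
            texts, filter_widths=(2, 3, 4), n_maps=5, max_epochs=2
        ).fit(texts, labels)
        assert model.softmax_weights_.shape[0] == 3 * 5
        for spec, h in zip(model.filters_, (2, 3, 4)):
            assert spec.h == h and spec.n_maps == 5

    def test_sklearn_clone_compatible(self, binary_dataset):
        texts, _ = binary_dataset
        model = small_cnn(texts, n_maps=4)
        cloned = clone(model)
        assert cloned.get_params()["n_maps"] == 4


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, binary_dataset):
        texts, labels = binary_dataset
        model = small_cnn(texts, max_epochs=3).fit(texts, labels)
        path = model.save(tmp_path / "model.npz")
        back = CNNTextClassifier.load(path)
        np.testing.assert_allclose(
            back.predict_proba(texts), model.predict_proba(texts), atol=1e-6
        )
        assert list(back.classes_) == list(model.classes_)

    def test_history_csv(self, tmp_path, binary_dataset):
        from relclass.cnn import write_history_csv

        texts, labels = binary_dataset
        model = small_cnn(texts, max_epochs=3).fit(texts, labels)
        path = write_history_csv(model, tmp_path / "h.csv")
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "epoch,train_loss,val_loss"
        assert len(lines) == 1 + model.n_epochs_
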