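"""GRU classifier: architecture, gradients, training and inference contracts."""

import numpy as np
import pytest

from falldetect import GruClassifier, GruConfig, ValidationError

TINY = dict(recurrent_units=3, dense_layers=(4, 3, 3, 3, 2),
            dropout_rate=0.0, validation_fraction=0.0)


def _archetype_data(noise=0.01, per_class=50, seed=0):
    """Four constant-level window archetypes: trivially separable."""
    rng = np.random.default_rng(seed)
    X = np.concatenate([
        np.full((per_class, 20, 3), float(level))
        + rng.normal(0, noise, (per_class, 20, 3))
        for level in range(4)
    ])
    y = np.repeat(np.arange(4), per_class)
    return X, y


class TestArchitecture:
    def test_parameter_count_matches_closed_form(self):
        u, c = 8, 5
        dense = (16, 8, 4, 4, 4)
        clf = GruClassifier(GruConfig(recurrent_units=u, dense_layers=dense)
                            ).build(c)
        expected = 3 * (u * (u + c) + u)          # recurrent kernel + biases
        widths = [u, *dense]
        expected += sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))
        expected += dense[-1] * 4 + 4             # softmax output layer
        assert clf.n_parameters == expected

    def test_untrained_output_is_probability_vector(self):
        clf = GruClassifier(GruConfig(**TINY)).build(2)
        probs = clf.predict_proba(np.zeros((7, 4, 2)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert probs.shape == (7, 4)

    def test_same_seed_identical_initial_weights(self):
        a = GruClassifier(GruConfig(seed=5, **TINY)).build(3)
        b = GruClassifier(GruConfig(seed=5, **TINY)).build(3)
        c = GruClassifier(GruConfig(seed=6, **TINY)).build(3)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])
        assert any(not np.array_equal(a.params[k], c.params[k])
                   for k in a.params)

    @pytest.mark.parametrize(
        "bad", [dict(dense_layers=()), dict(dropout_rate=1.0),
                dict(dropout_positions=(6,)), dict(recurrent_units=0),
                dict(activation_hidden="tanh")]
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            GruConfig(**{**TINY, **bad})


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        clf = GruClassifier(GruConfig(seed=2, **TINY)).build(2)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 4, 2))
        y = np.array([0, 1, 2, 3, 1])

        def loss():
            cache = {}
            logits = clf._forward(X, cache=cache)
            return (*clf._loss_grad(logits, y, None), cache)

        base_loss, dlogits, _, cache = loss()
        grads = clf._backward(X, dlogits, cache)
        eps = 1e-6
        rng_pick = np.random.default_rng(1)
        for k, v in clf.params.items():
            flat = v.reshape(-1)
            for idx in rng_pick.choice(flat.size, size=min(10, flat.size),
                                       replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()[0]
                flat[idx] = old - eps
                lm = loss()[0]
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[k].reshape(-1)[idx]
                assert ana == pytest.approx(num, abs=1e-6, rel=1e-3), k

    def test_weighted_loss_gradient_matches_finite_differences(self):
        clf = GruClassifier(GruConfig(seed=3, **TINY)).build(2)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(4, 3, 2))
        y = np.array([0, 1, 2, 3])
        w = np.array([0.5, 2.0, 1.0, 4.0])
        logits = clf._forward(X)
        _, dlogits, _ = clf._loss_grad(logits, y, w)
        eps = 1e-6
        for i in range(4):
            for j in range(4):
                pert = logits.copy()
                pert[i, j] += eps
                lp = clf._loss_grad(pert, y, w)[0]
                pert[i, j] -= 2 * eps
                lm = clf._loss_grad(pert, y, w)[0]
                num = (lp - lm) / (2 * eps)
                assert dlogits[i, j] == pytest.approx(num, abs=1e-6)


class TestTraining:
    def test_learns_separable_archetypes(self):
        X, y = _archetype_data()
        cfg = GruConfig(recurrent_units=16, dense_layers=(32, 16, 8, 8, 8),
                        dropout_rate=0.0, epochs=30, batch_size=32,
                        learning_rate=3e-3, seed=1, validation_fraction=0.2)
        clf = GruClassifier(cfg).fit(X, y)
        assert clf.history["accuracy"][-1] > 0.95
        Xh, yh = _archetype_data(seed=99, per_class=20)
        labels, _ = clf.predict(Xh)
        assert (labels == yh).mean() >= 0.9

    def test_zero_epochs_leaves_weights_untouched(self):
        X, y = _archetype_data(per_class=5)
        cfg = GruConfig(epochs=0, seed=4, **TINY)
        trained = GruClassifier(cfg).fit(X, y)
        fresh = GruClassifier(cfg).build(3)
        for k in fresh.params:
            assert np.array_equal(trained.params[k], fresh.params[k])
        assert trained.history["loss"] == []

    def test_history_lengths_and_finite_loss(self):
        X, y = _archetype_data(per_class=10)
        cfg = GruConfig(epochs=5, seed=1, recurrent_units=4,
                        dense_layers=(4, 4, 4, 4, 4), dropout_rate=0.2,
                        validation_fraction=0.25)
        clf = GruClassifier(cfg).fit(X, y)
        for key in ("loss", "accuracy", "val_loss", "val_accuracy"):
            assert len(clf.history[key]) == 5
        assert np.all(np.isfinite(clf.history["loss"]))
        assert np.all(np.isfinite(clf.history["val_loss"]))

    def test_training_reproducible_for_fixed_seed(self):
        X, y = _archetype_data(per_class=10)
        cfg = GruConfig(epochs=3, seed=7, recurrent_units=4,
                        dense_layers=(4, 4, 4, 4, 4))
        a = GruClassifier(cfg).fit(X, y)
        b = GruClassifier(cfg).fit(X, y)
        assert a.history == b.history
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_missing_class_rejected(self):
        X, y = _archetype_data(per_class=5)
        with pytest.raises(ValidationError, match="coma"):
            GruClassifier(GruConfig(epochs=1, **TINY)).fit(X[y < 3], y[y < 3])


class TestInference:
    def _fitted(self):
        X, y = _archetype_data(per_class=10)
        return GruClassifier(GruConfig(epochs=2, seed=1, **TINY)).fit(X, y)

    def test_probabilities_sum_to_one(self):
        clf = self._fitted()
        X, _ = _archetype_data(seed=2, per_class=8)
        _, probs = clf.predict(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_permutation_permutes_predictions(self):
        clf = self._fitted()
        X, _ = _archetype_data(seed=3, per_class=8)
        perm = np.random.default_rng(0).permutation(len(X))
        labels, probs = clf.predict(X)
        labels_p, probs_p = clf.predict(X[perm])
        assert np.array_equal(labels_p, labels[perm])
        np.testing.assert_allclose(probs_p, probs[perm], atol=1e-12)

    def test_labels_in_status_range(self):
        clf = self._fitted()
        X, _ = _archetype_data(seed=4)
        labels, _ = clf.predict(X * 5 - 2)
        assert set(np.unique(labels)) <= {0, 1, 2, 3}

    def test_channel_mismatch_rejected(self):
        clf = self._fitted()
        with pytest.raises(ValueError, match="channel"):
            clf.predict(np.zeros((2, 20, 5)))

    def test_save_load_round_trip(self, tmp_path):
        clf = self._fitted()
        path = tmp_path / "model.npz"
        clf.save(path)
        back = GruClassifier.load(path)
        X, _ = _archetype_data(seed=5, per_class=6)
        np.testing.assert_array_equal(back.predict(X)[0], clf.predict(X)[0])
        np.testing.assert_allclose(back.predict(X)[1], clf.predict(X)[1],
                                   atol=1e-12)
        assert back.config == clf.config
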