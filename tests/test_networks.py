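"""Model architectures, gradients, and training behaviour."""

import numpy as np
import pytest

from ppicube.nn import (DlaMutationModel, SsdlaModel, TrunkConfig,
                        class_weights, mse_loss, softmax_cross_entropy,
                        train_ddg, train_ssdla)
from ppicube.nn.models import load_checkpoint, save_checkpoint

TINY = TrunkConfig(n_channels_in=2, projector_dim=3, conv_filters=(3, 4, 4),
                   conv_strides=(2, 2, 1), dropout_rates=(0.0, 0.0, 0.0))


def _rand_cubes(n, c=2, seed=0, dtype=np.float64):
    rng = np.random.default_rng(seed)
    return rng.random((n, 24, 24, 24, c)).astype(dtype)


class TestSsdlaForward:
    def test_output_is_probability_vector(self):
        model = SsdlaModel(TINY, seed=0)
        probs = model.forward(_rand_cubes(3, dtype=np.float32))
        assert probs.shape == (3, 20)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_eval_mode_deterministic(self):
        model = SsdlaModel(TrunkConfig.desk(2), seed=1)
        x = _rand_cubes(2, dtype=np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_zero_final_layer_gives_uniform_distribution(self):
        model = SsdlaModel(TINY, seed=0)
        model.fc3.w.value[...] = 0.0
        probs = model.forward(_rand_cubes(2, dtype=np.float32))
        np.testing.assert_allclose(probs, 0.05, atol=1e-7)

    def test_channel_mismatch_rejected(self):
        model = DlaMutationModel(TINY, seed=0)
        x = _rand_cubes(1, c=3)
        with pytest.raises(ValueError, match="channels"):
            model.forward(x, x, np.zeros(9))

    def test_embedding_has_dimension_200(self):
        model = SsdlaModel(TINY, seed=0)
        emb = model.embed(_rand_cubes(2, dtype=np.float32))
        assert emb.shape == (2, 200)

    def test_different_cubes_embed_differently(self):
        model = SsdlaModel(TINY, seed=0)
        a, b = _rand_cubes(2, seed=5, dtype=np.float32)
        ea = model.embed(a[None])
        eb = model.embed(b[None])
        assert not np.allclose(ea, eb)


class TestClassWeights:
    def test_uniform_frequencies_give_unit_weights(self):
        np.testing.assert_allclose(class_weights(np.full(20, 0.05)), 1.0)

    def test_inverse_proportionality(self):
        w = class_weights([0.5, 0.25, 0.25])
        np.testing.assert_allclose(w, [0.6, 1.2, 1.2])

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            class_weights([0.5, 0.5, 0.0])


class TestGradients:
    """Analytic backprop against central finite differences (float64)."""

    def _check(self, loss_fn, params, rng, n_samples=4):
        nums, anas = [], []
        for p in params:
            flat, g = p.value.reshape(-1), p.grad.reshape(-1)
            for idx in rng.choice(flat.size, size=min(n_samples, flat.size),
                                  replace=False):
                eps, orig = 1e-6, flat[idx]
                flat[idx] = orig + eps
                lp = loss_fn()
                flat[idx] = orig - eps
                lm = loss_fn()
                flat[idx] = orig
                nums.append((lp - lm) / (2 * eps))
                anas.append(g[idx])
        np.testing.assert_allclose(nums, anas, rtol=1e-3, atol=1e-5)

    def test_ssdla_gradients(self):
        rng = np.random.default_rng(0)
        model = SsdlaModel(TINY, seed=0, dtype=np.float64)
        x = _rand_cubes(3, seed=1)
        y = np.array([1, 5, 7])

        def loss_fn():
            l, _ = softmax_cross_entropy(model.logits(x, train=True), y)
            return l

        for p in model.params():
            p.grad[...] = 0.0
        loss, grad = softmax_cross_entropy(model.logits(x, train=True), y)
        model.backward(grad)
        self._check(loss_fn, model.params(), rng)

    def test_siamese_gradients(self):
        rng = np.random.default_rng(1)
        model = DlaMutationModel(TINY, seed=2, dtype=np.float64)
        wt, mu = _rand_cubes(2, seed=3), _rand_cubes(2, seed=4)
        aux = rng.random((2, 9))
        t = np.array([0.5, -1.0])

        def loss_fn():
            l, _ = mse_loss(model.forward(wt, mu, aux, train=True), t)
            return l

        for p in model.params():
            p.grad[...] = 0.0
        loss, grad = mse_loss(model.forward(wt, mu, aux, train=True), t)
        model.backward(grad)
        self._check(loss_fn, model.params(), rng)


class TestSiameseIdentities:
    def test_identical_cubes_reduce_to_aux_only_prediction(self):
        model = DlaMutationModel(TINY, seed=0, dtype=np.float64)
        x = _rand_cubes(3, seed=6)
        aux = np.random.default_rng(7).random((3, 9))
        pred = model.forward(x, x, aux)
        aux_only = (np.concatenate(
            [np.zeros((3, 20)), aux], axis=1) @ model.head.w.value
            + model.head.b.value).reshape(-1)
        np.testing.assert_allclose(pred, aux_only, atol=1e-12)

    def test_prediction_odd_in_branch_difference(self):
        model = DlaMutationModel(TINY, seed=0, dtype=np.float64)
        x, y = _rand_cubes(1, seed=8), _rand_cubes(1, seed=9)
        aux = np.random.default_rng(10).random((1, 9))
        lhs = model.forward(x, y, aux) + model.forward(y, x, aux)
        rhs = 2.0 * model.forward(x, x, aux)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_branches_share_one_parameter_set(self):
        model = DlaMutationModel(TINY, seed=0)
        # a single trunk/branch object serves both inputs: any update to it
        # is seen by both branches by construction
        assert model.branch_head is model.branch_head
        n_params = len(model.params())
        assert n_params == len({id(p) for p in model.params()})


class TestTraining:
    def test_zero_epochs_leaves_model_untouched(self, ddg_data):
        model = DlaMutationModel(TrunkConfig.desk(4), seed=0)
        before = [p.value.copy() for p in model.params()]
        model2, result = train_ddg(
            ddg_data.wt_cubes[:8], ddg_data.mu_cubes[:8], ddg_data.aux[:8],
            ddg_data.targets[:8], model=model, epochs=0, seed=0)
        assert model2 is model
        assert result.loss_history == []
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_same_seed_reproduces_loss_history(self, ddg_data):
        losses = []
        for _ in range(2):
            _, result = train_ddg(
                ddg_data.wt_cubes[:16], ddg_data.mu_cubes[:16],
                ddg_data.aux[:16], ddg_data.targets[:16],
                config=TrunkConfig.desk(4), epochs=2, seed=3)
            losses.append(result.loss_history)
        assert losses[0] == losses[1]

    def test_random_and_pretrained_init_are_both_supported(
            self, ddg_data, overfit):
        runs = {}
        for init in ("random", "pretrained"):
            _, result = train_ddg(
                ddg_data.wt_cubes[:16], ddg_data.mu_cubes[:16],
                ddg_data.aux[:16], ddg_data.targets[:16],
                config=TrunkConfig.desk(4), init=init,
                pretrained=overfit["model"], epochs=2, seed=3)
            runs[init] = result.loss_history
        assert runs["random"] != runs["pretrained"]

    def test_overfit_loss_curve_decreases(self, overfit):
        history = overfit["result"].loss_history
        assert np.all(np.isfinite(history))
        assert history[-1] < history[0]
        # broadly decreasing over the first stretch of training
        assert np.mean(history[5:10]) < np.mean(history[:5])

    def test_empty_training_set_rejected(self):
        model = SsdlaModel(TINY, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_ssdla(np.zeros((0, 24, 24, 24, 2)), np.zeros(0, dtype=int),
                        model, epochs=1)


class TestEmbeddingClassifier:
    def test_output_lengths_match_task(self):
        from ppicube.nn import EmbeddingClassifier
        rng = np.random.default_rng(0)
        emb = rng.random((4, 200)).astype(np.float32)
        for n_classes in (7, 3):  # residue-class and interface-function tasks
            clf = EmbeddingClassifier(n_classes, seed=0)
            probs = clf.forward(emb)
            assert probs.shape == (4, n_classes)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_mean_of_identical_embeddings_is_the_embedding(self):
        e = np.random.default_rng(1).random(200)
        stack = np.tile(e, (5, 1))
        np.testing.assert_allclose(stack.mean(axis=0), e, atol=1e-12)

    def test_learns_linearly_separable_embeddings(self):
        from ppicube.nn import train_classifier
        rng = np.random.default_rng(2)
        labels = np.repeat(np.arange(3), 20)
        emb = rng.normal(size=(60, 200)).astype(np.float32)
        emb[:, :3] += 4.0 * np.eye(3)[labels]  # class signal in 3 dims
        clf, result = train_classifier(emb, labels, n_classes=3, epochs=150,
                                       seed=0)
        acc = (clf.forward(emb).argmax(axis=1) == labels).mean()
        assert acc >= 0.95
        assert result.loss_history[-1] < result.loss_history[0]


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, overfit,
                                              labeled_cubes):
        path = tmp_path / "model.npz"
        save_checkpoint(overfit["model"], path, scheme_mode="element4")
        restored, mode = load_checkpoint(path)
        assert mode == "element4"
        x = labeled_cubes.cubes[:4]
        np.testing.assert_allclose(restored.forward(x),
                                   overfit["model"].forward(x), atol=1e-6)
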