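"""Classifier architectures, gradients, training protocol, evaluation."""

import numpy as np
import pytest

import spikecode.nets as nets
from spikecode.nets import (
    LSTM,
    ChannelScaler,
    ClassifierSpec,
    Conv1D,
    Dense,
    GlobalAvgPool1D,
    TrainConfig,
    TrainedClassifier,
    build_cnn,
    build_lstm,
    build_mcdcnn,
    build_mlp,
    build_model,
    evaluate,
    train_classifier,
)
from spikecode.nets import _loss_and_grad, _sigmoid


def _toy_problem(rng, n=60, m=2, t=40):
    X = rng.normal(size=(n, m, t))
    y = (X[:, 0, :8].mean(axis=1) > 0).astype(int)
    return X, np.eye(2)[y]


class TestBuilders:
    def test_mlp_hidden_widths(self):
        spec = ClassifierSpec("mlp", 2, 30, 2)
        model = build_mlp(spec, seed=0)
        dense = [l for l in model.layers if isinstance(l, Dense)]
        assert [d.W.shape for d in dense] == [(60, 10), (10, 7), (7, 4), (4, 2)]

    def test_mlp_parameter_count_arithmetic(self):
        m, t, k = 3, 50, 4
        model = build_mlp(ClassifierSpec("mlp", m, t, k), seed=0)
        n_in = m * t
        expected = (
            (n_in * 10 + 10) + (10 * 7 + 7) + (7 * 4 + 4) + (4 * k + k)
        )
        assert model.n_params == expected

    def test_cnn_filter_counts(self):
        model = build_cnn(ClassifierSpec("cnn", 2, 64, 3), seed=0)
        convs = [l for l in model.layers if isinstance(l, Conv1D)]
        assert [c.W.shape[0] for c in convs] == [10, 7, 4]
        assert all(c.W.shape[2] == 3 for c in convs)

    def test_cnn_window_too_short(self):
        with pytest.raises(ValueError):
            build_cnn(ClassifierSpec("cnn", 2, 8, 2), seed=0)

    def test_mcdcnn_presets_enforced(self):
        ok = ClassifierSpec("mcdcnn", 2, 32, 2, arch_params={"filters": 3, "kernel": 2})
        build_mcdcnn(ok, seed=0)
        bad = ClassifierSpec("mcdcnn", 2, 32, 2, arch_params={"filters": 5, "kernel": 4})
        with pytest.raises(ValueError, match="preset"):
            build_mcdcnn(bad, seed=0)
        override = ClassifierSpec(
            "mcdcnn", 2, 32, 2,
            arch_params={"filters": 5, "kernel": 4, "allow_any_preset": True},
        )
        build_mcdcnn(override, seed=0)

    def test_mcdcnn_one_branch_per_channel(self):
        model = build_mcdcnn(
            ClassifierSpec("mcdcnn", 4, 32, 3, arch_params={"filters": 2, "kernel": 1}),
            seed=0,
        )
        assert len(model.branches) == 4

    def test_lstm_unit_counts(self):
        model = build_lstm(ClassifierSpec("lstm", 2, 16, 2), seed=0)
        lstms = [l for l in model.layers if isinstance(l, LSTM)]
        assert [l.units for l in lstms] == [6, 4]


class TestLayerSemantics:
    def test_conv_output_length_matches_sliding_window(self, rng):
        x = rng.normal(size=(3, 2, 20)).astype(nets.DTYPE)
        conv = Conv1D(2, 4, 3, np.random.default_rng(0))
        out = conv.forward(x, train=False)
        assert out.shape == (3, 4, 18)  # L - k + 1
        # direct sliding-window computation for one output element
        n, f, l = 1, 2, 5
        manual = (x[n, :, l : l + 3] * conv.W[f]).sum() + conv.b[f]
        assert out[n, f, l] == pytest.approx(manual, rel=1e-5)

    def test_global_average_pool_of_constant(self):
        x = np.full((2, 3, 9), 4.2, dtype=nets.DTYPE)
        out = GlobalAvgPool1D().forward(x, train=False)
        assert np.allclose(out, 4.2)

    def test_relu_definition(self):
        from spikecode.nets import ReLU

        out = ReLU().forward(np.array([-3.0, 2.0]), train=False)
        assert out.tolist() == [0.0, 2.0]

    def test_dropout_off_at_inference(self, rng):
        spec = ClassifierSpec(
            "mcdcnn", 2, 24, 2, arch_params={"filters": 3, "kernel": 2}
        )
        X, Y = _toy_problem(rng, n=20, t=24)
        clf = train_classifier(spec, X, Y, cfg=TrainConfig(epochs=2, batch_size=10))
        p1 = clf.predict_proba(X)
        p2 = clf.predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_lstm_single_step_closed_form(self):
        lstm = LSTM(1, 1, np.random.default_rng(0), return_sequences=False)
        lstm.Wx[...] = 0.5
        lstm.Wh[...] = 0.0
        lstm.b[...] = np.array([0.1, 0.2, 0.3, 0.4])
        x = np.array([[[2.0]]])  # one sample, one channel, one step
        out = lstm.forward(x, train=False)
        z = 0.5 * 2.0 + np.array([0.1, 0.2, 0.3, 0.4])
        i, f, o = _sigmoid(z[0]), _sigmoid(z[1]), _sigmoid(z[3])
        g = np.tanh(z[2])
        expected = o * np.tanh(i * g)  # zero initial cell state
        assert out[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_mcdcnn_channel_permutation_covariance(self, rng):
        spec = ClassifierSpec(
            "mcdcnn", 3, 20, 2, arch_params={"filters": 3, "kernel": 2}
        )
        model = build_mcdcnn(spec, seed=4)
        x = rng.normal(size=(6, 3, 20)).astype(nets.DTYPE)
        base = model.forward(x, train=False)
        perm = [2, 0, 1]
        model.branches = [model.branches[p] for p in perm]
        # permute the trunk's first dense block rows identically
        w = model.trunk.layers[0].W
        width = w.shape[0] // 3
        blocks = [w[i * width : (i + 1) * width].copy() for i in range(3)]
        for dst, src in enumerate(perm):
            w[dst * width : (dst + 1) * width] = blocks[src]
        out = model.forward(x[:, perm, :], train=False)
        assert np.allclose(out, base, atol=1e-5)


class TestGradients:
    @pytest.mark.parametrize("arch,ap", [
        ("mlp", {}),
        ("cnn", {}),
        ("mcdcnn", {"filters": 3, "kernel": 2}),
        ("lstm", {}),
    ])
    def test_backprop_matches_finite_differences(self, arch, ap, monkeypatch):
        monkeypatch.setattr(nets, "DTYPE", np.float64)
        rng = np.random.default_rng(3)
        spec = ClassifierSpec(arch, 2, 12, 3, arch_params=ap)
        model = build_model(spec, seed=2)
        X = rng.normal(size=(5, 2, 12))
        Y = np.eye(3)[rng.integers(0, 3, 5)]

        def loss_of():
            return _loss_and_grad(model.forward(X, train=False), Y, "softmax")[0]

        _, _, g = _loss_and_grad(model.forward(X, train=False), Y, "softmax")
        model.backward(g)
        for p, gr in zip(model.params(), model.grads()):
            flat, gflat = p.reshape(-1), gr.reshape(-1)
            for k in range(0, flat.size, max(flat.size // 2, 1)):
                eps = 1e-6
                old = flat[k]
                flat[k] = old + eps
                lp = loss_of()
                flat[k] = old - eps
                lm = loss_of()
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                assert gflat[k] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestTraining:
    def test_toy_convergence(self, rng):
        X, Y = _toy_problem(rng)
        spec = ClassifierSpec("mlp", 2, 40, 2)
        clf = train_classifier(spec, X, Y, cfg=TrainConfig(epochs=90, batch_size=16))
        assert clf.history["train_loss"][-1] <= clf.history["train_loss"][0]
        assert len(clf.history["train_loss"]) == 90

    def test_single_class_training_yields_constant_predictor(self, rng):
        X = rng.normal(size=(30, 2, 40))
        Y = np.tile([0.0, 1.0], (30, 1))  # every sample class 1
        spec = ClassifierSpec("mcdcnn", 2, 40, 2, arch_params={"filters": 3, "kernel": 2})
        clf = train_classifier(spec, X, Y, cfg=TrainConfig(epochs=10, batch_size=16))
        other = rng.normal(size=(20, 2, 40)) * 5
        assert np.all(clf.predict(other) == 1)

    def test_seed_determinism(self, rng):
        X, Y = _toy_problem(rng, n=24)
        spec = ClassifierSpec("mcdcnn", 2, 40, 2, arch_params={"filters": 3, "kernel": 2})
        cfg = TrainConfig(epochs=3, batch_size=8, seed=11)
        a = train_classifier(spec, X, Y, cfg=cfg)
        b = train_classifier(spec, X, Y, cfg=cfg)
        assert a.history == b.history
        assert all(np.array_equal(p, q) for p, q in zip(a.model.params(), b.model.params()))

    def test_validation_history_recorded(self, rng):
        X, Y = _toy_problem(rng, n=40)
        spec = ClassifierSpec("mlp", 2, 40, 2)
        clf = train_classifier(
            spec, X[:30], Y[:30], X[30:], Y[30:], TrainConfig(epochs=4, batch_size=10)
        )
        assert len(clf.history["val_acc"]) == 4

    def test_save_load_round_trip(self, rng, tmp_path):
        X, Y = _toy_problem(rng, n=20)
        spec = ClassifierSpec("mlp", 2, 40, 2)
        clf = train_classifier(spec, X, Y, cfg=TrainConfig(epochs=2, batch_size=8))
        path = tmp_path / "weights.npz"
        clf.save(path)
        back = TrainedClassifier.load(path)
        assert np.array_equal(back.predict(X), clf.predict(X))

    def test_shape_mismatch_rejected(self, rng):
        X, Y = _toy_problem(rng, n=10)
        spec = ClassifierSpec("mlp", 3, 40, 2)
        with pytest.raises(ValueError):
            train_classifier(spec, X, Y, cfg=TrainConfig(epochs=1))


class TestEvaluate:
    def _constant_clf(self, k=3, cls=0):
        spec = ClassifierSpec("mlp", 1, 8, k)
        model = build_model(spec, seed=0)
        for layer in model.layers:
            for p in layer.params():
                p[...] = 0.0
        # bias the head toward `cls`
        model.layers[-1].b[cls] = 10.0
        scaler = ChannelScaler()
        scaler.mean = np.zeros(1)
        scaler.std = np.ones(1)
        return TrainedClassifier(spec, model, scaler, {}, 0)

    def test_perfect_predictions_give_one(self, rng):
        clf = self._constant_clf(k=2, cls=1)
        X = rng.normal(size=(10, 1, 8))
        Y = np.tile([0.0, 1.0], (10, 1))
        acc, conf = evaluate(clf, X, Y)
        assert acc == 1.0

    def test_constant_predictor_is_chance_on_balanced_data(self, rng):
        k = 4
        clf = self._constant_clf(k=k, cls=2)
        X = rng.normal(size=(40, 1, 8))
        Y = np.eye(k)[np.repeat(np.arange(k), 10)]
        acc, conf = evaluate(clf, X, Y)
        assert acc == pytest.approx(1 / k)
        assert conf.sum() == 40
        assert acc == pytest.approx(np.trace(conf) / conf.sum())

    def test_order_invariance(self, rng):
        clf = self._constant_clf(k=2, cls=0)
        X = rng.normal(size=(12, 1, 8))
        Y = np.eye(2)[rng.integers(0, 2, 12)]
        acc1, _ = evaluate(clf, X, Y)
        perm = rng.permutation(12)
        acc2, _ = evaluate(clf, X[perm], Y[perm])
        assert acc1 == acc2

    def test_channel_mismatch_rejected(self, rng):
        clf = self._constant_clf()
        with pytest.raises(ValueError):
            evaluate(clf, rng.normal(size=(5, 2, 8)), np.eye(3)[np.zeros(5, int)])
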