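import numpy as np
import pytest

from introscan._nn import BatchNorm, Conv2D, Dense, bce_with_logits
from introscan.model import (
    ModelConfig,
    TrainingConfig,
    build_model,
    predict,
    split_train_val,
    train,
)


def _count_params(n, m, k, filters=16, kernel=(4, 4)):
    """Hand-computed parameter count from the layer arithmetic."""
    total = 2 * 1  # input batch norm (gamma, beta)
    c = 1
    h, w = n, m
    for _ in range(k):
        total += 2 * c  # block batch norm
        total += kernel[0] * kernel[1] * c * filters + filters  # conv + bias
        h, w = -(-h // 2), -(-w // 2)
        c = filters
    total += h * w * c + 1  # dense
    return total


class TestBuild:
    def test_m256_k7_bins_dim(self):
        clf = build_model(ModelConfig(m=256, k=7), (256, 256))
        # walk the conv layers to find the final spatial width
        h = w = 256
        for layer in clf.network.layers:
            if isinstance(layer, Conv2D):
                h, w = layer.out_shape(h, w)
        assert w == 2

    def test_k0_is_logistic_regression(self):
        clf = build_model(ModelConfig(m=16, k=0), (4, 16))
        kinds = [type(l).__name__ for l in clf.network.layers]
        assert kinds == ["BatchNorm", "Flatten", "Dense"]

    def test_default_k7(self):
        assert ModelConfig().k == 7 and ModelConfig().m == 256

    def test_too_deep_errors(self):
        with pytest.raises(ValueError, match="too deep"):
            build_model(ModelConfig(m=16, k=5), (8, 16))

    @pytest.mark.parametrize("n,m,k", [(68, 64, 5), (34, 64, 5), (16, 32, 3), (8, 8, 0)])
    def test_parameter_count(self, n, m, k):
        clf = build_model(ModelConfig(m=m, k=k), (n, m))
        assert clf.network.n_params() == _count_params(n, m, k)

    def test_bin_mismatch_errors(self):
        with pytest.raises(ValueError, match="bins"):
            build_model(ModelConfig(m=64, k=2), (16, 32))


class TestSplit:
    def test_proportions_and_stratification(self):
        y = np.r_[np.zeros(1000), np.ones(1000)]
        X = np.arange(2000)
        (Xt, yt), (Xv, yv) = split_train_val((X, y), 0.9, seed=0)
        assert len(yt) == 1800 and len(yv) == 200
        assert yt.sum() == 900 and yv.sum() == 100

    def test_partition(self):
        y = np.r_[np.zeros(50), np.ones(50)]
        X = np.arange(100)
        (Xt, _), (Xv, _) = split_train_val((X, y), 0.8, seed=1)
        assert sorted(np.concatenate([Xt, Xv]).tolist()) == list(range(100))
        assert set(Xt).isdisjoint(Xv)

    def test_deterministic(self):
        y = np.r_[np.zeros(30), np.ones(30)]
        X = np.arange(60)
        a = split_train_val((X, y), 0.9, seed=7)
        b = split_train_val((X, y), 0.9, seed=7)
        np.testing.assert_array_equal(a[0][0], b[0][0])
        np.testing.assert_array_equal(a[1][0], b[1][0])


def test_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    clf = build_model(ModelConfig(m=8, k=2), (8, 8), seed=1)
    X = rng.normal(size=(6, 8, 8, 1)).astype(np.float32)
    y = (rng.uniform(size=6) > 0.5).astype(float)
    net = clf.network
    z = net.forward(X, train=True)
    _, dz = bce_with_logits(z, y)
    net.backward(dz)
    def fd(flat, idx, eps):
        old = flat[idx]
        flat[idx] = old + eps
        lp, _ = bce_with_logits(net.forward(X, train=True), y)
        flat[idx] = old - eps
        lm, _ = bce_with_logits(net.forward(X, train=True), y)
        flat[idx] = old
        return (lp - lm) / (2 * eps)

    checked = 0
    for layer in net.layers:
        for p, g in zip(layer.params, layer.grads):
            flat, gflat = p.ravel(), g.ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                num1 = fd(flat, idx, 1e-3)
                num2 = fd(flat, idx, 5e-4)
                if abs(num1 - num2) > 0.05 * max(abs(num1), 1e-3):
                    continue  # rectifier kink crossed; finite differences invalid
                assert gflat[idx] == pytest.approx(num1, rel=0.05, abs=2e-3)
                checked += 1
    assert checked > 20


@pytest.fixture(scope="module")
def easy_task():
    rng = np.random.default_rng(3)
    n = 400
    X0 = rng.poisson(2.0, size=(n, 32, 32)).astype(np.uint8)
    X1 = rng.poisson(2.0, size=(n, 32, 32)).astype(np.uint8)
    X1[:, 4:12, 10:22] += 2
    X = np.concatenate([X0, X1])
    y = np.r_[np.zeros(n), np.ones(n)]
    return X, y


def test_training_learns_easy_task(easy_task):
    X, y = easy_task
    (tr, val) = split_train_val((X, y), 0.9, seed=0)
    clf = build_model(ModelConfig(m=32, k=3), (32, 32), seed=0)
    train(clf, tr, TrainingConfig(epochs=3), seed=0, validation_data=val)
    assert clf.history["val_accuracy"][-1] > 0.8
    # approximate convergence: train/val metric gap under 0.05
    assert abs(clf.history["accuracy"][-1] - clf.history["val_accuracy"][-1]) < 0.05


def test_shuffled_labels_chance_level(easy_task):
    X, y = easy_task
    rng = np.random.default_rng(1)
    y_shuf = rng.permutation(y)
    (tr, val) = split_train_val((X, y_shuf), 0.9, seed=0)
    clf = build_model(ModelConfig(m=32, k=3), (32, 32), seed=0)
    train(clf, tr, TrainingConfig(epochs=3), seed=0, validation_data=val)
    assert abs(clf.history["val_accuracy"][-1] - 0.5) < 0.1


def test_training_reproducible(easy_task):
    X, y = easy_task
    outs = []
    for _ in range(2):
        clf = build_model(ModelConfig(m=32, k=2), (32, 32), seed=11)
        idx = np.r_[0:100, 400:500]  # balanced subset
        train(clf, (X[idx], y[idx]), TrainingConfig(epochs=1), seed=11)
        outs.append(predict(clf, X[:50]))
    np.testing.assert_allclose(outs[0], outs[1], atol=1e-6)


class TestPredict:
    def test_range_and_determinism(self, easy_task):
        X, y = easy_task
        clf = build_model(ModelConfig(m=32, k=2), (32, 32), seed=2)
        p1 = predict(clf, X[:40])
        p2 = predict(clf, X[:40])
        assert np.all((p1 >= 0) & (p1 <= 1))
        np.testing.assert_array_equal(p1, p2)

    def test_batch_vs_single(self, easy_task):
        X, _ = easy_task
        clf = build_model(ModelConfig(m=32, k=2), (32, 32), seed=2)
        batch = predict(clf, X[:10])
        singles = np.array([predict(clf, X[i : i + 1])[0] for i in range(10)])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_shape_mismatch_errors(self, easy_task):
        X, y = easy_task
        clf = build_model(ModelConfig(m=32, k=2), (32, 32), seed=2)
        with pytest.raises(ValueError, match="match"):
            predict(clf, X[:4, :16, :])
        with pytest.raises(ValueError, match="match"):
            train(clf, (X[:8, :, :16], y[:8]), TrainingConfig(epochs=1))


def test_save_load_roundtrip(tmp_path, easy_task):
    X, y = easy_task
    clf = build_model(ModelConfig(m=32, k=2), (32, 32), seed=4)
    train(clf, (X[:128], y[:128]), TrainingConfig(epochs=1), seed=4)
    clf.save(tmp_path / "model")
    from introscan.model import TrainedClassifier

    clf2 = TrainedClassifier.load(tmp_path / "model")
    np.testing.assert_allclose(predict(clf, X[:20]), predict(clf2, X[:20]), atol=1e-6)
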