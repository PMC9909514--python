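"""CNN architecture, gradients, training contracts; classical baselines."""

import numpy as np
import pytest

from readmood.baselines import BaselineSpec, fit_baseline, predict_baseline
from readmood.cnn import (CnnArchitecture, TrainConfig, build_cnn,
                          load_checkpoint, predict_segments,
                          save_checkpoint, segments_to_array, train_cnn)
from readmood.spectro import LogMelSegment

from .oracles import cnn_parameter_count

TINY = CnnArchitecture(input_shape=(16, 32), conv_channels=(4, 4, 4, 4),
                       dense_units=(8, 4), dropout=0.0)


def band_segments(n_per_class, rng, shape=(64, 200)):
    """Two classes with disjoint band-energy signatures."""
    segs = []
    for cls in (0, 1):
        band = slice(8, 24) if cls == 0 else slice(40, 56)
        for i in range(n_per_class):
            v = np.full(shape, -60.0) + rng.normal(0, 3.0, shape)
            v[band, :] += 40.0
            v = np.maximum(v - v.max(), -80.0).astype(np.float32)
            segs.append(LogMelSegment(v, f"p{cls}_{i}", "t", i, cls))
    return segs


class TestArchitecture:
    def test_forward_probabilities_in_unit_interval(self):
        m = build_cnn(seed=0)
        x = np.random.default_rng(0).normal(
            size=(4, 64, 200, 1)).astype(np.float32)
        p = m.predict_proba(x)
        assert p.shape == (4,)
        assert np.all((p > 0) & (p < 1))

    @pytest.mark.parametrize("mode", ["halve", "literal"])
    def test_parameter_count_matches_layer_arithmetic(self, mode):
        arch = CnnArchitecture(pool_stride_mode=mode)
        m = build_cnn(arch, seed=0)
        expected = cnn_parameter_count(
            pool_stride=(2, 2) if mode == "halve" else (1, 2))
        assert m.parameter_count() == expected

    def test_default_parameter_count_is_small(self):
        # the headline model stays in the few-hundred-thousand range
        assert build_cnn(seed=0).parameter_count() == 246_817

    def test_collapsed_pooling_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(CnnArchitecture(input_shape=(8, 8)))

    def test_numeric_gradient_check(self):
        """Backward pass against central finite differences."""
        arch = CnnArchitecture(input_shape=(8, 12), conv_channels=(2, 3),
                               dense_units=(5,), dropout=0.0)
        m = build_cnn(arch, seed=1)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 8, 12, 1)).astype(np.float32)
        y = np.array([0.0, 1.0, 1.0], dtype=np.float32)

        def loss():
            logits, _ = m.forward(x)
            return float(np.mean(np.logaddexp(0.0, logits) - y * logits))

        logits, cache = m.forward(x)
        probs = 1.0 / (1.0 + np.exp(-logits))
        grads = m.backward((probs - y) / len(y), cache)
        for name in ("Wc0", "Wc1", "Wd0", "Wout", "bc1", "bd0"):
            w = m.params[name].ravel()
            g = grads[name].ravel()
            diffs = []
            for flat_idx in range(w.size):
                eps = 1e-3
                orig = w[flat_idx]
                w[flat_idx] = orig + eps
                up = loss()
                w[flat_idx] = orig - eps
                down = loss()
                w[flat_idx] = orig
                diffs.append(abs(g[flat_idx] - (up - down) / (2 * eps)))
            diffs = np.array(diffs)
            # ReLU/max-pool kinks make a few coordinates legitimately
            # one-sided; the bulk must agree to finite-difference accuracy
            assert np.median(diffs) < 1e-4, name
            assert np.mean(diffs < 1e-3) >= 0.75, name


class TestTraining:
    def test_learns_separable_band_signatures(self):
        rng = np.random.default_rng(0)
        segs = band_segments(60, rng)
        x, y = segments_to_array(segs)
        m = build_cnn(seed=0)
        hist = train_cnn(m, x, y, x[:16], y[:16],
                         TrainConfig(epochs=10, patience=10, seed=0))
        assert max(hist["train_acc"]) >= 0.95
        assert len(hist["train_acc"]) <= 10

    def test_early_stopping_contract(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(24, 16, 32, 1)).astype(np.float32)
        y = (rng.random(24) < 0.5).astype(np.float32)
        y[0], y[1] = 0.0, 1.0
        m = build_cnn(TINY, seed=0)
        hist = train_cnn(m, x, y, x, y,
                         TrainConfig(epochs=10, patience=1, seed=0))
        n_epochs = len(hist["train_acc"])
        assert 2 <= n_epochs <= 10
        assert len(hist["val_acc"]) == n_epochs

    def test_single_class_training_rejected(self):
        x = np.zeros((8, 16, 32, 1), dtype=np.float32)
        y = np.ones(8, dtype=np.float32)
        with pytest.raises(ValueError):
            train_cnn(build_cnn(TINY), x, y, x, y, TrainConfig(epochs=1))

    def test_fixed_seed_reproducible_history(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(32, 16, 32, 1)).astype(np.float32)
        y = (np.arange(32) % 2).astype(np.float32)
        h1 = train_cnn(build_cnn(TINY, seed=3), x, y, x, y,
                       TrainConfig(epochs=3, patience=5, seed=7))
        h2 = train_cnn(build_cnn(TINY, seed=3), x, y, x, y,
                       TrainConfig(epochs=3, patience=5, seed=7))
        assert h1 == h2


class TestPrediction:
    def test_inference_is_deterministic_and_order_preserving(self):
        rng = np.random.default_rng(3)
        segs = band_segments(3, rng)
        m = build_cnn(seed=0)
        p1 = predict_segments(m, segs)
        p2 = predict_segments(m, segs)
        np.testing.assert_array_equal(p1, p2)
        perm = [3, 0, 5, 1, 4, 2]
        p3 = predict_segments(m, [segs[i] for i in perm])
        np.testing.assert_allclose(p3, p1[perm], atol=1e-7)
        assert np.all((p1 >= 0) & (p1 <= 1))

    def test_shape_mismatch_rejected(self):
        m = build_cnn(seed=0)
        bad = LogMelSegment(np.zeros((32, 200), dtype=np.float32),
                            "p", "t", 0, 0)
        with pytest.raises(ValueError):
            predict_segments(m, [bad])

    def test_checkpoint_round_trip(self, tmp_path):
        m = build_cnn(TINY, seed=4)
        x = np.random.default_rng(5).normal(
            size=(6, 16, 32, 1)).astype(np.float32)
        save_checkpoint(m, tmp_path / "ckpt")
        restored = load_checkpoint(tmp_path / "ckpt")
        assert restored.arch == m.arch
        np.testing.assert_array_equal(restored.predict_proba(x),
                                      m.predict_proba(x))


class TestBaselines:
    def toy(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        X0 = rng.normal(0.0, 0.5, (n, 2))
        X1 = rng.normal(4.0, 0.5, (n, 2))
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        return X, y

    def test_linear_svm_separates_offset_clusters(self):
        X, y = self.toy()
        est = fit_baseline(BaselineSpec("svm_linear"), X, y)
        labels, scores = predict_baseline(est, X)
        assert np.mean(labels == y) == 1.0
        assert scores.shape == (len(y),)

    def test_knn_unanimous_neighborhood(self):
        X = np.array([[0.0], [0.1], [0.2], [0.05], [0.15],
                      [5.0], [5.1], [5.2], [5.05], [5.15]])
        y = np.array([0] * 5 + [1] * 5)
        est = fit_baseline(BaselineSpec("knn"), X, y)
        labels, _ = predict_baseline(est, np.array([[0.1], [5.1]]))
        assert list(labels) == [0, 1]

    def test_rf_seeded_and_accurate_out_of_sample(self):
        X, y = self.toy(seed=1, n=60)
        Xte, yte = self.toy(seed=2, n=30)
        est1 = fit_baseline(BaselineSpec("rf", seed=5), X, y)
        est2 = fit_baseline(BaselineSpec("rf", seed=5), X, y)
        l1, s1 = predict_baseline(est1, Xte)
        l2, s2 = predict_baseline(est2, Xte)
        assert np.mean(l1 == yte) >= 0.95
        np.testing.assert_array_equal(s1, s2)

    def test_lda_runs_and_scores(self):
        X, y = self.toy(seed=3)
        est = fit_baseline(BaselineSpec("lda"), X, y)
        labels, scores = predict_baseline(est, X)
        assert np.mean(labels == y) == 1.0

    def test_single_class_rejected(self):
        X = np.zeros((6, 2))
        with pytest.raises(ValueError):
            fit_baseline(BaselineSpec("rf"), X, np.ones(6, int))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            BaselineSpec("mlp")
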