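"""Shuffle-block classifier: permutation algebra, splits, gradients,
learning behavior and the 2-D embedding."""

import numpy as np
import pytest

from clss import nn
from clss.classifier import (
    EvalReport,
    ModelConfig,
    ShuffleBlockNet,
    build_model,
    channel_shuffle,
    embed_2d,
    evaluate,
    split_dataset,
    train,
)

TINY = ModelConfig(stem_filters=4, stage_widths=(8, 8), blocks_per_stage=1,
                   penultimate=8, epochs=5, seed=3)


class TestSplit:
    def test_80_20_counts(self):
        tr, te = split_dataset(100, 0.8, seed=0)
        assert tr.size == 80 and te.size == 20

    def test_deterministic_and_partitioning(self):
        tr1, te1 = split_dataset(57, 0.8, seed=5)
        tr2, te2 = split_dataset(57, 0.8, seed=5)
        np.testing.assert_array_equal(tr1, tr2)
        all_idx = np.sort(np.concatenate([tr1, te1]))
        np.testing.assert_array_equal(all_idx, np.arange(57))
        assert np.intersect1d(tr1, te1).size == 0

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_bad_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            split_dataset(10, frac, 0)


class TestChannelShuffle:
    def test_known_permutation_c4_g2(self):
        """reshape(2, 2) -> transpose -> flatten maps [0,1,2,3] to
        [0,2,1,3] (hand-enumerated)."""
        x = np.arange(4, dtype=float)[None, :, None, None]
        out = channel_shuffle(x, 2)
        np.testing.assert_array_equal(out[0, :, 0, 0], [0, 2, 1, 3])

    def test_composition_with_complement_is_identity(self, rng):
        x = rng.normal(size=(3, 12, 2, 5))
        for g in (2, 3, 4, 6):
            back = channel_shuffle(channel_shuffle(x, g), 12 // g)
            np.testing.assert_array_equal(back, x)

    def test_groups_one_is_identity(self, rng):
        x = rng.normal(size=(2, 6, 1, 4))
        np.testing.assert_array_equal(channel_shuffle(x, 1), x)

    def test_is_a_permutation(self, rng):
        x = rng.normal(size=(2, 8, 3, 3))
        out = channel_shuffle(x, 4)
        np.testing.assert_array_equal(np.sort(out, axis=1), np.sort(x, axis=1))

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            channel_shuffle(rng.normal(size=(1, 5, 2, 2)), 2)


class TestModel:
    def test_forward_shape_and_softmax_rows(self, rng):
        model = build_model(TINY)
        probs = model.predict_proba(rng.normal(size=(7, 4, 18)))
        assert probs.shape == (7, 9)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-9)

    def test_untrained_accuracy_is_chance_level(self):
        """Over 20 random initializations the untrained model predicts
        balanced labels at ~1/9 accuracy (binomial Monte Carlo band)."""
        accs = []
        x = np.random.default_rng(0).normal(size=(180, 4, 18))
        y = np.tile(np.arange(9), 20)
        for seed in range(20):
            cfg = ModelConfig(stem_filters=4, stage_widths=(8, 8),
                              blocks_per_stage=1, penultimate=8, seed=seed)
            model = build_model(cfg)
            accs.append(float(np.mean(model.predict(x) == y)))
        mean = np.mean(accs)
        sd = np.sqrt((1 / 9) * (8 / 9) / (180 * 20))
        assert abs(mean - 1 / 9) < 3 * sd + 0.02

    def test_width_increase_increases_parameters(self):
        small = build_model(ModelConfig(stage_widths=(24, 48)))
        big = build_model(ModelConfig(stage_widths=(48, 96)))
        assert big.n_parameters > small.n_parameters

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ModelConfig(stage_widths=(47, 96))

    def test_gradients_match_directional_derivative(self, rng):
        """Backprop agrees with a central-difference directional
        derivative through the whole network."""
        model = build_model(TINY)
        x = rng.normal(size=(6, 4, 18))
        y = rng.integers(0, 9, size=6)
        loss_fn = nn.SoftmaxCrossEntropy()
        for g in model.grads:
            g[...] = 0
        loss_fn.forward(model.forward(x, train=True), y)
        model.backward(loss_fn.backward())
        dirs = [rng.normal(size=p.shape) for p in model.params]
        eps = 1e-6
        for p, d in zip(model.params, dirs):
            p += eps * d
        lp = loss_fn.forward(model.forward(x, True), y)
        for p, d in zip(model.params, dirs):
            p -= 2 * eps * d
        lm = loss_fn.forward(model.forward(x, True), y)
        num = (lp - lm) / (2 * eps)
        ana = sum(float((g * d).sum()) for g, d in zip(model.grads, dirs))
        assert ana == pytest.approx(num, rel=1e-6)


class TestTraining:
    def _blobs(self, n_classes=2, n_per=40, seed=5):
        rng = np.random.default_rng(seed)
        centers = rng.normal(size=(n_classes, 4, 18)) * 2.0
        x = np.concatenate([c + 0.1 * rng.normal(size=(n_per, 4, 18))
                            for c in centers])
        y = np.repeat(np.arange(n_classes), n_per)
        return x, y

    def test_separable_blobs_reach_full_training_accuracy(self):
        x, y = self._blobs()
        cfg = ModelConfig(stem_filters=8, stage_widths=(16, 16),
                          blocks_per_stage=1, penultimate=16,
                          epochs=40, seed=1)
        model = build_model(cfg)
        history = train(model, x, y, cfg)
        assert max(history["accuracy"]) == 1.0

    def test_training_deterministic_given_seed(self):
        x, y = self._blobs()
        runs = []
        for _ in range(2):
            model = build_model(TINY)
            history = train(model, x, y, TINY)
            runs.append((history["loss"][-1],
                         model.params[0].copy()))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_loss_decreases_on_average(self):
        x, y = self._blobs(n_classes=4)
        cfg = ModelConfig(stem_filters=8, stage_widths=(16, 16),
                          blocks_per_stage=1, penultimate=16,
                          epochs=20, seed=2)
        model = build_model(cfg)
        history = train(model, x, y, cfg)
        first = np.mean(history["loss"][:5])
        last = np.mean(history["loss"][-5:])
        assert last < first

    def test_label_shuffled_data_stays_at_chance(self):
        """Training on permuted labels gives held-out accuracy at the
        1/9 chance level (permutation-null Monte Carlo)."""
        rng = np.random.default_rng(11)
        accs = []
        for run in range(6):
            x = rng.normal(size=(270, 4, 18))
            y = rng.permutation(np.tile(np.arange(9), 30))
            cfg = ModelConfig(stem_filters=4, stage_widths=(8, 8),
                              blocks_per_stage=1, penultimate=8,
                              epochs=8, seed=run)
            model = build_model(cfg)
            train(model, x[:180], y[:180], cfg)
            accs.append(float(np.mean(model.predict(x[180:]) == y[180:])))
        mean = np.mean(accs)
        se = max(np.std(accs) / np.sqrt(len(accs)),
                 np.sqrt((1 / 9) * (8 / 9) / (90 * len(accs))))
        assert abs(mean - 1 / 9) <= 3 * se + 0.02

    def test_single_class_training_rejected(self):
        x = np.zeros((10, 4, 18))
        with pytest.raises(ValueError, match="single class"):
            train(build_model(TINY), x, np.zeros(10, dtype=int), TINY)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(build_model(TINY), np.zeros((0, 4, 18)),
                  np.zeros(0, dtype=int), TINY)


class TestEvaluate:
    def test_perfect_predictor_diagonal_confusion(self, rng):
        """Evaluating a model against its own predictions as labels
        gives a diagonal confusion matrix and accuracy one."""
        model = build_model(TINY)
        x = rng.normal(size=(45, 4, 18))
        y = model.predict(x)
        if np.unique(y).size < 2:  # degenerate init; nudge labels
            y[0] = (y[0] + 1) % 9
            y[1:] = model.predict(x[1:])
        report = evaluate(model, x, model.predict(x))
        off_diag = report.confusion - np.diag(np.diag(report.confusion))
        assert off_diag.sum() == 0
        assert report.accuracy == 1.0

    def test_confusion_rows_sum_to_class_counts(self, rng):
        model = build_model(TINY)
        x = rng.normal(size=(90, 4, 18))
        y = np.tile(np.arange(9), 10)
        report = evaluate(model, x, y)
        np.testing.assert_array_equal(report.confusion.sum(axis=1),
                                      np.full(9, 10))
        assert report.accuracy == np.trace(report.confusion) / 90

    def test_inconsistent_report_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            EvalReport(accuracy=0.9, confusion=np.eye(9, dtype=int),
                       per_class_recall=np.ones(9))

    def test_empty_test_set_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            evaluate(build_model(TINY), np.zeros((0, 4, 18)),
                     np.zeros(0, dtype=int))


class TestEmbedding:
    def test_two_dimensions_and_determinism(self, rng):
        acts = rng.normal(size=(60, 8))
        e1 = embed_2d(acts, seed=4, perplexity=10)
        e2 = embed_2d(acts, seed=4, perplexity=10)
        assert e1.shape == (60, 2)
        np.testing.assert_array_equal(e1, e2)

    def test_duplicated_points_land_close(self, rng):
        base = rng.normal(size=(30, 8))
        acts = np.vstack([base, base])  # each point duplicated
        emb = embed_2d(acts, seed=0, perplexity=10)
        dup_d = np.linalg.norm(emb[:30] - emb[30:], axis=1)
        all_d = np.linalg.norm(emb[None, :30] - emb[:30, None], axis=-1)
        typical = np.median(all_d[np.triu_indices(30, 1)])
        assert np.median(dup_d) < 0.1 * typical

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            embed_2d(rng.normal(size=(5, 8)))
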