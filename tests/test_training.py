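"""Weighted loss, sampler, augmentation, schedules and the fit loop."""

import numpy as np
import pytest

import pvcnet as pv
from pvcnet.training import (
    PlateauEarlyStop,
    replay_validation_trace,
    weighted_bce,
)


class TestClassWeights:
    def test_balanced_batch_gives_equal_halves(self):
        y = np.array([0] * 16 + [1] * 16)
        assert np.allclose(pv.class_weights(y), [0.5, 0.5])

    def test_imbalanced_batch_upweights_the_rare_class(self):
        y = np.array([0] * 28 + [1] * 4)
        eta = pv.class_weights(y)
        assert np.allclose(eta, [4 / 32, 28 / 32])  # eta_N=0.125, eta_PVC=0.875

    def test_single_class_batch_degenerates_to_zero_weight(self):
        eta = pv.class_weights(np.zeros(8, dtype=int))
        assert eta[0] == 0.0 and eta[1] == 1.0


class TestWeightedBce:
    def test_perfect_prediction_is_zero_loss(self):
        y = np.array([0, 1, 1, 0])
        p = y.astype(float)
        assert weighted_bce(p, y, np.array([0.5, 0.5])) < 1e-5

    def test_balanced_weights_halve_the_unweighted_loss(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 16)
        p = rng.uniform(0.05, 0.95, y.size)
        half = weighted_bce(p, y, np.array([0.5, 0.5]))
        full = weighted_bce(p, y, np.array([1.0, 1.0]))
        assert np.isclose(half, 0.5 * full, atol=1e-6)

    def test_two_sample_hand_arithmetic(self):
        loss = weighted_bce(
            np.array([0.5, 0.5]), np.array([0, 1]), np.array([0.5, 0.5])
        )
        assert np.isclose(loss, 0.5 * np.log(2.0), atol=1e-6)

    def test_loss_is_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.integers(0, 2, 16)
            p = rng.uniform(0, 1, 16)
            assert weighted_bce(p, y, pv.class_weights(y)) >= 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            weighted_bce(np.array([0.5]), np.array([0, 1]), np.array([0.5, 0.5]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 8)
        p = rng.uniform(0.1, 0.9, 8)
        eta = pv.class_weights(y)
        _, grad = weighted_bce(p, y, eta, return_grad=True)
        eps = 1e-6
        for i in range(8):
            pp, pm = p.copy(), p.copy()
            pp[i] += eps
            pm[i] -= eps
            num = (weighted_bce(pp, y, eta) - weighted_bce(pm, y, eta)) / (2 * eps)
            assert np.isclose(grad[i], num, atol=1e-5)


class TestWeightedSampler:
    def test_draw_frequencies_balance_the_classes(self):
        labels = np.array([0] * 900 + [1] * 100)
        _, draw = pv.make_weighted_sampler(labels, seed=0)
        idx = draw(10_000)
        pvc_frac = labels[idx].mean()
        se = np.sqrt(0.25 / 10_000)
        assert abs(pvc_frac - 0.5) <= 3 * se

    def test_balanced_dataset_gives_equal_weights(self):
        weights, _ = pv.make_weighted_sampler(np.array([0, 1] * 10), seed=0)
        assert np.allclose(weights, weights[0])

    def test_fixed_seed_reproduces_the_draw_sequence(self):
        labels = np.array([0] * 50 + [1] * 10)
        _, draw_a = pv.make_weighted_sampler(labels, seed=9)
        _, draw_b = pv.make_weighted_sampler(labels, seed=9)
        assert np.array_equal(draw_a(100), draw_b(100))

    def test_single_class_dataset_names_the_missing_class(self):
        with pytest.raises(ValueError, match="PVC"):
            pv.make_weighted_sampler(np.zeros(10, dtype=int), seed=0)


class TestAugmentation:
    def _image(self):
        rec, _ = pv.generate_record(pv.RhythmSpec(n_beats=5, seed=3))
        beats = pv.segment_beats(rec, [a.sample_index for a in rec.annotations])
        return pv.render_beat_image(beats[0], pv.RenderConfig(height=64, width=64))

    def test_disabled_augmentation_is_pixel_identity(self):
        img = self._image()
        out = pv.augment(img, pv.AugmentConfig(enabled=False), np.random.default_rng(0))
        assert np.array_equal(out.pixels, img.pixels)

    def test_fixed_rng_state_reproduces_the_output(self):
        img = self._image()
        cfg = pv.AugmentConfig(enabled=True)
        a = pv.augment(img, cfg, np.random.default_rng(7))
        b = pv.augment(img, cfg, np.random.default_rng(7))
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, img.pixels)

    def test_trained_model_is_stable_under_augmentation(self, trained_tiny):
        # jittered copies of one beat should rarely flip the classification
        model, ds, _ = trained_tiny
        chw = ds.images[0]
        base_pred = model.predict(chw[None])[0]
        rng = np.random.default_rng(3)
        cfg = pv.AugmentConfig(enabled=True)
        from pvcnet.training import _augment_chw

        copies = np.stack([_augment_chw(chw.astype(np.float64), cfg, rng) for _ in range(300)])
        preds = model.predict(copies)
        assert (preds == base_pred).mean() >= 0.95


class TestSchedules:
    def test_learning_rate_decreases_only_in_exact_tenfold_steps(self):
        trace = [1.0, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8]
        hist = replay_validation_trace(trace, pv.TrainConfig(max_epochs=50))
        lrs = hist.learning_rate
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        for a, b in zip(lrs, lrs[1:]):
            assert b == a or np.isclose(b, 0.1 * a)

    def test_strictly_improving_trace_runs_to_max_epochs(self):
        trace = [1.0 / (k + 1) for k in range(10)]
        hist = replay_validation_trace(trace, pv.TrainConfig(max_epochs=10))
        assert hist.stop_epoch == 10
        assert hist.stop_reason == "max_epochs"

    def test_patience_counts_reset_on_improvement(self):
        ctl = PlateauEarlyStop(plateau_patience=2, early_stop_patience=4)
        flags = [ctl.update(v) for v in [1.0, 0.9, 0.95, 0.95, 0.5, 0.6, 0.6, 0.6, 0.6]]
        reduce_at = [i for i, (r, _) in enumerate(flags) if r]
        stop_at = [i for i, (_, s) in enumerate(flags) if s]
        assert reduce_at == [3, 6, 8]
        assert stop_at == [8]


class TestFit:
    def test_fit_learns_separable_synthetic_beats(self, trained_tiny):
        model, ds, hist = trained_tiny
        assert hist.train_loss[-1] < hist.train_loss[0]
        acc = (model.predict(ds.images) == ds.labels).mean()
        assert acc > 0.9
        assert all(b <= a for a, b in zip(hist.learning_rate, hist.learning_rate[1:]))

    def test_fit_refuses_subject_overlap_with_evaluation(self, trained_tiny):
        _, ds, _ = trained_tiny
        model = pv.build_model(pv.resnet_tiny_spec(), seed=0)
        some_subject = str(ds.subjects[0])
        with pytest.raises(ValueError, match=some_subject):
            pv.fit(model, ds, pv.TrainConfig(max_epochs=1), eval_subjects={some_subject})

    def test_fit_rejects_empty_dataset(self):
        empty = pv.BeatDataset(
            np.zeros((0, 3, 8, 8), dtype=np.float32), np.zeros(0, dtype=int),
            np.array([], dtype=object),
        )
        model = pv.build_model(pv.resnet_tiny_spec(), seed=0)
        with pytest.raises(ValueError, match="empty"):
            pv.fit(model, empty, pv.TrainConfig(max_epochs=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            pv.TrainConfig(validation_fraction=0.0)
        with pytest.raises(ValueError):
            pv.TrainConfig(plateau_patience=0)
        with pytest.raises(ValueError):
            pv.TrainConfig(sampler="other")
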