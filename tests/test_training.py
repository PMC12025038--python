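"""Training loop: schedule, SGD step, stopping, pruning persistence."""

import dataclasses

import numpy as np
import pytest

from fssmr import losses, mwr
from fssmr.network import MultiStreamCNN, NetworkSpec
from fssmr.phantoms import CLASSES, generate_dataset
from fssmr.training import (
    TrainConfig,
    evaluate,
    lr_schedule,
    samples_to_arrays,
    sgd_momentum_step,
    stratified_split,
    train,
)


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,want", [(0, 0.001), (10, 0.0009), (25, 0.00081)])
    def test_step_decay(self, epoch, want):
        assert lr_schedule(epoch, TrainConfig()) == pytest.approx(want)


class TestSgdStep:
    def test_plain_gradient_descent_limit(self):
        w = np.array([1.0])
        v = np.zeros(1)
        sgd_momentum_step(w, np.array([0.5]), v, lr=0.1, momentum=0.0)
        assert w[0] == pytest.approx(0.95)

    def test_zero_gradient_zero_velocity_no_change(self):
        w = np.array([2.0, -1.0])
        v = np.zeros(2)
        sgd_momentum_step(w, np.zeros(2), v, lr=0.1)
        np.testing.assert_array_equal(w, [2.0, -1.0])

    def test_masked_positions_frozen(self):
        w = np.array([1.0, 2.0])
        v = np.zeros(2)
        mask = np.array([True, False])
        w *= mask  # pruned position starts at zero
        sgd_momentum_step(w, np.array([0.5, 0.5]), v, lr=0.1, mask=mask)
        assert w[1] == 0.0 and v[1] == 0.0 and w[0] != 1.0

    def test_nonfinite_gradient_rejected(self):
        w = np.array([1.0])
        v = np.zeros(1)
        ok = sgd_momentum_step(w, np.array([np.nan]), v, lr=0.1)
        assert not ok and w[0] == 1.0


class _StubModel:
    """Protocol stand-in emitting fixed logits; no trainable layers."""

    def __init__(self, class_logits_fn, image_size=8):
        self._fn = class_logits_fn
        self._hw = image_size

    def forward(self, x, train=False):
        n = len(x)
        seg = np.zeros((n, 2, self._hw, self._hw))
        seg[:, 0] = 5.0  # confident background
        return self._fn(x), seg

    def backward(self, d_class, d_seg):
        pass

    def prunable_layers(self, include_heads=False):
        return iter(())

    def n_parameters(self):
        return 1

    def n_nonzero(self):
        return 1


def _tiny_splits(n=24, image_size=8, seed=0):
    from fssmr.phantoms import PhantomSpec
    spec = PhantomSpec(image_size=image_size, kidney_axes=(3.0, 2.5),
                       lesion_params_per_class={
                           "cyst": {"radius": (1.0, 1.8), "offset": -0.35},
                           "stone": {"radius": (0.8, 1.2), "offset": 0.55},
                           "tumor": {"radius": (1.0, 2.0), "offset": 0.30},
                       })
    samples, _ = generate_dataset(n, spec=spec, seed=seed)
    return stratified_split(samples, seed=seed)


def _tiny_model(image_size=8, seed=0, dropout=0.0):
    spec = NetworkSpec(
        image_size=image_size,
        stream_channels=((4, 3), (4, 3)),
        stream_dilations=(1, 2),
        dropout_rate=dropout,
    )
    return MultiStreamCNN(spec, seed=seed)


class TestTrainLoop:
    def test_constant_val_loss_stops_by_patience(self):
        model = _StubModel(lambda x: np.tile([5.0, 0.0, 0.0, 0.0], (len(x), 1)))
        splits = _tiny_splits()
        cfg = TrainConfig(epochs=30, alpha=0.0, patience=10, min_delta=0.01, seed=0)
        report = train(model, splits, cfg)
        assert report.stop_reason == "patience"
        assert len(report.records) == cfg.patience + 1

    def test_completed_run_has_exact_record_count(self):
        model = _tiny_model()
        cfg = TrainConfig(epochs=3, alpha=0.0, seed=0)
        report = train(model, _tiny_splits(), cfg)
        assert len(report.records) == 3
        assert report.stop_reason == "completed"

    def test_never_stops_before_patience(self):
        model = _StubModel(lambda x: np.tile([5.0, 0.0, 0.0, 0.0], (len(x), 1)))
        cfg = TrainConfig(epochs=10, alpha=0.0, patience=10, seed=0)
        report = train(model, _tiny_splits(), cfg)
        assert report.stop_reason == "completed"
        assert len(report.records) == 10

    def test_memorization_loss_decreases(self):
        """With pruning off and a small lr, total training loss falls over
        the first 10 epochs on a 20-sample memorization set."""
        samples, _ = generate_dataset(20, seed=9)
        splits = (samples, samples)
        spec = NetworkSpec(image_size=46, stream_channels=((6, 5), (6, 5)),
                           stream_dilations=(1, 2), dropout_rate=0.0)
        model = MultiStreamCNN(spec, seed=1)
        cfg = TrainConfig(epochs=10, alpha=0.0, lr0=0.01, seed=1)
        report = train(model, splits, cfg)
        assert report.records[-1].train_total_loss < report.records[0].train_total_loss

    def test_fixed_seed_bit_identical(self):
        def run():
            model = _tiny_model(seed=2, dropout=0.1)
            cfg = TrainConfig(epochs=4, alpha=0.5, prune_warmup=2,
                              prune_every=2, seed=2)
            return train(model, _tiny_splits(seed=2), cfg)

        a, b = run(), run()
        assert [dataclasses.asdict(r) for r in a.records] == [
            dataclasses.asdict(r) for r in b.records
        ]

    def test_lr_column_matches_schedule(self):
        model = _tiny_model()
        cfg = TrainConfig(epochs=3, alpha=0.0, seed=0)
        report = train(model, _tiny_splits(), cfg)
        for r in report.records:
            assert r.lr == pytest.approx(lr_schedule(r.epoch, cfg))

    def test_pruning_event_recorded_and_masks_persist(self):
        model = _tiny_model(seed=3)
        cfg = TrainConfig(epochs=6, alpha=0.8, prune_warmup=2, prune_every=10,
                          seed=3)
        report = train(model, _tiny_splits(seed=3), cfg)
        assert len(report.prune_events) == 1
        # pruned positions stayed zero through the remaining training steps
        for _, layer in model.prunable_layers():
            assert np.all(layer.W[~layer.mask] == 0.0)
        assert report.records[-1].sparsity > 0


class TestMaskCorrectnessEndToEnd:
    def test_pruned_forward_equals_manually_zeroed_dense(self):
        model = _tiny_model(seed=4)
        x = np.random.default_rng(0).random((3, 1, 8, 8))
        dense_weights = {
            name: layer.W.copy() for name, layer in model.prunable_layers(True)
        }
        mwr.apply_pruning(model, alpha=1.0)
        a = model.forward(x, train=False)

        model2 = _tiny_model(seed=4)
        for name, layer in model2.prunable_layers(True):
            if name in dense_weights:
                ref = dict(model.prunable_layers(True))[name]
                layer.W[...] = dense_weights[name] * ref.mask
        b = model2.forward(x, train=False)
        np.testing.assert_allclose(a[0], b[0], atol=1e-12)
        np.testing.assert_allclose(a[1], b[1], atol=1e-12)


class TestEvaluate:
    def test_perfect_stub_scores_one(self):
        splits = _tiny_splits()
        val = splits[1]
        X, y_seg, y_cls = samples_to_arrays(val)

        class Perfect(_StubModel):
            def forward(self, x, train=False):
                n = len(x)
                # emit the true labels for whichever slice is being evaluated
                idx = [np.flatnonzero((X == xi).all(axis=(1, 2, 3)))[0] for xi in x]
                logits = np.zeros((n, 4))
                logits[np.arange(n), y_cls[idx]] = 10.0
                seg = np.zeros((n, 2, x.shape[2], x.shape[3]))
                seg[:, 0] = 5.0
                return logits, seg

        rep = evaluate(Perfect(None), val)
        assert rep.accuracy == 1.0 and rep.mse == 0.0

    def test_constant_class_on_balanced_split_scores_quarter(self):
        samples, _ = generate_dataset(40, seed=11)
        model = _StubModel(lambda x: np.tile([10.0, 0, 0, 0], (len(x), 1)),
                           image_size=46)
        rep = evaluate(model, samples)
        assert rep.accuracy == pytest.approx(0.25)

    def test_metrics_agree_with_losses_module(self):
        model = _tiny_model(seed=5)
        samples = [s for part in _tiny_splits(n=16, seed=5) for s in part]
        rep = evaluate(model, samples)
        X, y_seg, y_cls = samples_to_arrays(samples)
        class_logits, _ = model.forward(X, train=False)
        direct = losses.macro_metrics(y_cls, class_logits.argmax(axis=1), len(CLASSES))
        assert rep.accuracy == pytest.approx(direct.accuracy)
        assert rep.precision == pytest.approx(direct.precision)
        assert rep.f1 == pytest.approx(direct.f1)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_tiny_model(), [])


class TestStratifiedSplit:
    def test_ratios_and_coverage(self):
        samples, _ = generate_dataset(40, seed=3)
        tr, va, te = stratified_split(samples, seed=0)
        assert len(tr) + len(va) + len(te) == 40
        assert len(tr) == 28  # 70% of each class of 10
        for part in (tr, va, te):
            assert {s.label for s in part} == set(CLASSES)
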