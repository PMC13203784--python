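"""Training automation: plateau schedule and early stopping on scripted
metric sequences, gradient clipping, checkpointing, warm-start transfer,
and the evaluation driver."""

import numpy as np
import pytest

from hybridseg.autodiff import Tensor
from hybridseg.data import ImageRecord, split_by_patient, read_manifest
from hybridseg.model import ArchitectureConfig, HybridUNet
from hybridseg import nn
from hybridseg.training import (
    Adam,
    EarlyStopping,
    ExperimentVariant,
    ReduceLROnPlateau,
    TrainConfig,
    clip_grad_norm,
    evaluate_split,
    fit_minibatch,
    load_checkpoint,
    save_checkpoint,
    sequential_transfer,
    train,
    warm_start,
)


class TestControllers:
    def test_lr_halves_after_five_stagnant_epochs(self):
        opt = Adam([], lr=1e-4)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=5)
        dice = [0.5] + [0.5] * 6  # epoch 0 sets the best; 6 stagnant epochs follow
        reductions = [sched.step(d) for d in dice]
        assert reductions == [False] * 6 + [True]
        assert opt.lr == pytest.approx(5e-5)

    def test_lr_sequence_non_increasing_with_exact_halving(self):
        opt = Adam([], lr=1e-4)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=2)
        lrs = []
        for d in [0.4] * 10:
            sched.step(d)
            lrs.append(opt.lr)
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        distinct = sorted(set(lrs), reverse=True)
        for a, b in zip(distinct, distinct[1:]):
            assert b == pytest.approx(a * 0.5)

    def test_improvement_resets_the_plateau_counter(self):
        opt = Adam([], lr=1e-4)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=3)
        for d in [0.5, 0.5, 0.5, 0.6, 0.6, 0.6, 0.6]:
            sched.step(d)
        assert opt.lr == pytest.approx(1e-4)  # never 3+1 stagnant in a row

    def test_early_stop_after_twelve_stagnant_epochs(self):
        stopper = EarlyStopping(patience=12)
        outcomes = [stopper.step(0.7) for _ in range(14)]
        assert outcomes[:13] == [False] * 13  # first sets best, 12 stale allowed
        assert outcomes[13] is True

    def test_tiny_improvements_do_not_reset_patience(self):
        stopper = EarlyStopping(patience=2, tol=1e-5)
        assert not stopper.step(0.5)
        assert not stopper.step(0.5 + 1e-7)
        assert not stopper.step(0.5 + 2e-7)
        assert stopper.step(0.5 + 3e-7)


class TestClipGradNorm:
    def _params_with_grad(self, grads):
        params = []
        for g in grads:
            p = nn.Parameter(np.zeros_like(g))
            p.grad = g
            params.append(p)
        return params

    def test_huge_gradient_clipped_to_max_norm(self):
        params = self._params_with_grad([np.full(100, 50.0, dtype=np.float32)])
        pre = clip_grad_norm(params, 5.0)
        assert pre == pytest.approx(500.0)
        post = np.sqrt(sum((p.grad**2).sum() for p in params))
        assert post <= 5.0 + 1e-6

    def test_small_gradient_untouched(self):
        g = np.array([0.1, 0.2], dtype=np.float32)
        params = self._params_with_grad([g.copy()])
        clip_grad_norm(params, 5.0)
        np.testing.assert_array_equal(params[0].grad, g)

    def test_global_norm_spans_parameters(self):
        params = self._params_with_grad(
            [np.full(8, 3.0, dtype=np.float32), np.full(8, 4.0, dtype=np.float32)]
        )
        pre = clip_grad_norm(params, 5.0)
        assert pre == pytest.approx(np.sqrt(8 * 9 + 8 * 16))


class TestCheckpointing:
    def test_save_load_round_trip(self, tmp_path, tiny_model):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, tiny_model, epoch=3, best_val_dice=0.87)
        state, meta = load_checkpoint(path)
        assert meta["epoch"] == 3
        assert meta["best_val_dice"] == pytest.approx(0.87)
        assert ArchitectureConfig.from_dict(meta["architecture"]) == tiny_model.cfg
        own = tiny_model.state_dict()
        assert set(state) == set(own)
        for k in own:
            np.testing.assert_array_equal(state[k], own[k])

    def test_corrupt_file_raises_io_error(self, tmp_path):
        path = tmp_path / "bad.npz"
        path.write_bytes(b"not a checkpoint")
        with pytest.raises(IOError):
            load_checkpoint(path)


class TestWarmStart:
    def test_full_restore_reproduces_predictions_bit_exactly(self, tmp_path, tiny_config, rng):
        source = HybridUNet(tiny_config, np.random.default_rng(1))
        path = tmp_path / "best.npz"
        save_checkpoint(path, source, epoch=0, best_val_dice=0.0)
        target = HybridUNet(tiny_config, np.random.default_rng(99))
        report = warm_start(target, path)
        assert not report.from_scratch
        assert not report.missing and not report.shape_mismatch
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        source.eval()
        target.eval()
        np.testing.assert_array_equal(source(x).data, target(x).data)

    def test_missing_path_is_the_from_scratch_branch(self, tmp_path, tiny_model):
        before = {k: v.copy() for k, v in tiny_model.state_dict().items()}
        report = warm_start(tiny_model, tmp_path / "does_not_exist.npz")
        assert report.from_scratch
        after = tiny_model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_cross_architecture_restores_only_name_and_shape_matches(self, tmp_path):
        wide = HybridUNet(
            ArchitectureConfig(base_channels=8, input_size=32,
                               transformer_layers=1, attention_heads=4),
            np.random.default_rng(0),
        )
        path = tmp_path / "wide.npz"
        save_checkpoint(path, wide, epoch=0, best_val_dice=0.0)
        narrow = HybridUNet(
            ArchitectureConfig(base_channels=4, input_size=32,
                               transformer_layers=1, attention_heads=4),
            np.random.default_rng(5),
        )
        before = {k: v.copy() for k, v in narrow.state_dict().items()}
        report = warm_start(narrow, path)
        assert not report.from_scratch
        assert report.shape_mismatch  # channel-dependent tensors cannot load
        assert "bottleneck.pos_embed" in report.shape_mismatch
        after = narrow.state_dict()
        wide_state = wide.state_dict()
        for name in report.shape_mismatch:
            np.testing.assert_array_equal(before[name], after[name])
        for name in report.matched:
            np.testing.assert_array_equal(wide_state[name], after[name])

    def test_corrupt_checkpoint_distinct_from_missing(self, tmp_path, tiny_model):
        path = tmp_path / "corrupt.npz"
        path.write_bytes(b"\x00" * 32)
        with pytest.raises(IOError):
            warm_start(tiny_model, path)


class TestTrainLoop:
    def _quick_cfg(self, **kw):
        defaults = dict(learning_rate=1e-3, max_epochs=3, batch_size=4,
                        input_size=32, seed=0)
        defaults.update(kw)
        return TrainConfig(**defaults)

    def test_best_checkpoint_matches_log_maximum(self, phantom_dataset, tiny_config):
        manifest_path, _ = phantom_dataset
        splits = split_by_patient(read_manifest(manifest_path), seed=0)
        model = HybridUNet(tiny_config, np.random.default_rng(0))
        best, log = train(model, splits, self._quick_cfg(), ExperimentVariant())
        assert best["val_dice"] == pytest.approx(max(log.val_dice))

    def test_two_runs_same_seed_identical_logs(self, phantom_dataset, tiny_config):
        manifest_path, _ = phantom_dataset
        splits = split_by_patient(read_manifest(manifest_path), seed=0)
        logs = []
        for _ in range(2):
            model = HybridUNet(tiny_config, np.random.default_rng(0))
            _, log = train(model, splits, self._quick_cfg(max_epochs=2),
                           ExperimentVariant())
            logs.append(log)
        assert logs[0].train_loss == logs[1].train_loss
        assert logs[0].val_dice == logs[1].val_dice

    def test_empty_train_split_rejected(self, tiny_config):
        from hybridseg.data import DatasetSplit

        model = HybridUNet(tiny_config, np.random.default_rng(0))
        empty = DatasetSplit(train=[], val=[], test=[], ratios=(0.7, 0.15, 0.15), seed=0)
        with pytest.raises(ValueError):
            train(model, empty, self._quick_cfg(), ExperimentVariant())

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            TrainConfig(plateau_patience=12, early_stop_patience=12)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)


class TestSequentialTransfer:
    def test_phase_two_starts_from_phase_one_best(self, phantom_dataset, tmp_path):
        manifest_path, _ = phantom_dataset
        records = read_manifest(manifest_path)
        splits = split_by_patient(records, seed=0)
        arch = ArchitectureConfig(base_channels=4, input_size=32,
                                  transformer_layers=1, attention_heads=4)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=1, batch_size=4,
                          input_size=32, seed=0)
        results = sequential_transfer([splits, splits], cfg,
                                      ExperimentVariant(), arch,
                                      out_dir=tmp_path / "chain")
        assert len(results) == 2
        first_report = results[0][2]
        second_report = results[1][2]
        assert first_report.from_scratch
        assert not second_report.from_scratch
        assert not second_report.missing and not second_report.shape_mismatch
        # phase-2 initialisation equals phase-1 best checkpoint
        phase1_best, _ = load_checkpoint(tmp_path / "chain" / "phase_0" / "best.npz")
        probe = HybridUNet(arch, np.random.default_rng(cfg.seed + 1))
        warm_start(probe, tmp_path / "chain" / "phase_0" / "best.npz")
        for k, v in probe.state_dict().items():
            np.testing.assert_array_equal(v, phase1_best[k])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequential_transfer([], TrainConfig(), ExperimentVariant())


class _OracleModel:
    """Stub that returns the ground-truth mask as its probability map."""

    def __init__(self, answers):
        self.answers = answers
        self.calls = 0

    def eval(self):
        return self

    def __call__(self, x):
        out = self.answers[self.calls][None, None].astype(np.float32)
        self.calls += 1
        return Tensor(out)


class _ConstantModel:
    def eval(self):
        return self

    def __call__(self, x):
        return Tensor(np.full((1, 1, x.shape[2], x.shape[3]), 0.5, dtype=np.float32))


class TestEvaluateSplit:
    def test_oracle_stub_scores_one_everywhere(self, phantom_dataset):
        manifest_path, _ = phantom_dataset
        records = read_manifest(manifest_path)[:4]
        from hybridseg.data import load_pair

        masks = [load_pair(r, target_size=32)[1] for r in records]
        model = _OracleModel(masks)
        report = evaluate_split(model, records, input_size=32, resamples=50)
        assert all(v == pytest.approx(1.0) for v in report.point.values())

    def test_constant_half_scores_give_auc_half(self, phantom_dataset):
        manifest_path, _ = phantom_dataset
        records = read_manifest(manifest_path)[:4]
        report = evaluate_split(_ConstantModel(), records, input_size=32, resamples=50)
        assert report.auc == pytest.approx(0.5)

    def test_report_matches_manual_per_image_loop(self, phantom_dataset, tiny_model):
        from hybridseg.data import load_pair
        from hybridseg.metrics import overlap_metrics
        from hybridseg.model import binarize

        manifest_path, _ = phantom_dataset
        records = read_manifest(manifest_path)[:6]
        report = evaluate_split(tiny_model, records, input_size=32, resamples=50)
        tiny_model.eval()
        manual = []
        for r in records:
            img, msk = load_pair(r, target_size=32)
            pred = binarize(tiny_model(img[None]).data)[0, 0]
            manual.append(overlap_metrics(pred, msk)["dice"])
        assert report.point["dice"] == pytest.approx(float(np.mean(manual)))

    def test_empty_split_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            evaluate_split(tiny_model, [], input_size=32)


class TestFitMinibatch:
    def test_loss_decreases_on_fixed_batch(self, phantom_batch):
        imgs, masks = phantom_batch
        model = HybridUNet(
            ArchitectureConfig(base_channels=4, input_size=32,
                               transformer_layers=1, attention_heads=4),
            np.random.default_rng(0),
        )
        history = fit_minibatch(model, imgs[:4], masks[:4], steps=12, lr=3e-3)
        assert history[-1] > history[0]
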