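"""Training loop, freezing protocols, and fine-tune contracts."""

from dataclasses import replace

import numpy as np
import pytest

from mitransfer.io import TrialTensor
from mitransfer.model import EEGNet
from mitransfer.transfer import (TrainConfig, TransferPlan, apply_plan,
                                 evaluate_accuracy, finetune, pretrain, train)


@pytest.fixture(scope="module")
def source_weights(fast_trials, fast_model_cfg):
    weights, _ = pretrain(fast_trials, fast_model_cfg,
                          TrainConfig(epochs=10, seed=0))
    return weights


class TestTrainConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)


class TestPlans:
    @pytest.mark.parametrize("name,frozen", [
        ("eegnet_0", set()),
        ("eegnet_1", {"block1"}),
        ("eegnet_2", {"block1", "block2"}),
    ])
    def test_frozen_blocks_per_plan(self, name, frozen):
        plan = TransferPlan.from_name(name)
        assert set(plan.frozen_blocks) == frozen
        assert plan.uses_source_weights == (name != "eegnet_0")

    def test_unknown_plan_rejected(self):
        with pytest.raises(ValueError, match="unknown plan"):
            TransferPlan.from_name("eegnet_3")

    def test_trainable_flags(self, source_weights, fast_model_cfg):
        m1 = apply_plan(source_weights, TransferPlan.from_name("eegnet_1"),
                        fast_model_cfg)
        for p in m1.parameters():
            assert p.trainable == (p.block != "block1"), p.name
        m0 = apply_plan(None, TransferPlan.from_name("eegnet_0"), fast_model_cfg)
        assert m0.frozen_parameter_names() == []
        m2 = apply_plan(source_weights, TransferPlan.from_name("eegnet_2"),
                        fast_model_cfg)
        trainable = [p.name for p in m2.parameters() if p.trainable]
        assert all(n.startswith("classifier.") for n in trainable)
        assert trainable  # classifier head itself remains trainable

    def test_missing_source_weights_rejected(self, fast_model_cfg):
        with pytest.raises(ValueError, match="requires pre-trained"):
            apply_plan(None, TransferPlan.from_name("eegnet_1"), fast_model_cfg)

    def test_classifier_reinitialized_blocks_loaded(self, source_weights,
                                                    fast_model_cfg):
        m = apply_plan(source_weights, TransferPlan.from_name("eegnet_1"),
                       fast_model_cfg, seed=5)
        np.testing.assert_array_equal(
            m.conv_temporal.w.value, source_weights["block1.conv_temporal.w"])
        assert np.abs(m.dense.w.value
                      - source_weights["classifier.dense.w"]).max() > 0


class TestTraining:
    def test_pretrain_is_seeded_deterministic(self, fast_trials,
                                              fast_model_cfg):
        tc = TrainConfig(epochs=5, seed=4)
        w1, h1 = pretrain(fast_trials, fast_model_cfg, tc)
        w2, h2 = pretrain(fast_trials, fast_model_cfg, tc)
        assert h1.loss == h2.loss
        for k in w1:
            np.testing.assert_array_equal(w1[k], w2[k])

    def test_single_class_data_rejected(self, fast_trials, fast_model_cfg):
        bad = TrialTensor(fast_trials.data, np.zeros(fast_trials.n_trials),
                          fast_trials.fs, fast_trials.class_names)
        with pytest.raises(ValueError, match="two classes"):
            pretrain(bad, fast_model_cfg, TrainConfig(epochs=1))

    def test_frozen_weights_bitwise_unchanged(self, source_weights,
                                              fast_trials, fast_model_cfg):
        model = apply_plan(source_weights, TransferPlan.from_name("eegnet_1"),
                           fast_model_cfg)
        before = {p.name: p.value.copy() for p in model.parameters()
                  if not p.trainable}
        stats_before = {k: v.copy() for bn in model.bn_layers()
                        for k, v in bn.state().items()
                        if k.startswith("block1")}
        finetune(model, fast_trials, TrainConfig(epochs=5, seed=1))
        for p in model.parameters():
            if p.name in before:
                np.testing.assert_array_equal(p.value, before[p.name])
        for bn in model.bn_layers():
            for k, v in bn.state().items():
                if k in stats_before:
                    np.testing.assert_array_equal(v, stats_before[k])

    def test_trainable_weights_move(self, source_weights, fast_trials,
                                    fast_model_cfg):
        model = apply_plan(source_weights, TransferPlan.from_name("eegnet_1"),
                           fast_model_cfg)
        before = model.dense.w.value.copy()
        finetune(model, fast_trials, TrainConfig(epochs=1, seed=1))
        assert np.abs(model.dense.w.value - before).max() > 0

    def test_dense_rows_respect_max_norm_every_epoch(self, fast_trials,
                                                     fast_model_cfg):
        model = EEGNet(fast_model_cfg, seed=0)
        for epoch in range(5):
            train(model, fast_trials, TrainConfig(epochs=1, seed=epoch))
            norms = np.linalg.norm(model.dense.w.value, axis=1)
            assert np.all(norms <= 0.25 + 1e-6)

    def test_fully_frozen_model_rejected(self, source_weights, fast_trials,
                                         fast_model_cfg):
        model = apply_plan(source_weights, TransferPlan.from_name("eegnet_2"),
                           fast_model_cfg)
        model.set_block_trainable("classifier", False)
        with pytest.raises(RuntimeError, match="no trainable"):
            finetune(model, fast_trials, TrainConfig(epochs=1))

    def test_loss_trend_non_increasing_smoothed(self, fast_trials,
                                                fast_model_cfg):
        """On separable synthetic data the window-10 smoothed loss does not
        increase from epoch 10 to 100."""
        model = EEGNet(fast_model_cfg, seed=0)
        history = train(model, fast_trials, TrainConfig(epochs=100, seed=0))
        loss = np.asarray(history.loss)
        smoothed = np.convolve(loss, np.ones(10) / 10, mode="valid")
        assert smoothed[-1] <= smoothed[0] + 1e-3
        diffs = np.diff(smoothed)
        assert np.all(diffs <= 0.02)  # no sustained increase

    def test_training_reaches_high_accuracy_on_separable_data(
            self, fast_trials, fast_model_cfg):
        model = EEGNet(fast_model_cfg, seed=0)
        train(model, fast_trials, TrainConfig(epochs=100, seed=0))
        assert evaluate_accuracy(model, fast_trials) >= 0.95
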