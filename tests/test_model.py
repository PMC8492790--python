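"""Architecture fidelity, parameter counting, and FLOP accounting."""

import numpy as np
import pytest

from mitransfer.model import (EEGNet, EEGNetConfig, LayerSpec, apply_max_norm,
                              complexity_report, count_flops, count_params,
                              load_weights, save_weights, trace_shapes)
from mitransfer import nn


def _random_config(rng):
    pool1 = int(rng.integers(2, 5))
    pool2 = int(rng.integers(2, 9))
    t = int(rng.integers(pool1 * pool2, 400))
    return EEGNetConfig(
        n_channels=int(rng.integers(2, 65)),
        n_samples=t,
        n_classes=int(rng.integers(2, 5)),
        f1=int(rng.integers(1, 9)),
        depth=int(rng.integers(1, 4)),
        f2=int(rng.integers(1, 13)),
        temporal_kernel=int(rng.integers(2, 65)),
        separable_kernel=int(rng.integers(2, 17)),
        pool1=pool1, pool2=pool2,
        dropout_p=float(rng.uniform(0.1, 0.9)),
    )


def _observed_shapes(cfg, batch=2):
    model = EEGNet(cfg, seed=0)
    x = np.random.default_rng(0).normal(size=(batch, cfg.n_channels, cfg.n_samples))
    h = np.ascontiguousarray(x, dtype=np.float32)[:, None]
    shapes = []
    for layer in model.layers:
        h = layer.forward(h, False, None)
        shapes.append(h.shape[1:])
    return model, shapes


class TestShapeTrace:
    def test_symbolic_equals_observed_for_random_configs(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            cfg = _random_config(rng)
            rows = trace_shapes(cfg)
            _, observed = _observed_shapes(cfg)
            for spec, shape in zip(rows, observed):
                assert spec.out_shape == shape, (cfg, spec.name)

    def test_reference_config_block_outputs(self):
        """F1=4, D=2, F2=8: block1 ends at (D*F1, 1, T/4), block2 at
        (F2, 1, T/32); with T=320 that is (8,1,80) and (8,1,10), flatten 80."""
        cfg = EEGNetConfig(n_channels=64, n_samples=320)
        by_name = {r.name: r for r in trace_shapes(cfg)}
        assert by_name["block1.dropout"].out_shape == (8, 1, 80)
        assert by_name["block2.dropout"].out_shape == (8, 1, 10)
        assert by_name["classifier.flatten"].out_shape == (80,)
        assert by_name["classifier.dense"].out_shape == (2,)

    def test_overall_temporal_reduction_is_pool1_times_pool2(self):
        cfg = EEGNetConfig(n_channels=8, n_samples=320)
        rows = trace_shapes(cfg)
        assert rows[-3].out_shape[-1] == 320 // 32

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            EEGNetConfig(n_channels=8, n_samples=16)


class TestForward:
    def test_softmax_normalized(self, tiny_model_cfg, rng):
        model = EEGNet(tiny_model_cfg, seed=0)
        x = rng.normal(size=(7, 6, 64))
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_inference_deterministic(self, tiny_model_cfg, rng):
        model = EEGNet(tiny_model_cfg, seed=0)
        x = rng.normal(size=(4, 6, 64))
        a = model.forward(x, training=False)
        b = model.forward(x, training=False)
        np.testing.assert_array_equal(a, b)

    def test_depthwise_has_no_cross_map_connections(self, rng):
        """Zeroing temporal map j changes only its D child maps."""
        cfg = EEGNetConfig(n_channels=6, n_samples=64, f1=3, depth=2, f2=4,
                           temporal_kernel=8, separable_kernel=5,
                           pool1=4, pool2=4)
        layer = nn.SpatialDepthwiseConv(3, 2, 6, np.random.default_rng(0),
                                        dtype=np.float64)
        x = rng.normal(size=(2, 3, 6, 20))
        y_full = layer.forward(x, False)
        x_zeroed = x.copy()
        x_zeroed[:, 1] = 0.0
        y_zeroed = layer.forward(x_zeroed, False)
        children = {2, 3}  # maps j*D .. j*D+D-1 for j=1, D=2
        for m in range(6):
            if m in children:
                assert np.abs(y_full[:, m] - y_zeroed[:, m]).max() > 0
            else:
                np.testing.assert_array_equal(y_full[:, m], y_zeroed[:, m])


class TestParamCounting:
    def test_matches_model_enumeration_random_configs(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            cfg = _random_config(rng)
            model = EEGNet(cfg, seed=0)
            report = count_params(trace_shapes(cfg), conv_bias=cfg.conv_bias)
            enumerated = sum(p.value.size for p in model.parameters())
            assert report.total_trainable_params == enumerated
            stats = sum(v.size for bn in model.bn_layers()
                        for v in bn.state().values())
            assert report.total_params == enumerated + stats

    def test_reference_layer_counts(self):
        cfg = EEGNetConfig(n_channels=64, n_samples=320)
        rows = {r["name"]: r for r in count_params(trace_shapes(cfg)).rows}
        assert rows["classifier.dense"]["params"] == 80 * 2 + 2  # 162
        assert rows["block1.conv_spatial"]["params"] == 4 * 2 * 64  # 512
        assert rows["block1.conv_temporal"]["params"] == 4 * 64  # bias-free

    def test_empty_layer_list_zero_totals(self):
        report = count_params([])
        assert report.total_params == 0
        assert report.total_flops == 0

    def test_bytes_follow_param_count(self):
        cfg = EEGNetConfig(n_channels=8, n_samples=64)
        report = count_params(trace_shapes(cfg))
        assert report.total_bytes == 4 * report.total_params


class TestFlopCounting:
    def test_dense_flops_by_direct_enumeration(self):
        spec = LayerSpec("classifier.dense", "dense_softmax", None, 2,
                         (80,), (2,))
        row = count_flops([spec]).rows[0]
        # 80 multiply-adds per unit (x2) + 1 bias add per unit + softmax
        assert row["flops"] == 2 * 80 * 2 + 2 + 3 * 2
        row1 = count_flops([spec], convention="mac1").rows[0]
        assert row1["flops"] == 80 * 2 + 2 + 3 * 2

    def test_pooling_flops_by_brute_force(self):
        """(window-1) additions plus one divide per output element."""
        spec = LayerSpec("p", "average_pool", (1, 8), None, (1, 1, 8), (1, 1, 1))
        row = count_flops([spec]).rows[0]
        adds, divides = 7, 1
        assert row["flops"] == 1 * (adds + divides)

    def test_conv_flops_linear_in_time(self):
        cfg1 = EEGNetConfig(n_channels=8, n_samples=128)
        cfg2 = EEGNetConfig(n_channels=8, n_samples=256)
        f = lambda cfg: {r["name"]: r["flops"]
                         for r in count_flops(trace_shapes(cfg)).rows}
        assert f(cfg2)["block1.conv_temporal"] == 2 * f(cfg1)["block1.conv_temporal"]

    def test_unknown_layer_kind_rejected(self):
        bogus = LayerSpec("x", "recurrent", None, None, (1,), (1,))
        with pytest.raises(ValueError, match="recurrent"):
            count_flops([bogus])

    def test_convention_recorded_and_rendered(self):
        report = complexity_report(EEGNetConfig(n_channels=8, n_samples=64),
                                   convention="mac1")
        assert report.convention == "mac1"
        assert "mac1" in report.render()
        assert "G FLOPs" in report.render()


class TestMaxNormAndWeights:
    def test_apply_max_norm_rescales_only_violations(self, tiny_model_cfg, rng):
        model = EEGNet(tiny_model_cfg, seed=0)
        w = model.dense.w.value
        w[0] = rng.normal(size=w.shape[1]).astype(np.float32)
        w[0] *= 1.0 / np.linalg.norm(w[0])
        w[1] *= 0.1 / np.linalg.norm(w[1])
        apply_max_norm(model, 0.25)
        norms = np.linalg.norm(model.dense.w.value, axis=1)
        assert norms[0] == pytest.approx(0.25, rel=1e-5)
        assert norms[1] == pytest.approx(0.1, rel=1e-5)
        before = model.dense.w.value.copy()
        apply_max_norm(model)
        np.testing.assert_array_equal(model.dense.w.value, before)

    def test_weight_container_round_trip(self, tiny_model_cfg, tmp_path):
        model = EEGNet(tiny_model_cfg, seed=3)
        weights = model.get_weights()
        assert any(k.startswith("block1.") for k in weights)
        assert any(k.startswith("block2.") for k in weights)
        assert any(k.startswith("classifier.") for k in weights)
        path = tmp_path / "w.npz"
        save_weights(weights, path)
        back = load_weights(path)
        model2 = EEGNet(tiny_model_cfg, seed=99)
        model2.set_weights(back)
        x = np.random.default_rng(0).normal(size=(2, 6, 64))
        np.testing.assert_array_equal(model.forward(x), model2.forward(x))
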