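"""The compact EEG CNN (EEGNet-style): construction, shape tracing, and
complexity accounting.

The architecture takes a ``(C, T)`` trial (C channels, T samples), reshapes
it to a single feature map, and applies two blocks followed by a softmax
classifier:

* Block 1 — a temporal convolution with F1 filters of length 64 (learning
  frequency-selective filters), batch norm, then a depthwise spatial
  convolution with D filters per temporal map spanning all C channels
  (learning frequency-specific spatial filters), batch norm, ELU, average
  pooling (1, 4) and dropout.
* Block 2 — a separable convolution (depthwise length-16 temporal kernel
  followed by a 1x1 pointwise combination into F2 maps), batch norm, ELU,
  average pooling (1, 8) and dropout.
* Classifier — flatten and a dense softmax layer whose weight rows carry an
  L2 max-norm bound of 0.25.

Temporal pooling therefore reduces T by a factor of 32 overall.  Block
names ("block1", "block2", "classifier") tag every parameter and are
load-bearing for the transfer-learning module, which freezes whole blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn


@dataclass(frozen=True)
class EEGNetConfig:
    """All architecture hyperparameters.

    Defaults follow the reference setting for two-class motor imagery:
    F1=4 temporal filters, depth multiplier D=2, F2=8 pointwise filters,
    dropout 0.5, dense max-norm 0.25.
    """

    n_channels: int = 64
    n_samples: int = 300
    n_classes: int = 2
    f1: int = 4
    depth: int = 2
    f2: int = 8
    temporal_kernel: int = 64
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout_p: float = 0.5
    dense_max_norm: float = 0.25
    conv_bias: bool = False

    def __post_init__(self) -> None:
        for name in ("n_channels", "n_samples", "n_classes", "f1", "depth",
                     "f2", "temporal_kernel", "separable_kernel", "pool1", "pool2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not 0 < self.dropout_p < 1:
            raise ValueError(f"dropout_p must be in (0, 1), got {self.dropout_p}")
        if self.n_samples // self.pool1 // self.pool2 < 1:
            raise ValueError(
                f"n_samples={self.n_samples} too short for pooling "
                f"{self.pool1}x{self.pool2} (floor semantics need T >= pool1*pool2)"
            )

    @property
    def flat_features(self) -> int:
        return self.f2 * (self.n_samples // self.pool1 // self.pool2)


@dataclass(frozen=True)
class LayerSpec:
    """One symbolic layer row: shapes as (maps, space, time) tuples."""

    name: str
    kind: str
    kernel: tuple[int, int] | None
    filters: int | None
    in_shape: tuple[int, ...]
    out_shape: tuple[int, ...]


def trace_shapes(cfg: EEGNetConfig) -> list[LayerSpec]:
    """Symbolically trace every layer's output shape from the config."""
    c, t = cfg.n_channels, cfg.n_samples
    f1, d, f2 = cfg.f1, cfg.depth, cfg.f2
    t1 = t // cfg.pool1
    t2 = t1 // cfg.pool2
    rows: list[LayerSpec] = []

    def add(name, kind, kernel, filters, ins, outs):
        rows.append(LayerSpec(name, kind, kernel, filters, tuple(ins), tuple(outs)))

    add("block1.conv_temporal", "conv2d", (1, cfg.temporal_kernel), f1,
        (1, c, t), (f1, c, t))
    add("block1.bn_temporal", "batch_norm", None, None, (f1, c, t), (f1, c, t))
    add("block1.conv_spatial", "depthwise_conv2d", (c, 1), d * f1,
        (f1, c, t), (d * f1, 1, t))
    add("block1.bn_spatial", "batch_norm", None, None, (d * f1, 1, t), (d * f1, 1, t))
    add("block1.elu", "activation_elu", None, None, (d * f1, 1, t), (d * f1, 1, t))
    add("block1.pool", "average_pool", (1, cfg.pool1), None,
        (d * f1, 1, t), (d * f1, 1, t1))
    add("block1.dropout", "dropout", None, None, (d * f1, 1, t1), (d * f1, 1, t1))
    add("block2.conv_separable", "separable_conv2d", (1, cfg.separable_kernel), f2,
        (d * f1, 1, t1), (f2, 1, t1))
    add("block2.bn", "batch_norm", None, None, (f2, 1, t1), (f2, 1, t1))
    add("block2.elu", "activation_elu", None, None, (f2, 1, t1), (f2, 1, t1))
    add("block2.pool", "average_pool", (1, cfg.pool2), None, (f2, 1, t1), (f2, 1, t2))
    add("block2.dropout", "dropout", None, None, (f2, 1, t2), (f2, 1, t2))
    add("classifier.flatten", "flatten", None, None, (f2, 1, t2), (f2 * t2,))
    add("classifier.dense", "dense_softmax", None, cfg.n_classes,
        (f2 * t2,), (cfg.n_classes,))
    return rows


class EEGNet:
    """A trainable instance of the architecture (NumPy engine).

    ``forward`` takes trials shaped ``(batch, C, T)`` and returns logits;
    ``predict_proba`` applies softmax with dropout inactive.
    """

    def __init__(self, cfg: EEGNetConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c, t = cfg.n_channels, cfg.n_samples
        self.conv_temporal = nn.TemporalConv(
            cfg.f1, cfg.temporal_kernel, rng, name="block1.conv_temporal",
            block="block1", dtype=dtype)
        self.bn_temporal = nn.BatchNorm(cfg.f1, name="block1.bn_temporal",
                                        block="block1", dtype=dtype)
        self.conv_spatial = nn.SpatialDepthwiseConv(
            cfg.f1, cfg.depth, c, rng, name="block1.conv_spatial",
            block="block1", dtype=dtype)
        self.bn_spatial = nn.BatchNorm(cfg.depth * cfg.f1, name="block1.bn_spatial",
                                       block="block1", dtype=dtype)
        self.conv_separable = nn.SeparableConv(
            cfg.depth * cfg.f1, cfg.f2, cfg.separable_kernel, rng,
            name="block2.conv_separable", block="block2", dtype=dtype)
        self.bn_sep = nn.BatchNorm(cfg.f2, name="block2.bn", block="block2",
                                   dtype=dtype)
        self.dense = nn.Dense(cfg.flat_features, cfg.n_classes, rng,
                              max_norm=cfg.dense_max_norm,
                              name="classifier.dense", block="classifier",
                              dtype=dtype)
        self.layers: list[nn.Layer] = [
            self.conv_temporal,
            self.bn_temporal,
            self.conv_spatial,
            self.bn_spatial,
            nn.ELU(),
            nn.AvgPool(cfg.pool1),
            nn.Dropout(cfg.dropout_p),
            self.conv_separable,
            self.bn_sep,
            nn.ELU(),
            nn.AvgPool(cfg.pool2),
            nn.Dropout(cfg.dropout_p),
            nn.Flatten(),
            self.dense,
        ]

    # -- core passes --------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if x.ndim != 3 or x.shape[1:] != (self.cfg.n_channels, self.cfg.n_samples):
            raise ValueError(
                f"expected input (batch, {self.cfg.n_channels}, "
                f"{self.cfg.n_samples}), got {x.shape}"
            )
        h = np.ascontiguousarray(x, dtype=self.dtype)[:, None]  # (B, 1, C, T)
        for layer in self.layers:
            h = layer.forward(h, training, rng)
        return h

    def backward(self, grad_logits: np.ndarray) -> None:
        g = grad_logits.astype(self.dtype)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, training=False).astype(np.float64))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # -- parameter plumbing --------------------------------------------------

    def parameters(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def bn_layers(self) -> list[nn.BatchNorm]:
        return [l for l in self.layers if isinstance(l, nn.BatchNorm)]

    def get_weights(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for bn in self.bn_layers():
            for k, v in bn.state().items():
                state[k] = v.copy()
        return state

    def set_weights(self, weights: dict[str, np.ndarray],
                    blocks: set[str] | None = None) -> None:
        """Load named weights, optionally restricted to the given blocks."""
        for p in self.parameters():
            if blocks is not None and p.block not in blocks:
                continue
            if p.name in weights:
                if weights[p.name].shape != p.value.shape:
                    raise ValueError(
                        f"shape mismatch for {p.name}: "
                        f"{weights[p.name].shape} vs {p.value.shape}"
                    )
                p.value = weights[p.name].astype(p.value.dtype).copy()
        for bn in self.bn_layers():
            if blocks is not None and bn.gamma.block not in blocks:
                continue
            for k in list(bn.state()):
                if k in weights:
                    if k.endswith("running_mean"):
                        bn.running_mean = weights[k].astype(bn.running_mean.dtype).copy()
                    else:
                        bn.running_var = weights[k].astype(bn.running_var.dtype).copy()

    def set_block_trainable(self, block: str, trainable: bool) -> None:
        for p in self.parameters():
            if p.block == block:
                p.trainable = trainable
        for bn in self.bn_layers():
            if bn.gamma.block == block:
                bn.stats_frozen = not trainable

    def frozen_parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters() if not p.trainable]


def build_eegnet(cfg: EEGNetConfig, seed: int = 0) -> tuple[list[LayerSpec], EEGNet]:
    """Construct the symbolic layer table and a trainable model instance."""
    return trace_shapes(cfg), EEGNet(cfg, seed=seed)


def apply_max_norm(model: EEGNet, bound: float | None = None) -> None:
    """Project dense weight rows onto the max-norm ball (idempotent)."""
    if bound is not None:
        model.dense.max_norm = bound
    model.dense.project_max_norm()


# ---------------------------------------------------------------------------
# Complexity accounting
# ---------------------------------------------------------------------------

@dataclass
class ComplexityReport:
    """Per-layer and total parameter / FLOP counts.

    ``bytes`` follows the parameter-storage convention: number of stored
    parameter values times ``bytes_per_param`` (4 for float32).
    """

    rows: list[dict] = field(default_factory=list)
    convention: str = "mac2"
    bytes_per_param: int = 4

    @property
    def total_params(self) -> int:
        return sum(r["params"] for r in self.rows)

    @property
    def total_trainable_params(self) -> int:
        return sum(r["trainable_params"] for r in self.rows)

    @property
    def total_flops(self) -> int:
        return sum(r["flops"] for r in self.rows)

    @property
    def total_bytes(self) -> int:
        return self.total_params * self.bytes_per_param

    def render(self) -> str:
        lines = [
            f"complexity report (FLOPs convention: {self.convention}; "
            f"{self.bytes_per_param} bytes/param)",
            f"{'layer':<28}{'kind':<20}{'params':>10}{'trainable':>10}{'FLOPs':>12}",
        ]
        for r in self.rows:
            lines.append(
                f"{r['name']:<28}{r['kind']:<20}{r['params']:>10}"
                f"{r['trainable_params']:>10}{r['flops']:>12}"
            )
        lines.append(
            f"{'TOTAL':<28}{'':<20}{self.total_params:>10}"
            f"{self.total_trainable_params:>10}{self.total_flops:>12}"
        )
        lines.append(
            f"totals: {self.total_params / 1e6:.6f} M params, "
            f"{self.total_flops / 1e9:.6f} G FLOPs, {self.total_bytes} bytes"
        )
        return "\n".join(lines)


def _layer_param_counts(spec: LayerSpec, conv_bias: bool) -> tuple[int, int]:
    """(trainable, total) parameter counts for one symbolic layer."""
    if spec.kind == "conv2d":
        kh, kw = spec.kernel
        n = spec.filters * kh * kw + (spec.filters if conv_bias else 0)
        return n, n
    if spec.kind == "depthwise_conv2d":
        kh, kw = spec.kernel
        n = spec.filters * kh * kw + (spec.filters if conv_bias else 0)
        return n, n
    if spec.kind == "separable_conv2d":
        kh, kw = spec.kernel
        maps_in = spec.in_shape[0]
        n = maps_in * kh * kw + spec.filters * maps_in
        n += spec.filters if conv_bias else 0
        return n, n
    if spec.kind == "batch_norm":
        maps = spec.out_shape[0]
        return 2 * maps, 4 * maps  # gamma/beta trainable; running stats stored
    if spec.kind == "dense_softmax":
        fin = spec.in_shape[0]
        n = spec.filters * fin + spec.filters
        return n, n
    return 0, 0


def _layer_flops(spec: LayerSpec, mac: int) -> int:
    """Inference FLOPs for one trial.  ``mac`` is ops per multiply-add."""
    out_elems = int(np.prod(spec.out_shape))
    if spec.kind == "conv2d":
        kh, kw = spec.kernel
        return out_elems * kh * kw * mac
    if spec.kind == "depthwise_conv2d":
        c = spec.in_shape[1]  # spatial kernel spans all channels
        return out_elems * c * mac
    if spec.kind == "separable_conv2d":
        kh, kw = spec.kernel
        maps_in = spec.in_shape[0]
        t = spec.out_shape[2]
        depthwise = maps_in * t * kh * kw * mac
        pointwise = out_elems * maps_in * mac
        return depthwise + pointwise
    if spec.kind == "batch_norm":
        return out_elems * mac  # one scale + one shift per element
    if spec.kind == "activation_elu":
        return out_elems
    if spec.kind == "average_pool":
        window = spec.kernel[0] * spec.kernel[1]
        return out_elems * window  # (window-1) adds + 1 divide
    if spec.kind == "dense_softmax":
        fin = spec.in_shape[0]
        n = spec.filters
        return mac * fin * n + n + 3 * n  # matmul + bias adds + softmax
    if spec.kind in ("dropout", "flatten"):
        return 0
    raise ValueError(f"unsupported layer kind for FLOP counting: {spec.kind}")


def count_params(layers: list[LayerSpec], include_nontrainable: bool = True,
                 conv_bias: bool = False) -> ComplexityReport:
    """Count parameters per layer from the symbolic trace.

    Convolutions are bias-free under the default convention (batch norm
    follows each and absorbs shifts); batch norm contributes 2 trainable
    values per feature map plus 2 stored running statistics.
    """
    report = ComplexityReport()
    for spec in layers:
        trainable, total = _layer_param_counts(spec, conv_bias)
        report.rows.append({
            "name": spec.name, "kind": spec.kind,
            "trainable_params": trainable,
            "params": total if include_nontrainable else trainable,
            "flops": 0,
        })
    return report


def count_flops(layers: list[LayerSpec], convention: str = "mac2",
                conv_bias: bool = False) -> ComplexityReport:
    """Count inference FLOPs per layer; ``mac2`` scores a multiply-add as 2
    operations (the default), ``mac1`` as 1."""
    if convention not in ("mac2", "mac1"):
        raise ValueError(f"unknown FLOPs convention {convention!r}")
    mac = 2 if convention == "mac2" else 1
    report = ComplexityReport(convention=convention)
    for spec in layers:
        trainable, total = _layer_param_counts(spec, conv_bias)
        report.rows.append({
            "name": spec.name, "kind": spec.kind,
            "trainable_params": trainable, "params": total,
            "flops": _layer_flops(spec, mac),
        })
    return report


def complexity_report(cfg: EEGNetConfig, convention: str = "mac2") -> ComplexityReport:
    """Full per-layer parameter + FLOP report for a config."""
    return count_flops(trace_shapes(cfg), convention=convention,
                       conv_bias=cfg.conv_bias)


def save_weights(weights: dict[str, np.ndarray], path) -> None:
    np.savez(path, **weights)


def load_weights(path) -> dict[str, np.ndarray]:
    with np.load(path, allow_pickle=False) as archive:
        return {k: archive[k] for k in archive.files}


__all__ = [
    "EEGNetConfig", "LayerSpec", "EEGNet", "ComplexityReport",
    "build_eegnet", "trace_shapes", "apply_max_norm",
    "count_params", "count_flops", "complexity_report",
    "save_weights", "load_weights",
]
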