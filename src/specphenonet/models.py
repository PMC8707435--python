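"""The two phenotype classifiers, built from declarative layer tables.

* A 4-channel 1D residual CNN: a kernel-32 stem convolution followed by four
  stages of residual blocks (4, 3, 3, 4 blocks with 64, 128, 256, 512
  filters; kernel 7; the first convolution of each block carries stride 2),
  giving 29 convolution layers in total, then average pooling, dropout
  (p = 0.3) and a 512 -> 4 dense softmax head.  Inputs are the four channels
  proteomic m/z, proteomic intensity, metabolomic m/z, metabolomic intensity.

* A 3D CNN over (256, 256, 98) RT x m/z image volumes: eight 3D convolutions
  with batch normalization and PReLU, three max-pool stages, adaptive average
  pooling to a 4096-wide flatten, then dense 4096 -> 64 -> 4 with softmax.
  Either omics layer's volume is a valid input.

Skip-connection projections (kernel-1 convolutions) are not counted as
convolution layers in the architecture audit, matching the usual residual
network counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import gelu  # re-exported: the activation used by the 1D model

N_CLASSES = 4


@dataclass
class ResidualBlockSpec:
    kernel: int = 7
    filters: int = 64
    stride_first: int = 2
    layers_per_block: int = 2
    activation: str = "gelu"
    normalization: str = "batch"


@dataclass
class Model1DSpec:
    """Layer table of the 1D residual CNN."""

    in_channels: int = 4
    channel_length: int = 2 ** 15
    stem_kernel: int = 32
    stem_filters: int = 64
    stem_stride: int = 2
    stage_blocks: tuple = (4, 3, 3, 4)
    stage_filters: tuple = (64, 128, 256, 512)
    block_kernel: int = 7
    block_stride: int = 2
    avgpool_kernel: int = 3
    dropout_p: float = 0.3
    n_classes: int = N_CLASSES

    @property
    def n_conv_layers(self) -> int:
        return 1 + 2 * sum(self.stage_blocks)

    @property
    def min_channel_length(self) -> int:
        # every stage's first block halves the length, as does the stem;
        # the average pool then needs at least `avgpool_kernel` samples
        factor = self.stem_stride * self.block_stride ** len(self.stage_blocks)
        return self.avgpool_kernel * factor

    @classmethod
    def reduced(cls, channel_length: int = 1024) -> "Model1DSpec":
        """Desk-scale variant: same topology, one block per stage, thin filters."""
        return cls(
            channel_length=channel_length,
            stem_filters=32,
            stage_blocks=(1, 1, 1, 1),
            stage_filters=(32, 64, 64, 128),
        )


@dataclass
class Model3DSpec:
    """Layer table of the 3D CNN.

    Max-pool strides equal their kernels (the non-overlapping reading that
    actually reduces the volume), and adaptive average pooling guarantees the
    4096-wide flatten demanded by the first dense layer.
    """

    input_shape: tuple = (256, 256, 98)      # (height, width, frames)
    conv_layers: tuple = (
        ((7, 9, 9), 16),
        ((5, 7, 7), 16),
        ((5, 7, 7), 32),
        ((2, 5, 5), 32),
        ((2, 5, 5), 64),
        ((1, 3, 3), 128),
        ((1, 3, 3), 256),
        ((1, 3, 3), 512),
    )
    pool_after: dict = field(default_factory=lambda: {0: (3, 3, 3), 1: (2, 2, 2), 2: (2, 2, 2)})
    dense_widths: tuple = (4096, 64, 4)
    adaptive_output: tuple = (2, 2, 2)

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_layers)

    @classmethod
    def reduced(cls) -> "Model3DSpec":
        """Thin variant for CPU-scale smoke training (same depth and pools)."""
        return cls(
            conv_layers=(
                ((7, 9, 9), 4), ((5, 7, 7), 4), ((5, 7, 7), 8), ((2, 5, 5), 8),
                ((2, 5, 5), 16), ((1, 3, 3), 16), ((1, 3, 3), 32), ((1, 3, 3), 64),
            ),
            dense_widths=(64 * 8, 16, 4),
        )


class SpectrumClassifier:
    """A built network: forward to class probabilities, penultimate embed."""

    def __init__(self, layers: list[nn.Layer], embed_cut: int, spec, seed: int):
        self.net = nn.Sequential(layers)
        self._embed_cut = embed_cut   # layers[:cut] produce the embedding
        self.spec = spec
        self.seed = seed

    # -- inference ----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(np.asarray(x, dtype=float), training=training)

    __call__ = forward

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Features immediately before the final dense layer (eval mode)."""
        h = np.asarray(x, dtype=float)
        for layer in self.net.layers[: self._embed_cut]:
            h = layer.forward(h, training=False)
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def parameters(self) -> list[nn.Param]:
        return self.net.parameters()

    # -- audit --------------------------------------------------------------
    def layer_table(self) -> list[dict]:
        rows = []
        for layer in nn.walk(self.net):
            row = {"type": type(layer).__name__, "role": layer.role}
            if isinstance(layer, nn.Conv1d):
                row.update(kernel=layer.kernel, filters=layer.out_channels,
                           stride=layer.stride)
            elif isinstance(layer, nn.Conv3d):
                row.update(kernel=layer.kernel, filters=layer.out_channels)
            elif isinstance(layer, nn.Linear):
                row.update(in_features=layer.in_features,
                           out_features=layer.out_features)
            elif isinstance(layer, (nn.MaxPool3d, nn.AvgPool1d)):
                row.update(kernel=getattr(layer, "kernel", None))
            rows.append(row)
        return rows

    @property
    def n_conv_layers(self) -> int:
        return sum(1 for r in self.layer_table() if r["role"] == "conv")

    @property
    def dropout_layers(self) -> list[nn.Dropout]:
        return [l for l in nn.walk(self.net) if isinstance(l, nn.Dropout)]

    def spec_json(self) -> str:
        return json.dumps({"spec": asdict(self.spec), "seed": self.seed,
                           "layers": self.layer_table()}, indent=1, default=str)


def build_1d_model(spec: Model1DSpec | None = None, seed: int = 0) -> SpectrumClassifier:
    """Construct the 4-channel 1D residual CNN from its layer table."""
    spec = spec or Model1DSpec()
    if spec.channel_length < spec.min_channel_length:
        raise ValueError(
            f"channel_length {spec.channel_length} is below the minimum "
            f"{spec.min_channel_length} required by the stride cascade"
        )
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        nn.Conv1d(spec.in_channels, spec.stem_filters, spec.stem_kernel,
                  spec.stem_stride, rng=rng),
        nn.BatchNorm(spec.stem_filters),
        nn.GELU(),
    ]
    in_ch = spec.stem_filters
    for n_blocks, filters in zip(spec.stage_blocks, spec.stage_filters):
        for b in range(n_blocks):
            stride = spec.block_stride if b == 0 else 1
            layers.append(nn.Residual1dBlock(in_ch, filters, spec.block_kernel,
                                             stride, rng=rng))
            in_ch = filters
    layers += [
        nn.AvgPool1d(spec.avgpool_kernel),
        nn.GlobalAvgPool1d(),
        nn.Dropout(spec.dropout_p, seed=int(rng.integers(2 ** 31))),
    ]
    embed_cut = len(layers)      # embedding = features entering the dense head
    head = nn.Linear(in_ch, spec.n_classes, rng=rng)
    head.W.data[...] = 0.0       # uniform class probabilities before training
    layers += [head, nn.Softmax()]
    return SpectrumClassifier(layers, embed_cut, spec, seed)


def build_3d_model(spec: Model3DSpec | None = None, seed: int = 0) -> SpectrumClassifier:
    """Construct the 3D CNN from its layer table.

    The forward pass expects volumes shaped ``(batch, height, width, frames)``
    or ``(batch, 1, depth, height, width)``; the RT/frame axis becomes the
    convolution depth axis.
    """
    spec = spec or Model3DSpec()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    for i, (kernel, filters) in enumerate(spec.conv_layers):
        layers += [
            nn.Conv3d(in_ch, filters, kernel, rng=rng),
            nn.BatchNorm(filters),
            nn.PReLU(filters),
        ]
        in_ch = filters
        if i in spec.pool_after:
            layers.append(nn.MaxPool3d(spec.pool_after[i]))
    flat = in_ch * int(np.prod(spec.adaptive_output))
    if flat != spec.dense_widths[0]:
        raise ValueError(
            f"adaptive pool produces a {flat}-wide flatten but the dense head "
            f"expects {spec.dense_widths[0]}"
        )
    layers += [
        nn.AdaptiveAvgPool3d(spec.adaptive_output),
        nn.Flatten(),
        nn.Linear(spec.dense_widths[0], spec.dense_widths[1], rng=rng),
        nn.PReLU(spec.dense_widths[1]),
    ]
    embed_cut = len(layers)
    head = nn.Linear(spec.dense_widths[1], spec.dense_widths[2], rng=rng)
    head.W.data[...] = 0.0       # uniform class probabilities before training
    layers += [head, nn.Softmax()]
    model = SpectrumClassifier(layers, embed_cut, spec, seed)
    model.as_volume_input = _as_volume_input
    return model


def _as_volume_input(v: np.ndarray) -> np.ndarray:
    """(batch, H, W, frames) volumes -> (batch, 1, frames, H, W) conv input."""
    v = np.asarray(v, dtype=float)
    if v.ndim == 3:
        v = v[None]
    if v.ndim == 4:                      # (B, H, W, F) -> (B, 1, F, H, W)
        v = v.transpose(0, 3, 1, 2)[:, None]
    return v


def embed(model: SpectrumClassifier, x: np.ndarray) -> np.ndarray:
    """Penultimate feature vector (512 for the 1D model, 64 for the 3D one)."""
    return model.embed(x)


def save_model(model: SpectrumClassifier, path) -> None:
    """Checkpoint: npz of all parameter/running arrays plus the spec + seed."""
    kind = "1d" if isinstance(model.spec, Model1DSpec) else "3d"
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    bn = [l for l in nn.walk(model.net) if isinstance(l, nn.BatchNorm)]
    for i, layer in enumerate(bn):
        arrays[f"bn_mean_{i}"] = layer.running_mean
        arrays[f"bn_var_{i}"] = layer.running_var
    meta = {"kind": kind, "seed": model.seed, "spec": asdict(model.spec)}
    np.savez(path, meta=json.dumps(meta, default=list), **arrays)


def load_model(path) -> SpectrumClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        spec_d = meta["spec"]
        for key in ("stage_blocks", "stage_filters", "dense_widths",
                    "adaptive_output", "input_shape"):
            if key in spec_d and isinstance(spec_d[key], list):
                spec_d[key] = tuple(spec_d[key])
        if meta["kind"] == "1d":
            model = build_1d_model(Model1DSpec(**spec_d), seed=meta["seed"])
        else:
            spec_d["conv_layers"] = tuple(
                (tuple(k), f) for k, f in spec_d["conv_layers"])
            spec_d["pool_after"] = {int(k): tuple(v)
                                    for k, v in spec_d["pool_after"].items()}
            model = build_3d_model(Model3DSpec(**spec_d), seed=meta["seed"])
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"param_{i}"]
        bn = [l for l in nn.walk(model.net) if isinstance(l, nn.BatchNorm)]
        for i, layer in enumerate(bn):
            layer.running_mean[...] = data[f"bn_mean_{i}"]
            layer.running_var[...] = data[f"bn_var_{i}"]
    return model
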