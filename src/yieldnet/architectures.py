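"""Declarative network architectures and exact parameter counting.

The dual-head network consumes the ``T x b x d`` histogram tensor with 2-D
convolutions over the (time, bin) plane and the ``d`` bands as input
channels. Five convolutional layers form a shared backbone feature
extractor; each crop then owns a head of two convolutional layers, FC-100,
FC-50 and a 1-unit linear output. Sharing the backbone halves the parameters
relative to two separate single-crop networks — the mechanism by which
information transfers between the crops.

Parameter counting conventions (these reproduce the published total
1,436,050 for the dual-head model exactly, and they are the only plain
convention that does):

* convolution: ``prod(filter) * C_in * C_out + C_out`` (bias kept even when
  batch norm follows);
* batch norm: 2 trainable parameters per channel (scale, shift); running
  statistics are not trainable and are not counted;
* fully connected: ``in * out + out``;
* batch norm follows every convolution of the dual-head network but none of
  its FC layers; the output layer is linear with no batch norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from . import nn

Variant = Literal["dual", "corn_only", "soy_only"]

CORN = "corn"
SOY = "soybean"


@dataclass(frozen=True)
class LayerSpec:
    kind: Literal[
        "conv2d", "conv3d", "maxpool3d", "flatten", "fully_connected", "output_linear"
    ]
    units_or_filters: int = 0
    filter_shape: tuple[int, ...] = ()
    stride: tuple[int, ...] = ()
    padding: Literal["valid", "same"] = "valid"
    batch_norm: bool = False
    activation: Literal["relu", "linear"] = "linear"


@dataclass(frozen=True)
class ArchitectureSpec:
    """A named architecture: shared backbone plus per-crop heads.

    Single-output models (the baselines and the single-head ablation
    variants) simply keep all layers in the backbone / one head.
    """

    name: str
    input_shape: tuple[int, ...]
    backbone: tuple[LayerSpec, ...]
    heads: Mapping[str, tuple[LayerSpec, ...]]


def _conv(filters, filter_shape, stride, padding, kind="conv2d") -> LayerSpec:
    return LayerSpec(
        kind=kind,
        units_or_filters=filters,
        filter_shape=filter_shape,
        stride=stride,
        padding=padding,
        batch_norm=(kind == "conv2d"),
        activation="relu",
    )


def _head_layers() -> tuple[LayerSpec, ...]:
    return (
        _conv(148, (3, 3), (1, 1), "same"),
        _conv(148, (3, 3), (1, 1), "same"),
        LayerSpec(kind="flatten"),
        LayerSpec(kind="fully_connected", units_or_filters=100, activation="relu"),
        LayerSpec(kind="fully_connected", units_or_filters=50, activation="relu"),
        LayerSpec(kind="output_linear", units_or_filters=1),
    )


def yieldnet_spec(
    input_shape: tuple[int, int, int] = (30, 32, 9), variant: Variant = "dual"
) -> ArchitectureSpec:
    """The dual-head histogram network, or a single-head ablation variant."""
    backbone = (
        _conv(48, (7, 7), (2, 2), "valid"),
        _conv(64, (5, 5), (2, 2), "valid"),
        _conv(96, (5, 5), (2, 2), "same"),
        _conv(128, (3, 3), (1, 1), "same"),
        _conv(128, (3, 3), (1, 1), "same"),
    )
    all_heads = {CORN: _head_layers(), SOY: _head_layers()}
    heads = {
        "dual": all_heads,
        "corn_only": {CORN: all_heads[CORN]},
        "soy_only": {SOY: all_heads[SOY]},
    }[variant]
    return ArchitectureSpec(
        name=f"yieldnet_{variant}", input_shape=tuple(input_shape),
        backbone=backbone, heads=heads,
    )


def dfnn_spec(input_dim: int = 30 * 32 * 9, crop: str = CORN) -> ArchitectureSpec:
    """Deep feed-forward baseline: nine batch-normalized ReLU FC-50 layers."""
    layers = [LayerSpec(kind="flatten")]
    layers += [
        LayerSpec(
            kind="fully_connected", units_or_filters=50,
            batch_norm=True, activation="relu",
        )
        for _ in range(9)
    ]
    layers.append(LayerSpec(kind="output_linear", units_or_filters=1))
    return ArchitectureSpec(
        name="dfnn", input_shape=(input_dim,),
        backbone=tuple(layers), heads={crop: ()},
    )


def cnn3d_spec(
    input_shape: tuple[int, int, int] = (30, 32, 9), crop: str = CORN
) -> ArchitectureSpec:
    """3-D convolutional baseline: kernels span time, bin and band.

    The histogram tensor is treated as a single-channel ``T x b x d`` volume.
    Homogeneous 3x3x1 convolutions with two interleaved max-pool stages,
    then FC-256, FC-128 and a linear output.
    """
    c3 = lambda f: _conv(f, (3, 3, 1), (1, 1, 1), "same", kind="conv3d")
    layers = (
        c3(64),
        LayerSpec(kind="maxpool3d", filter_shape=(4, 4, 2), stride=(4, 4, 2), padding="same"),
        c3(64), c3(64), c3(64), c3(64), c3(128),
        LayerSpec(kind="maxpool3d", filter_shape=(2, 2, 1), stride=(2, 2, 1), padding="same"),
        LayerSpec(kind="flatten"),
        LayerSpec(kind="fully_connected", units_or_filters=256, activation="relu"),
        LayerSpec(kind="fully_connected", units_or_filters=128, activation="relu"),
        LayerSpec(kind="output_linear", units_or_filters=1),
    )
    return ArchitectureSpec(
        name="cnn3d", input_shape=tuple(input_shape), backbone=layers, heads={crop: ()}
    )


# ---------------------------------------------------------------------------
# shape propagation and parameter counting (analytic; no arrays allocated)
# ---------------------------------------------------------------------------


def _propagate(shape: tuple[int, ...], spec: LayerSpec) -> tuple[tuple[int, ...], int]:
    """Return (output shape, trainable parameter count) for one layer.

    ``shape`` is ``(*spatial, channels)`` for conv stacks or ``(features,)``
    after flattening. conv3d input ``(T, b, d)`` is implicitly the volume
    with one channel.
    """
    kind = spec.kind
    if kind in ("conv2d", "conv3d"):
        ndim = 2 if kind == "conv2d" else 3
        if kind == "conv3d" and len(shape) == 3:
            shape = (*shape, 1)  # single-channel volume
        if len(shape) != ndim + 1:
            raise ValueError(f"{kind} expects {ndim + 1}-D input, got shape {shape}")
        spatial, cin = shape[:-1], shape[-1]
        out_spatial = tuple(
            nn.conv_output_size(s, f, st, spec.padding)
            for s, f, st in zip(spatial, spec.filter_shape, spec.stride)
        )
        f = spec.units_or_filters
        count = int(np.prod(spec.filter_shape)) * cin * f + f
        if spec.batch_norm:
            count += 2 * f
        return (*out_spatial, f), count
    if kind == "maxpool3d":
        if len(shape) == 3:
            shape = (*shape, 1)
        spatial, cin = shape[:-1], shape[-1]
        out_spatial = tuple(
            nn.conv_output_size(s, f, st, "same")
            for s, f, st in zip(spatial, spec.filter_shape, spec.stride)
        )
        return (*out_spatial, cin), 0
    if kind == "flatten":
        return (int(np.prod(shape)),), 0
    if kind in ("fully_connected", "output_linear"):
        if len(shape) != 1:
            shape = (int(np.prod(shape)),)
        units = spec.units_or_filters
        count = shape[0] * units + units
        if spec.batch_norm:
            count += 2 * units
        return (units,), count
    raise ValueError(f"unknown layer kind {kind!r}")


def count_parameters(spec: ArchitectureSpec) -> int:
    """Exact trainable parameter total under the documented conventions."""
    total = 0
    shape = spec.input_shape
    for layer in spec.backbone:
        shape, c = _propagate(shape, layer)
        total += c
    for head in spec.heads.values():
        hshape = shape
        for layer in head:
            hshape, c = _propagate(hshape, layer)
            total += c
    return total


def backbone_output_shape(spec: ArchitectureSpec) -> tuple[int, ...]:
    shape = spec.input_shape
    for layer in spec.backbone:
        shape, _ = _propagate(shape, layer)
    return shape


# ---------------------------------------------------------------------------
# concrete model construction
# ---------------------------------------------------------------------------


class _ExpandChannel(nn.Layer):
    """Append a unit channel axis (histogram volume -> single-channel 3-D)."""

    def forward(self, x, train):
        return x[..., None]

    def backward(self, grad):
        return grad[..., 0]


def _materialize(
    specs: tuple[LayerSpec, ...], shape: tuple[int, ...], rng: np.random.Generator
) -> tuple[list[nn.Layer], tuple[int, ...]]:
    layers: list[nn.Layer] = []
    for spec in specs:
        if spec.kind in ("conv3d", "maxpool3d") and len(shape) == 3:
            layers.append(_ExpandChannel())
            shape = (*shape, 1)
        out_shape, _ = _propagate(shape, spec)
        if spec.kind in ("conv2d", "conv3d"):
            layers.append(
                nn.Conv(
                    in_channels=shape[-1],
                    filters=spec.units_or_filters,
                    filter_shape=spec.filter_shape,
                    stride=spec.stride,
                    padding=spec.padding,
                    rng=rng,
                )
            )
            if spec.batch_norm:
                layers.append(nn.BatchNorm(spec.units_or_filters))
            if spec.activation == "relu":
                layers.append(nn.ReLU())
        elif spec.kind == "maxpool3d":
            layers.append(nn.MaxPool(spec.filter_shape))
        elif spec.kind == "flatten":
            layers.append(nn.Flatten())
        elif spec.kind in ("fully_connected", "output_linear"):
            in_features = shape[0] if len(shape) == 1 else int(np.prod(shape))
            if len(shape) != 1:
                layers.append(nn.Flatten())
            layers.append(nn.Dense(in_features, spec.units_or_filters, rng))
            if spec.batch_norm:
                layers.append(nn.BatchNorm(spec.units_or_filters))
            if spec.activation == "relu":
                layers.append(nn.ReLU())
        shape = out_shape
    return layers, shape


@dataclass
class ModelHandle:
    """A constructed network: shared backbone plus per-crop head networks."""

    spec: ArchitectureSpec
    backbone: nn.Sequential
    heads: dict[str, nn.Sequential]
    seed: int

    @property
    def crops(self) -> tuple[str, ...]:
        return tuple(self.heads)

    def params(self) -> list[nn.Parameter]:
        out = self.backbone.params()
        for head in self.heads.values():
            out += head.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward_full(self, batch: np.ndarray, train: bool = False) -> dict[str, np.ndarray]:
        feats = self.backbone.forward(batch, train)
        return {
            crop: head.forward(feats, train)[:, 0] for crop, head in self.heads.items()
        }

    def backward(self, head_grads: dict[str, np.ndarray]) -> None:
        total = None
        for crop, head in self.heads.items():
            g = head.backward(head_grads[crop][:, None])
            total = g if total is None else total + g
        self.backbone.backward(total)


def build_from_spec(spec: ArchitectureSpec, seed: int) -> ModelHandle:
    rng = np.random.default_rng(seed)
    backbone_layers, shape = _materialize(spec.backbone, spec.input_shape, rng)
    heads = {}
    for crop, head_spec in spec.heads.items():
        head_layers, out_shape = _materialize(head_spec, shape, rng)
        final = out_shape[0] if len(out_shape) == 1 else int(np.prod(out_shape))
        if final != 1:
            raise ValueError(f"head {crop!r} does not end in a single output")
        heads[crop] = nn.Sequential(head_layers)
    return ModelHandle(
        spec=spec, backbone=nn.Sequential(backbone_layers), heads=heads, seed=seed
    )


def build_yieldnet(
    input_shape: tuple[int, int, int] = (30, 32, 9),
    variant: Variant = "dual",
    seed: int = 0,
) -> ModelHandle:
    """Construct the dual-head network (or an ablation variant), Xavier-seeded.

    The two strided valid-padded backbone convolutions require the time and
    bin extents to survive: the first conv needs >= 7, and its output must
    reach the 5x5 second conv, so ``T >= 15`` and ``b >= 15``.
    """
    T, b, _ = input_shape
    for name, size in (("T", T), ("b", b)):
        after1 = (size - 7) // 2 + 1 if size >= 7 else 0
        if after1 < 5:
            raise ValueError(
                f"input {name}={size} too small: first valid conv gives {after1} < 5"
            )
    return build_from_spec(yieldnet_spec(input_shape, variant), seed)


def build_dfnn(input_dim: int = 30 * 32 * 9, seed: int = 0, crop: str = CORN) -> ModelHandle:
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    return build_from_spec(dfnn_spec(input_dim, crop), seed)


def build_3dcnn(
    input_shape: tuple[int, int, int] = (30, 32, 9), seed: int = 0, crop: str = CORN
) -> ModelHandle:
    return build_from_spec(cnn3d_spec(input_shape, crop), seed)


def _batchnorms(model: ModelHandle) -> list[nn.BatchNorm]:
    layers = list(model.backbone.layers)
    for head in model.heads.values():
        layers.extend(head.layers)
    return [l for l in layers if isinstance(l, nn.BatchNorm)]


def save_model(model: ModelHandle, path) -> None:
    """Serialize weights, batch-norm buffers and enough metadata to rebuild."""
    import json

    meta = {
        "name": model.spec.name,
        "input_shape": list(model.spec.input_shape),
        "seed": model.seed,
        "crops": list(model.heads),
    }
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    for i, bn in enumerate(_batchnorms(model)):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> ModelHandle:
    import json

    with np.load(path) as archive:
        meta = json.loads(archive["meta"].tobytes().decode())
        shape = tuple(meta["input_shape"])
        name = meta["name"]
        if name.startswith("yieldnet_"):
            model = build_yieldnet(shape, name.removeprefix("yieldnet_"), meta["seed"])
        elif name == "dfnn":
            model = build_dfnn(shape[0], meta["seed"], crop=meta["crops"][0])
        elif name == "cnn3d":
            model = build_3dcnn(shape, meta["seed"], crop=meta["crops"][0])
        else:
            raise ValueError(f"unknown model name {name!r}")
        for i, p in enumerate(model.params()):
            p.value[...] = archive[f"p{i}"]
        for i, bn in enumerate(_batchnorms(model)):
            bn.running_mean = archive[f"bn{i}_mean"].copy()
            bn.running_var = archive[f"bn{i}_var"].copy()
    return model


def forward(model: ModelHandle, batch: np.ndarray) -> dict[str, np.ndarray]:
    """Inference-mode forward pass: one predicted yield per head per sample."""
    batch = np.asarray(batch, dtype=np.float32)
    expected = model.spec.input_shape
    if batch.ndim == len(expected):
        batch = batch[None]
    if tuple(batch.shape[1:]) != tuple(expected) and not (
        len(expected) == 1 and int(np.prod(batch.shape[1:])) == expected[0]
    ):
        raise ValueError(
            f"batch shape {batch.shape[1:]} does not match input {expected}"
        )
    return model.forward_full(batch, train=False)
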