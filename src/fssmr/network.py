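"""Convolutional building blocks and the single-/multi-stream architectures.

Every layer implements an explicit ``forward`` and ``backward`` (reverse-mode
differentiation of the documented forward op), so the whole network trains
with plain numpy.  Convolutions are stride-1 cross-correlations with 'same'
padding realized through im2col; the multi-stream model downsamples with
2x2 max-pooling under floor division, which reproduces the odd stage sizes
46 -> 23 -> 11 -> 5 exactly.

Tensor layout is NCHW (batch, channels, rows, cols) throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkSpec",
    "Conv2D",
    "Dense",
    "relu",
    "maxpool",
    "affine_forward",
    "SingleStreamCNN",
    "MultiStreamCNN",
    "build_single_stream",
    "build_multi_stream",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# architecture description
# ---------------------------------------------------------------------------

# documented default stage widths of the multi-stream model; the 138-channel
# stage is unconventional but kept verbatim
DEFAULT_MULTI_CHANNELS = (256, 138, 128, 64)
DEFAULT_SINGLE_CHANNELS = (16, 32, 64, 128)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description for both model families.

    ``stream_channels`` holds one channel sequence per stream; a
    single-stream spec has exactly one.  ``stream_dilations`` gives the
    convolution dilation of each stream (the second default stream uses
    dilated convolutions to widen its receptive field, the multi-scale
    pathway of the dual-path design).
    """

    image_size: int = 46
    in_channels: int = 1
    stream_channels: tuple[tuple[int, ...], ...] = (DEFAULT_SINGLE_CHANNELS,)
    stream_dilations: tuple[int, ...] = (1,)
    n_classes: int = 4
    seg_classes: int = 2
    dropout_rate: float = 0.25
    allow_nonstandard: bool = False

    def __post_init__(self) -> None:
        if len(self.stream_channels) != len(self.stream_dilations):
            raise ValueError("one dilation per stream is required")


def multi_stream_spec(
    channels: tuple[int, ...] = DEFAULT_MULTI_CHANNELS,
    image_size: int = 46,
    dropout_rate: float = 0.25,
) -> NetworkSpec:
    """Two-pathway spec: plain convs and dilation-2 convs, shared widths."""
    return NetworkSpec(
        image_size=image_size,
        stream_channels=(tuple(channels), tuple(channels)),
        stream_dilations=(1, 2),
        dropout_rate=dropout_rate,
    )


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2D:
    """3x3 (by default) stride-1 'same' cross-correlation with bias.

    Holds the layer state: weights ``W`` (cout, cin, k, k), bias ``b``,
    pruning ``mask`` (True = active), and after a forward pass the
    pre-activation ``z``.  Dilation `d` enlarges the effective kernel to
    (k-1)*d + 1 while keeping the parameter count.
    """

    prunable = True

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        # He initialization keeps activation scale through ReLU stacks
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.standard_normal((cout, cin, k, k)) * std
        self.b = np.zeros(cout)
        self.mask = np.ones_like(self.W, dtype=bool)
        self.k, self.dilation, self.name = k, dilation, name
        self.z: np.ndarray | None = None
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cout, cin, k, _ = self.W.shape
        if x.ndim != 4 or x.shape[1] != cin:
            raise ValueError(
                f"input shape {x.shape} incompatible with layer fan-in "
                f"{(cin, k, k)} of {self.name!r}"
            )
        d = self.dilation
        ke = (k - 1) * d + 1
        pad = (ke - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        n, _, h, w = x.shape
        ho, wo = h, w  # stride 1, same padding
        # im2col by k*k contiguous slice copies (cache-friendly)
        cols = np.empty((n, cin, k, k, ho, wo))
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i * d:i * d + ho, j * d:j * d + wo]
        self._cols, self._xshape = cols, x.shape
        z = np.tensordot(self.W, cols, axes=([1, 2, 3], [1, 2, 3]))
        self.z = z.transpose(1, 0, 2, 3) + self.b[None, :, None, None]
        return self.z

    def backward(self, dz: np.ndarray) -> np.ndarray:
        cout, cin, k, _ = self.W.shape
        n, _, ho, wo = dz.shape
        self.dW = np.tensordot(dz, self._cols, axes=([0, 2, 3], [0, 4, 5]))
        self.db = dz.sum(axis=(0, 2, 3))
        # dcols[n, cin, i, j, ho, wo] = sum_cout W[cout, cin, i, j] dz[n, cout, ho, wo]
        dcols = np.tensordot(dz, self.W, axes=([1], [0]))  # (n, ho, wo, cin, k, k)
        d = self.dilation
        ke = (k - 1) * d + 1
        pad = (ke - 1) // 2
        _, _, h, w = self._xshape
        dxp = np.zeros((n, cin, h + 2 * pad, w + 2 * pad))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i * d:i * d + ho, j * d:j * d + wo] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        return dxp[:, :, pad:h + pad, pad:w + pad] if pad else dxp


class Dense:
    """Fully connected layer on flattened inputs."""

    prunable = True

    def __init__(self, fan_in: int, fan_out: int,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        self.W = rng.standard_normal((fan_out, fan_in)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(fan_out)
        self.mask = np.ones_like(self.W, dtype=bool)
        self.name = name
        self.z: np.ndarray | None = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = x.reshape(x.shape[0], -1)
        if x.shape[1] != self.W.shape[1]:
            raise ValueError(
                f"input shape {x.shape} incompatible with layer fan-in "
                f"{self.W.shape[1]} of {self.name!r}"
            )
        self._x = x
        self.z = x @ self.W.T + self.b
        return self.z

    def backward(self, dz: np.ndarray) -> np.ndarray:
        self.dW = dz.T @ self._x
        self.db = dz.sum(axis=0)
        return dz @ self.W


class ReLULayer:
    prunable = False

    def forward(self, x, train=False):
        self._m = x > 0
        return x * self._m

    def backward(self, d):
        return d * self._m


class MaxPool2:
    """2x2, stride-2 max pooling with floor division on odd sizes."""

    prunable = False

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h < 2 or w < 2:
            raise ValueError(f"pool window 2 larger than input plane {(h, w)}")
        ho, wo = h // 2, w // 2
        xc = x[:, :, :2 * ho, :2 * wo]
        win = xc.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, ho, wo, 4)
        self._idx = win.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, d):
        n, c, h, w = self._inshape
        ho, wo = h // 2, w // 2
        dwin = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dwin, self._idx[..., None], d[..., None], axis=-1)
        dx = np.zeros((n, c, h, w))
        dx[:, :, :2 * ho, :2 * wo] = (
            dwin.reshape(n, c, ho, wo, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * ho, 2 * wo)
        )
        return dx


class Dropout:
    """Inverted dropout; identity at evaluation time."""

    prunable = False

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._m = None
            return x
        keep = 1.0 - self.rate
        self._m = (self.rng.random(x.shape) < keep) / keep
        return x * self._m

    def backward(self, d):
        return d if self._m is None else d * self._m


class NearestUpsample:
    """Resize to a fixed target plane by nearest-neighbor index mapping."""

    prunable = False

    def __init__(self, target: int):
        self.target = target

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        t = self.target
        self._ri = (np.arange(t) * h) // t
        self._ci = (np.arange(t) * w) // t
        self._inshape = x.shape
        return x[:, :, self._ri[:, None], self._ci[None, :]]

    def backward(self, d):
        dx = np.zeros(self._inshape)
        np.add.at(dx, (slice(None), slice(None), self._ri[:, None], self._ci[None, :]), d)
        return dx


# ---------------------------------------------------------------------------
# primitive ops exposed for direct use / oracles
# ---------------------------------------------------------------------------


def relu(z: np.ndarray) -> np.ndarray:
    """Elementwise max(0, z)."""
    return np.maximum(0.0, z)


def maxpool(a: np.ndarray, window: int = 2) -> np.ndarray:
    """Non-overlapping max pooling with floor division on the spatial dims.

    Accepts (H, W) or (N, C, H, W).
    """
    squeeze = a.ndim == 2
    if squeeze:
        a = a[None, None]
    n, c, h, w = a.shape
    if h < window or w < window:
        raise ValueError(f"pool window {window} larger than input plane {(h, w)}")
    ho, wo = h // window, w // window
    xc = a[:, :, :window * ho, :window * wo]
    out = xc.reshape(n, c, ho, window, wo, window).max(axis=(3, 5))
    return out[0, 0] if squeeze else out


def affine_forward(x: np.ndarray, layer) -> np.ndarray:
    """Pre-activation z = W . a_(l-1) + b of a conv or dense layer."""
    return layer.forward(x, train=False)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class _Model:
    """Shared plumbing: named layer traversal, prunable-weight access."""

    spec: NetworkSpec

    def named_layers(self):
        raise NotImplementedError

    def prunable_layers(self, include_heads: bool = False):
        for name, layer in self.named_layers():
            if not layer.prunable:
                continue
            if not include_heads and name.startswith("head"):
                continue
            yield name, layer

    def parameter_arrays(self):
        """(name, layer, param_key, array) for every trainable array."""
        for name, layer in self.named_layers():
            if layer.prunable:
                yield name, layer, "W", layer.W
                yield name, layer, "b", layer.b

    def n_parameters(self) -> int:
        return sum(a.size for *_, a in self.parameter_arrays())

    def n_nonzero(self) -> int:
        return sum(
            int(np.count_nonzero(a)) for *_, a in self.parameter_arrays()
        )

    def predict(self, x: np.ndarray):
        """Class and per-pixel probabilities, dropout off."""
        class_logits, seg_logits = self.forward(x, train=False)
        return _softmax(class_logits, axis=1), _softmax(seg_logits, axis=1)


class SingleStreamCNN(_Model):
    """Four stride-1 'same' 3x3 conv+ReLU layers plus two heads.

    With stride-1 same-padding convolutions only, the spatial plane is
    preserved end to end, so the segmentation head needs no upsampling.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        if len(spec.stream_channels) != 1:
            raise ValueError("single-stream spec must have exactly one stream")
        channels = spec.stream_channels[0]
        if len(channels) != 4 and not spec.allow_nonstandard:
            raise ValueError(
                f"single-stream default is exactly four conv layers, got "
                f"{len(channels)}; set allow_nonstandard to override"
            )
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.convs, self.relus = [], []
        cin = spec.in_channels
        for i, cout in enumerate(channels):
            self.convs.append(Conv2D(cin, cout, rng=rng, name=f"conv{i + 1}"))
            self.relus.append(ReLULayer())
            cin = cout
        self.head_seg = Conv2D(cin, spec.seg_classes, rng=rng, name="head_seg")
        self.head_cls = Dense(cin * spec.image_size**2, spec.n_classes,
                              rng=rng, name="head_cls")

    def named_layers(self):
        for conv in self.convs:
            yield conv.name, conv
        yield "head_seg", self.head_seg
        yield "head_cls", self.head_cls

    def forward(self, x, train=False):
        for conv, act in zip(self.convs, self.relus):
            x = act.forward(conv.forward(x, train), train)
        self._feat = x
        return self.head_cls.forward(x, train), self.head_seg.forward(x, train)

    def backward(self, d_class, d_seg):
        dx = self.head_cls.backward(d_class).reshape(self._feat.shape)
        dx = dx + self.head_seg.backward(d_seg)
        for conv, act in zip(reversed(self.convs), reversed(self.relus)):
            dx = conv.backward(act.backward(dx))
        return dx


class _Stream:
    """One pathway: [conv+relu, pool+dropout] x3, conv+relu."""

    def __init__(self, channels, dilation, in_channels, dropout_rate, rng, tag):
        self.layers = []
        cin = in_channels
        for i, cout in enumerate(channels):
            self.layers.append(
                Conv2D(cin, cout, dilation=dilation, rng=rng,
                       name=f"{tag}_conv{i + 1}")
            )
            self.layers.append(ReLULayer())
            if i < len(channels) - 1:
                self.layers.append(MaxPool2())
                self.layers.append(Dropout(dropout_rate, rng))
            cin = cout

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, d):
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class MultiStreamCNN(_Model):
    """Dual-pathway network with fused features and two output heads.

    Each stream follows the stage shapes (S, S, c1) -> (S/2, S/2, c2) ->
    (S/4, S/4, c3) -> (S/8, S/8, c4) under floor division (46 -> 23 -> 11
    -> 5 at the default size).  Stream outputs are concatenated along the
    channel axis; the classification head is a dense layer over the
    flattened fusion, the segmentation head upsamples back to the input
    plane (nearest-neighbor) followed by one 3x3 conv.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        if len(spec.stream_channels) < 2:
            raise ValueError("multi-stream model needs at least two streams")
        n_stages = len(spec.stream_channels[0])
        final = spec.image_size
        for _ in range(n_stages - 1):
            final //= 2
        if final < 1:
            raise ValueError(
                f"image size {spec.image_size} cannot sustain {n_stages - 1} "
                "floor-division poolings"
            )
        self.spec = spec
        self.final_plane = final
        rng = np.random.default_rng(seed)
        self.streams = [
            _Stream(ch, dil, spec.in_channels, spec.dropout_rate, rng, f"s{i}")
            for i, (ch, dil) in enumerate(
                zip(spec.stream_channels, spec.stream_dilations)
            )
        ]
        fused_c = sum(ch[-1] for ch in spec.stream_channels)
        self.head_cls = Dense(fused_c * final * final, spec.n_classes,
                              rng=rng, name="head_cls")
        self.up = NearestUpsample(spec.image_size)
        self.head_seg = Conv2D(fused_c, spec.seg_classes, rng=rng,
                               name="head_seg")

    def named_layers(self):
        for s in self.streams:
            for layer in s.layers:
                if layer.prunable:
                    yield layer.name, layer
        yield "head_seg", self.head_seg
        yield "head_cls", self.head_cls

    def stage_shapes(self, stream: int = 0):
        """(rows, cols, channels) after every stage of one stream."""
        shapes = []
        size = self.spec.image_size
        for i, c in enumerate(self.spec.stream_channels[stream]):
            if i > 0:
                size //= 2
            shapes.append((size, size, c))
        return shapes

    def forward(self, x, train=False):
        feats = [s.forward(x, train) for s in self.streams]
        self._split = np.cumsum([f.shape[1] for f in feats])[:-1]
        fused = np.concatenate(feats, axis=1)
        self._fused_shape = fused.shape
        class_logits = self.head_cls.forward(fused, train)
        seg_logits = self.head_seg.forward(self.up.forward(fused, train), train)
        return class_logits, seg_logits

    def backward(self, d_class, d_seg):
        dfused = self.head_cls.backward(d_class).reshape(self._fused_shape)
        dfused = dfused + self.up.backward(self.head_seg.backward(d_seg))
        parts = np.split(dfused, self._split, axis=1)
        for s, dp in zip(self.streams, parts):
            s.backward(dp)


def build_single_stream(spec: NetworkSpec | None = None, seed: int = 0) -> SingleStreamCNN:
    return SingleStreamCNN(spec or NetworkSpec(), seed=seed)


def build_multi_stream(spec: NetworkSpec | None = None, seed: int = 0) -> MultiStreamCNN:
    return MultiStreamCNN(spec or multi_stream_spec(), seed=seed)


# ---------------------------------------------------------------------------
# persistence: single-file array archive + JSON sidecar with the spec
# ---------------------------------------------------------------------------


def save_model(model: _Model, path: str | Path) -> None:
    path = Path(path)
    arrays = {}
    for name, layer, key, arr in model.parameter_arrays():
        arrays[f"{name}.{key}"] = arr
        if key == "W":
            arrays[f"{name}.mask"] = layer.mask
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "kind": type(model).__name__,
        "spec": {
            "image_size": model.spec.image_size,
            "in_channels": model.spec.in_channels,
            "stream_channels": [list(c) for c in model.spec.stream_channels],
            "stream_dilations": list(model.spec.stream_dilations),
            "n_classes": model.spec.n_classes,
            "seg_classes": model.spec.seg_classes,
            "dropout_rate": model.spec.dropout_rate,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> _Model:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    s = meta["spec"]
    spec = NetworkSpec(
        image_size=s["image_size"],
        in_channels=s["in_channels"],
        stream_channels=tuple(tuple(c) for c in s["stream_channels"]),
        stream_dilations=tuple(s["stream_dilations"]),
        n_classes=s["n_classes"],
        seg_classes=s["seg_classes"],
        dropout_rate=s["dropout_rate"],
        allow_nonstandard=True,
    )
    model = (
        SingleStreamCNN(spec) if meta["kind"] == "SingleStreamCNN"
        else MultiStreamCNN(spec)
    )
    with np.load(path.with_suffix(".npz")) as data:
        for name, layer in model.named_layers():
            layer.W[...] = data[f"{name}.W"]
            layer.b[...] = data[f"{name}.b"]
            layer.mask[...] = data[f"{name}.mask"]
    return model
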