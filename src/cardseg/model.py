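"""Residual encoder-decoder segmentation network and the plain U-Net baseline.

The proposed architecture is a U-shaped network whose convolutional unit is
a residual block: two 3x3 convolutions and a 1x1 shortcut convolution, each
followed by batch normalization, with ReLU after the first convolution and
after the shortcut addition::

    out = ReLU( BN(conv3(ReLU(BN(conv3(x))))) + BN(conv1(x)) )

The encoder alternates residual blocks with 2x2 max pooling over four
levels, channel widths growing 24 -> 48 -> 96 -> 192; the bottleneck is a
residual block at width 384 followed by dropout (rate 0.5); the decoder
mirrors the encoder with 2x2 stride-2 transposed convolutions, skip
concatenation, and residual blocks; a 1x1 convolution maps the final 24
channels to 4 class scores, and a per-pixel SoftMax yields probabilities.
With this wiring the default network has ~4.6 million trainable scalars.

The baseline swaps the residual block for the classic plain
double-convolution block (conv-BN-ReLU twice, no shortcut); with 64 initial
filters it weighs in around 31 million parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataio import GrayImage, LabelMap
from .errors import ConfigurationError, ContractError
from .nn import (
    F32,
    Adam,  # noqa: F401  (re-exported for training)
    BatchNorm2d,
    Conv2d,
    ConvTranspose2x2,
    Dropout,
    Layer,
    MaxPool2x2,
    Parameter,
    ReLU,
    softmax,
    softmax_backward,
)


@dataclass
class NetSpec:
    """Declarative description of a segmentation network."""

    rows: int = 160
    cols: int = 128
    in_channels: int = 1
    n_classes: int = 4
    base_width: int = 24
    levels: int = 4
    growth: int = 2
    dropout: float = 0.5
    batch_norm: bool = True
    block: str = "residual"  # "residual" | "double"

    def __post_init__(self) -> None:
        if self.base_width < 1 or self.n_classes < 2 or self.levels < 1:
            raise ConfigurationError("base_width >= 1, n_classes >= 2, levels >= 1 required")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must lie in [0, 1)")
        div = 2**self.levels
        if self.rows % div or self.cols % div:
            raise ConfigurationError(
                f"input {self.rows}x{self.cols} not divisible by 2^{self.levels}"
            )
        if self.block not in ("residual", "double"):
            raise ConfigurationError(f"unknown block type {self.block!r}")

    def width(self, level: int) -> int:
        return self.base_width * self.growth**level


class ResidualBlock(Layer):
    """Two 3x3 convolutions plus a 1x1 shortcut, BN after every convolution,
    ReLU after the first convolution and after the addition.  Spatial size
    is preserved; the shortcut always uses a 1x1 convolution, even when the
    channel counts match."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, bn: bool = True, name: str = ""):
        bias = not bn
        self.conv1 = Conv2d(c_in, c_out, 3, rng, bias=bias, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(c_out, name=f"{name}.bn1") if bn else None
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng, bias=bias, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(c_out, name=f"{name}.bn2") if bn else None
        self.conv_sc = Conv2d(c_in, c_out, 1, rng, bias=bias, name=f"{name}.conv_sc")
        self.bn_sc = BatchNorm2d(c_out, name=f"{name}.bn_sc") if bn else None
        self.relu_out = ReLU()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for lyr in (self.conv1, self.bn1, self.conv2, self.bn2, self.conv_sc, self.bn_sc):
            if lyr is not None:
                params += lyr.parameters()
        return params

    def _bn(self, bn, x, train):
        return x if bn is None else bn.forward(x, train)

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        a = self.relu1.forward(self._bn(self.bn1, self.conv1.forward(x, train), train))
        b = self._bn(self.bn2, self.conv2.forward(a, train), train)
        s = self._bn(self.bn_sc, self.conv_sc.forward(x, train), train)
        return self.relu_out.forward(b + s)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        ds = d if self.bn_sc is None else self.bn_sc.backward(d)
        dx_sc = self.conv_sc.backward(ds)
        db = d if self.bn2 is None else self.bn2.backward(d)
        da = self.relu1.backward(self.conv2.backward(db))
        da = da if self.bn1 is None else self.bn1.backward(da)
        return self.conv1.backward(da) + dx_sc

    def bn_layers(self):
        return [b for b in (self.bn1, self.bn2, self.bn_sc) if b is not None]


class DoubleConvBlock(Layer):
    """The plain U-Net unit: (conv3x3 -> BN -> ReLU) twice, no shortcut."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, bn: bool = True, name: str = ""):
        bias = not bn
        self.conv1 = Conv2d(c_in, c_out, 3, rng, bias=bias, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(c_out, name=f"{name}.bn1") if bn else None
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng, bias=bias, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(c_out, name=f"{name}.bn2") if bn else None
        self.relu2 = ReLU()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for lyr in (self.conv1, self.bn1, self.conv2, self.bn2):
            if lyr is not None:
                params += lyr.parameters()
        return params

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        a = self.conv1.forward(x, train)
        a = a if self.bn1 is None else self.bn1.forward(a, train)
        a = self.relu1.forward(a)
        b = self.conv2.forward(a, train)
        b = b if self.bn2 is None else self.bn2.forward(b, train)
        return self.relu2.forward(b)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dy)
        d = d if self.bn2 is None else self.bn2.backward(d)
        d = self.relu1.backward(self.conv2.backward(d))
        d = d if self.bn1 is None else self.bn1.backward(d)
        return self.conv1.backward(d)

    def bn_layers(self):
        return [b for b in (self.bn1, self.bn2) if b is not None]


def _make_block(kind: str, c_in: int, c_out: int, rng, bn: bool, name: str):
    cls = ResidualBlock if kind == "residual" else DoubleConvBlock
    return cls(c_in, c_out, rng, bn=bn, name=name)


class Network:
    """A realized encoder-decoder segmenter.

    ``forward`` maps an (N, rows, cols, 1) unit-float batch to per-pixel
    class probabilities (N, rows, cols, K) that sum to 1 at every pixel;
    ``backward`` accepts dLoss/dprobabilities and accumulates parameter
    gradients.
    """

    def __init__(self, spec: NetSpec, rng: np.random.Generator):
        self.spec = spec
        kind, bn = spec.block, spec.batch_norm
        self.enc_blocks: list[Layer] = []
        self.pools: list[MaxPool2x2] = []
        c_prev = spec.in_channels
        for lv in range(spec.levels):
            c = spec.width(lv)
            self.enc_blocks.append(_make_block(kind, c_prev, c, rng, bn, f"enc{lv}"))
            self.pools.append(MaxPool2x2())
            c_prev = c
        c_bottom = spec.width(spec.levels)
        self.bottleneck = _make_block(kind, c_prev, c_bottom, rng, bn, "bottleneck")
        self.drop = Dropout(spec.dropout)
        self.upconvs: list[ConvTranspose2x2] = []
        self.dec_blocks: list[Layer] = []
        c_prev = c_bottom
        for lv in reversed(range(spec.levels)):
            c = spec.width(lv)
            self.upconvs.append(ConvTranspose2x2(c_prev, c, rng, name=f"up{lv}"))
            self.dec_blocks.append(_make_block(kind, 2 * c, c, rng, bn, f"dec{lv}"))
            c_prev = c
        self.head = Conv2d(spec.base_width, spec.n_classes, 1, rng, bias=True, name="head")

    # -- plumbing ---------------------------------------------------------

    def blocks(self) -> list[Layer]:
        return self.enc_blocks + [self.bottleneck] + self.dec_blocks

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for blk in self.enc_blocks:
            params += blk.parameters()
        params += self.bottleneck.parameters()
        for up, blk in zip(self.upconvs, self.dec_blocks):
            params += up.parameters()
            params += blk.parameters()
        params += self.head.parameters()
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All mutable state: parameters plus BN running statistics."""
        state = {f"p{i:04d}": p.value for i, p in enumerate(self.parameters())}
        bns = [b for blk in self.blocks() for b in blk.bn_layers()]
        for i, b in enumerate(bns):
            state[f"rm{i:04d}"] = b.running_mean
            state[f"rv{i:04d}"] = b.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            src = state[f"p{i:04d}"]
            if src.shape != p.value.shape:
                raise ContractError(f"checkpoint shape mismatch at parameter {i}")
            p.value = np.ascontiguousarray(src, dtype=F32)
        bns = [b for blk in self.blocks() for b in blk.bn_layers()]
        for i, b in enumerate(bns):
            b.running_mean = np.asarray(state[f"rm{i:04d}"], dtype=F32)
            b.running_var = np.asarray(state[f"rv{i:04d}"], dtype=F32)

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        if x.ndim != 4 or x.shape[1:] != (self.spec.rows, self.spec.cols, self.spec.in_channels):
            raise ContractError(
                f"expected input (N, {self.spec.rows}, {self.spec.cols}, "
                f"{self.spec.in_channels}), got {x.shape}"
            )
        x = np.ascontiguousarray(x, dtype=F32)
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x, train)
        x = self.drop.forward(x, train, rng)
        self._skip_channels = []
        for up, blk, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            u = up.forward(x, train)
            self._skip_channels.append(skip.shape[-1])
            x = blk.forward(np.concatenate([skip, u], axis=-1), train)
        logits = self.head.forward(x, train)
        self._probs = softmax(logits, axis=-1)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        d = softmax_backward(self._probs, dprobs, axis=-1)
        d = self.head.backward(d)
        dskips = []
        for up, blk in zip(reversed(self.upconvs), reversed(self.dec_blocks)):
            dcat = blk.backward(d)
            csk = self._skip_channels[len(self.upconvs) - 1 - len(dskips)]
            dskips.append(dcat[..., :csk])
            d = up.backward(np.ascontiguousarray(dcat[..., csk:]))
        # dskips[lv] is now the gradient flowing into encoder level lv's skip
        d = self.drop.backward(d)
        d = self.bottleneck.backward(d)
        for lv in reversed(range(self.spec.levels)):
            d = self.pools[lv].backward(d) + dskips[lv]
            d = self.enc_blocks[lv].backward(d)


def build_residual_block(
    in_channels: int, out_channels: int, seed: int = 0, bn: bool = True
) -> ResidualBlock:
    """Standalone residual block constructor (He-initialized)."""
    if in_channels < 1 or out_channels < 1:
        raise ConfigurationError("channel counts must be >= 1")
    return ResidualBlock(in_channels, out_channels, np.random.default_rng(seed), bn=bn)


def build_network(spec: NetSpec | None = None, seed: int = 0) -> Network:
    """Build a He-initialized network from its spec (default: the proposed
    residual architecture at 160 x 128)."""
    spec = spec or NetSpec()
    return Network(spec, np.random.default_rng(seed))


def build_unet_baseline(
    initial_filters: int = 64,
    n_classes: int = 4,
    bn: bool = True,
    rows: int = 160,
    cols: int = 128,
    seed: int = 0,
) -> Network:
    """The plain U-Net comparison arm: 4 levels of double-convolution blocks
    with widths doubling from ``initial_filters``, same pooling/up-sampling,
    head and SoftMax as the proposed network."""
    if initial_filters < 1:
        raise ConfigurationError("initial_filters must be >= 1")
    spec = NetSpec(
        rows=rows,
        cols=cols,
        n_classes=n_classes,
        base_width=initial_filters,
        levels=4,
        growth=2,
        batch_norm=bn,
        block="double",
    )
    return Network(spec, np.random.default_rng(seed))


def count_parameters(net: Network) -> int:
    """Exact number of trainable scalars (conv kernels, biases, BN affine)."""
    return int(sum(p.size for p in net.parameters()))


def predict(net: Network, image: GrayImage) -> LabelMap:
    """Segment one preprocessed unit-float image: per-pixel argmax over the
    class probabilities, ties broken toward the lower label value."""
    if image.bit_depth != "float":
        raise ContractError("predict expects a unit-float preprocessed image")
    if image.shape != (net.spec.rows, net.spec.cols):
        raise ContractError(f"expected {net.spec.rows}x{net.spec.cols}, got {image.shape}")
    x = image.pixels.astype(F32)[None, :, :, None]
    probs = net.forward(x, train=False)
    return LabelMap(probs_to_labels(probs)[0])


def probs_to_labels(probs: np.ndarray) -> np.ndarray:
    """(N, H, W, K) probabilities -> (N, H, W) labels in {1..K}; argmax takes
    the first (lowest) class on ties."""
    return probs.argmax(axis=-1).astype(np.int64) + 1


# ---------------------------------------------------------------------------
# checkpoints

CHECKPOINT_VERSION = 1


def save_checkpoint(net: Network, path: str | Path, extra: dict | None = None) -> None:
    """Serialize spec + weights + BN statistics to an .npz container."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "spec": dataclasses.asdict(net.spec),
        "extra": extra or {},
    }
    np.savez(Path(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **net.state_arrays())


def load_checkpoint(path: str | Path) -> tuple[Network, dict]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ContractError(f"unsupported checkpoint version {meta.get('version')}")
        net = build_network(NetSpec(**meta["spec"]))
        net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return net, meta.get("extra", {})
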