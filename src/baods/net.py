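"""BAODS-Net: the gantry-angle ranking network and its losses.

The network maps the assembled geometric feature array (one channel,
40,500 x 4,000 by default) to the 360-element ranking score vector. Its
feature extractor opens with two 'integration' convolutions — a 9x1
kernel at stride 9 that merges the nine features of one ray, then a
25x1 kernel at stride 25 that merges the 25 rays of one angle — and
continues with six 3x3 stride-1 convolutions interleaved with 2x2 max
pooling. The flattened output (1,220 values at default size) feeds a
four-layer fully connected predictor ending in 360 outputs. Every
convolution and fully connected layer except the last is followed by
batch normalization and a leaky ReLU.

Loss functions: L1, L2, and smooth-L1 with threshold beta (default
0.5), each averaged over all elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .targets import SBeam

DEFAULT_INPUT_SHAPE = (1, 40500, 4000)  # (channels, rows, bins)
LEAKY_SLOPE = 0.01


# --- layer descriptors ------------------------------------------------------

@dataclass(frozen=True)
class ConvSpec:
    out_ch: int
    in_ch: int
    kh: int
    kw: int
    sh: int = 1
    sw: int = 1
    ph: int = 0
    pw: int = 0


@dataclass(frozen=True)
class BatchNorm2dSpec:
    features: int


@dataclass(frozen=True)
class BatchNorm1dSpec:
    features: int


@dataclass(frozen=True)
class ActSpec:
    slope: float = LEAKY_SLOPE


@dataclass(frozen=True)
class PoolSpec:
    pass


@dataclass(frozen=True)
class FlattenSpec:
    pass


@dataclass(frozen=True)
class LinearSpec:
    out_features: int
    in_features: int


LayerSpecT = (
    ConvSpec
    | BatchNorm2dSpec
    | BatchNorm1dSpec
    | ActSpec
    | PoolSpec
    | FlattenSpec
    | LinearSpec
)


class ShapeError(ValueError):
    """A layer is inconsistent with its incoming shape."""

    def __init__(self, layer_index: int, spec, message: str):
        self.layer_index = layer_index
        self.spec = spec
        super().__init__(f"layer {layer_index} ({spec}): {message}")


@dataclass
class NetSpec:
    """Ordered layer descriptors plus the expected input shape."""

    layers: list[LayerSpecT]
    input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE

    @classmethod
    def default(cls) -> "NetSpec":
        """The full-size architecture (input 1 x 40500 x 4000)."""
        specs: list[LayerSpecT] = []

        def conv_bn(out_ch, in_ch, kh, kw, sh=1, sw=1):
            specs.append(ConvSpec(out_ch, in_ch, kh, kw, sh, sw))
            specs.append(BatchNorm2dSpec(out_ch))
            specs.append(ActSpec())

        # ray-feature integration, then ray integration; the kernel tiles
        # the stride exactly so 'same' padding contributes no pixels
        conv_bn(1, 1, 9, 1, sh=9)
        conv_bn(1, 1, 25, 1, sh=25)
        conv_bn(3, 1, 3, 3)
        specs.append(PoolSpec())
        conv_bn(9, 3, 3, 3)
        specs.append(PoolSpec())
        conv_bn(27, 9, 3, 3)
        specs.append(PoolSpec())
        conv_bn(9, 27, 3, 3)
        specs.append(PoolSpec())
        conv_bn(3, 9, 3, 3)
        conv_bn(1, 3, 3, 3)
        specs.append(FlattenSpec())
        for out_f, in_f in ((560, 1220), (560, 560), (560, 560)):
            specs.append(LinearSpec(out_f, in_f))
            specs.append(BatchNorm1dSpec(out_f))
            specs.append(ActSpec())
        specs.append(LinearSpec(360, 560))
        return cls(specs, DEFAULT_INPUT_SHAPE)

    @classmethod
    def scaled(
        cls,
        n_angles: int,
        n_bins: int,
        channels: tuple[int, ...] = (3, 9, 9),
        hidden: int = 64,
        n_out: int = 360,
    ) -> "NetSpec":
        """A proportionally shrunk architecture for desk-scale training.

        Keeps the two integration convolutions (9x1/s9 over features,
        25x1/s25 over rays) and as many 3x3 conv(+pool) blocks as the
        reduced spatial extent allows, then the flatten + fully
        connected predictor with ``hidden`` units.
        """
        rows = n_angles * 25 * 9
        specs: list[LayerSpecT] = []

        def conv_bn(out_ch, in_ch, kh, kw, sh=1, sw=1):
            specs.append(ConvSpec(out_ch, in_ch, kh, kw, sh, sw))
            specs.append(BatchNorm2dSpec(out_ch))
            specs.append(ActSpec())

        conv_bn(1, 1, 9, 1, sh=9)
        conv_bn(1, 1, 25, 1, sh=25)
        h, w, in_ch = n_angles, n_bins, 1
        for i, ch in enumerate(channels):
            if h < 3 or w < 3:
                break
            conv_bn(ch, in_ch, 3, 3)
            h, w, in_ch = h - 2, w - 2, ch
            if i < len(channels) - 1 and h >= 4 and w >= 4:
                specs.append(PoolSpec())
                h, w = h // 2, w // 2
        specs.append(FlattenSpec())
        flat = in_ch * h * w
        for out_f, in_f in ((hidden, flat), (hidden, hidden)):
            specs.append(LinearSpec(out_f, in_f))
            specs.append(BatchNorm1dSpec(out_f))
            specs.append(ActSpec())
        specs.append(LinearSpec(n_out, hidden))
        return cls(specs, (1, rows, n_bins))


def shape_inference(
    spec: NetSpec, input_shape: tuple[int, int, int] | None = None
) -> list[tuple[int, ...]]:
    """Per-layer output shapes, computed without running the network.

    Convolution: H' = floor((H + 2p - k) / s) + 1 per spatial axis;
    pooling halves each axis with floor. Raises :class:`ShapeError` if
    any intermediate dimension becomes non-positive or a layer's channel
    or feature count disagrees with its input.
    """
    shape: tuple[int, ...] = tuple(input_shape or spec.input_shape)
    out: list[tuple[int, ...]] = []
    for i, ls in enumerate(spec.layers):
        if isinstance(ls, ConvSpec):
            c, h, w = shape
            if c != ls.in_ch:
                raise ShapeError(i, ls, f"expects {ls.in_ch} channels, got {c}")
            nh = (h + 2 * ls.ph - ls.kh) // ls.sh + 1
            nw = (w + 2 * ls.pw - ls.kw) // ls.sw + 1
            if nh <= 0 or nw <= 0:
                raise ShapeError(i, ls, f"output {nh}x{nw} is non-positive")
            shape = (ls.out_ch, nh, nw)
        elif isinstance(ls, BatchNorm2dSpec):
            if shape[0] != ls.features:
                raise ShapeError(i, ls, f"expects {ls.features} ch, got {shape[0]}")
        elif isinstance(ls, PoolSpec):
            c, h, w = shape
            if h < 2 or w < 2:
                raise ShapeError(i, ls, f"cannot pool {h}x{w}")
            shape = (c, h // 2, w // 2)
        elif isinstance(ls, FlattenSpec):
            shape = (int(np.prod(shape)),)
        elif isinstance(ls, LinearSpec):
            if shape != (ls.in_features,):
                raise ShapeError(
                    i, ls, f"expects ({ls.in_features},), got {shape}"
                )
            shape = (ls.out_features,)
        elif isinstance(ls, BatchNorm1dSpec):
            if shape != (ls.features,):
                raise ShapeError(i, ls, f"expects ({ls.features},), got {shape}")
        out.append(shape)
    return out


def build_net(
    spec: NetSpec, seed: int = 0, dtype=np.float32
) -> nn.Network:
    """Instantiate the network with deterministic initialization."""
    shape_inference(spec)  # validate before building
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    for ls in spec.layers:
        if isinstance(ls, ConvSpec):
            layers.append(
                nn.Conv2d(
                    ls.out_ch, ls.in_ch, ls.kh, ls.kw, ls.sh, ls.sw,
                    ls.ph, ls.pw, rng=rng, dtype=dtype,
                )
            )
        elif isinstance(ls, BatchNorm2dSpec):
            layers.append(nn.BatchNorm2d(ls.features, rng=rng, dtype=dtype))
        elif isinstance(ls, BatchNorm1dSpec):
            layers.append(nn.BatchNorm1d(ls.features, rng=rng, dtype=dtype))
        elif isinstance(ls, ActSpec):
            layers.append(nn.LeakyReLU(ls.slope))
        elif isinstance(ls, PoolSpec):
            layers.append(nn.MaxPool2d())
        elif isinstance(ls, FlattenSpec):
            layers.append(nn.Flatten())
        elif isinstance(ls, LinearSpec):
            layers.append(
                nn.Linear(ls.out_features, ls.in_features, rng=rng, dtype=dtype)
            )
    return nn.Network(layers)


# --- losses -----------------------------------------------------------------

@dataclass
class LossConfig:
    """Which training loss to use; beta is the smooth-L1 threshold."""

    name: str = "smooth_L1"
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in ("L1", "L2", "smooth_L1"):
            raise ValueError(f"unknown loss {self.name!r}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def loss(config: LossConfig, x: np.ndarray, y: np.ndarray) -> float:
    """Scalar loss between reference ``x`` and prediction ``y``."""
    return loss_and_grad(config, x, y)[0]


def loss_and_grad(
    config: LossConfig, x: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the prediction ``y``.

    Per-element terms: L1 |d|; L2 d^2; smooth-L1 0.5 d^2 / beta when
    |d| < beta, else |d| - 0.5 beta (d = x - y). The loss is the mean
    term over all elements.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    d = y - x
    n = d.size
    if config.name == "L1":
        value = np.abs(d).mean()
        grad = np.sign(d) / n
    elif config.name == "L2":
        value = (d**2).mean()
        grad = 2.0 * d / n
    else:
        b = config.beta
        quad = np.abs(d) < b
        z = np.where(quad, 0.5 * d**2 / b, np.abs(d) - 0.5 * b)
        value = z.mean()
        grad = np.where(quad, d / b, np.sign(d)) / n
    return float(value), grad


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error (the reported accuracy metric)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return float(((x - y) ** 2).mean())


# --- inference --------------------------------------------------------------

def predict_sbeam(network: nn.Network, features) -> SBeam:
    """Run the network on one feature tensor and clamp into [0, 1].

    Clamping only affects out-of-range values, so the induced angle
    ranking is unchanged for in-range scores.
    """
    values = np.asarray(features.values, dtype=np.float32)
    x = values[None, None, :, :]
    y = network.forward(x, training=False)[0]
    if y.shape != (360,):
        raise ValueError(f"network produced {y.shape}, expected (360,)")
    return SBeam(np.clip(y.astype(np.float64), 0.0, 1.0))


# --- weight persistence -----------------------------------------------------

def save_weights(network: nn.Network, spec: NetSpec, path: str | Path) -> None:
    state = network.state_arrays()
    state["_spec_repr"] = np.array(repr(spec.layers) + repr(spec.input_shape))
    np.savez(path, **state)


def load_weights(network: nn.Network, spec: NetSpec, path: str | Path) -> None:
    with np.load(path, allow_pickle=False) as data:
        stored = str(data["_spec_repr"])
        expect = repr(spec.layers) + repr(spec.input_shape)
        if stored != expect:
            raise ValueError("weight file does not match the given NetSpec")
        network.load_state_arrays({k: data[k] for k in data.files if not k.startswith("_")})
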