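"""The SCDU-Net architecture.

A symmetric U-shaped encoder-decoder: each encoder stage applies a
cascaded pair of residual blocks, recalibrates the result with the
spatial-channel dual attention module, and halves the resolution with a
stride-2 convolution (doubling channels).  The bottleneck is the pruned
dense ASPP; the decoder mirrors the encoder with 2x upsampling, skip
concatenation and two plain conv-norm-ReLU layers per stage, ending in a
1x1 classification head.

With kernel 3 and dilations 1/2/3, the bottleneck's branch receptive
fields are 3/5/7, and stacking the two largest through the dense
connectivity gives a maximum theoretical receptive field of 13.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .aspp import DenseASPP
from .attention import SCAttention
from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, Module, Sequential,
                 Tensor, concat)

__all__ = ["NetworkConfig", "ResidualBlock", "ResidualStage", "SCDUNet",
           "build_scdunet", "encoder_conv_count", "dilated_receptive_field",
           "stacked_receptive_field", "max_receptive_field",
           "save_checkpoint", "load_checkpoint"]


# ---------------------------------------------------------------------------
# receptive-field algebra

def dilated_receptive_field(k: int, d: int) -> int:
    """Receptive field of one k x k convolution with dilation d:
    RF = k + (k-1)(d-1)."""
    if k < 1 or d < 1:
        raise ValueError("kernel size and dilation must be >= 1")
    if k % 2 == 0:
        raise ValueError("kernel size must be odd")
    return k + (k - 1) * (d - 1)


def stacked_receptive_field(k1: int, k2: int) -> int:
    """Receptive field of two stacked convolutions with fields K1, K2:
    K = K1 + K2 - 1."""
    if k1 < 1 or k2 < 1:
        raise ValueError("receptive fields must be >= 1")
    return k1 + k2 - 1


def max_receptive_field(kernel: int, dilations) -> int:
    """Maximum theoretical receptive field of the pruned dense pyramid.

    Each branch l sees the concatenation of the input with the outputs of
    all smaller-dilation branches, so its accumulated field is its own
    dilated field superposed on the largest field among its inputs.  With
    kernel 3 and dilations 1/2/3 the branch fields are 3/5/7, the d1->d2
    chain accumulates 3 + 5 - 1 = 7, and the final superposition of two
    7-wide fields gives 13.
    """
    from .aspp import denseaspp_input_sets

    schedule = denseaspp_input_sets(dilations)
    chained: list[int] = []
    for l, d in enumerate(schedule.dilations, start=1):
        own = dilated_receptive_field(kernel, d)
        feed = max([1] + [chained[i - 1] for i in schedule.input_sets[l - 1]])
        chained.append(stacked_receptive_field(own, feed))
    return max(chained)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``base_channels`` doubles at every downsampling; with the full-scale
    default (64, 4 stages) the bottleneck is 1024-wide.  The test preset
    uses ``base_channels=8`` on 64x64 inputs.
    """

    in_channels: int = 1
    num_classes: int = 3
    base_channels: int = 64
    stages: int = 4
    reduction_ratio: int = 16
    aspp_dilations: tuple = (1, 2, 3)
    aspp_layer_channels: int | None = None   # default: bottleneck width / 4
    sc_placement: str = "encoder"            # encoder | decoder | both
    upsample: str = "transposed"             # transposed | bilinear
    init_seed: int = 0

    def __post_init__(self):
        if self.stages < 1:
            raise ValueError("stages must be >= 1")
        dil = tuple(self.aspp_dilations)
        if any(d <= 0 for d in dil) or any(b <= a for a, b in zip(dil, dil[1:])):
            raise ValueError("aspp_dilations must be strictly increasing and positive")
        self.aspp_dilations = dil
        if self.sc_placement not in ("encoder", "decoder", "both"):
            raise ValueError("sc_placement must be encoder, decoder or both")
        if self.upsample not in ("transposed", "bilinear"):
            raise ValueError("upsample must be transposed or bilinear")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** self.stages

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aspp_dilations"] = list(self.aspp_dilations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


def encoder_conv_count(config: NetworkConfig) -> int:
    """Learnable convolutions on the encoder path.

    Per stage: 2 residual blocks x 2 convolutions + 1 downsampling
    convolution = 5; the default four stages give a 20-layer encoder.
    """
    return 5 * config.stages


# ---------------------------------------------------------------------------
# blocks

def _conv_bn_relu(in_ch, out_ch, *, stride=1, rng, dtype):
    return Sequential(Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                             rng=rng, dtype=dtype),
                      BatchNorm2d(out_ch, dtype=dtype))


class ResidualBlock(Module):
    """x + F(x), F = [3x3 conv -> BN -> ReLU] x 2 with matched channels."""

    def __init__(self, channels: int, *, rng=None, dtype=np.float32):
        super().__init__()
        self.body1 = _conv_bn_relu(channels, channels, rng=rng, dtype=dtype)
        self.body2 = _conv_bn_relu(channels, channels, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        f = self.body2(self.body1(x).relu()).relu()
        return x + f


class ResidualStage(Module):
    """Two cascaded residual blocks: x' = x + F1(x) + F2(x + F1(x))."""

    def __init__(self, channels: int, *, rng=None, dtype=np.float32):
        super().__init__()
        self.block1 = ResidualBlock(channels, rng=rng, dtype=dtype)
        self.block2 = ResidualBlock(channels, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


def _bilinear_up2(x: Tensor) -> Tensor:
    """Differentiable 2x bilinear upsampling (half-pixel centres)."""

    def up_axis(t: Tensor, axis: int) -> Tensor:
        n = t.shape[axis]
        sl = [slice(None)] * t.ndim

        def take(a, b):
            s = list(sl)
            s[axis] = slice(a, b)
            return t[tuple(s)]

        left = concat([take(0, 1), take(0, n - 1)], axis=axis)
        right = concat([take(1, n), take(n - 1, n)], axis=axis)
        even = 0.25 * left + 0.75 * t
        odd = 0.75 * t + 0.25 * right
        shape = list(t.shape)
        shape.insert(axis + 1, 1)
        stacked = concat([even.reshape(*shape), odd.reshape(*shape)], axis=axis + 1)
        out_shape = list(t.shape)
        out_shape[axis] = 2 * n
        return stacked.reshape(*out_shape)

    return up_axis(up_axis(x, 2), 3)


class _Upsample(Module):
    def __init__(self, in_ch, out_ch, mode, *, rng, dtype):
        super().__init__()
        self.mode = mode
        if mode == "transposed":
            self.op = ConvTranspose2d(in_ch, out_ch, rng=rng, dtype=dtype)
        else:
            self.op = Conv2d(in_ch, out_ch, 3, padding=1, rng=rng, dtype=dtype)

    def forward(self, x):
        if self.mode == "transposed":
            return self.op(x)
        return self.op(_bilinear_up2(x))


class SCDUNet(Module):
    """Full network; see module docstring for the stage layout."""

    def __init__(self, config: NetworkConfig, *, dtype=np.float32):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        base, stages = config.base_channels, config.stages
        r = config.reduction_ratio
        enc_sc = config.sc_placement in ("encoder", "both")
        dec_sc = config.sc_placement in ("decoder", "both")

        self.stem = _conv_bn_relu(config.in_channels, base, rng=rng, dtype=dtype)
        self.enc_stages, self.enc_attn, self.downs = [], [], []
        for s in range(stages):
            w = base * 2 ** s
            self.enc_stages.append(ResidualStage(w, rng=rng, dtype=dtype))
            self.enc_attn.append(SCAttention(w, r, rng=rng, dtype=dtype) if enc_sc else None)
            self.downs.append(_conv_bn_relu(w, 2 * w, stride=2, rng=rng, dtype=dtype))
        self.bottleneck = DenseASPP(config.bottleneck_channels,
                                    dilations=config.aspp_dilations,
                                    growth=config.aspp_layer_channels,
                                    rng=rng, dtype=dtype)
        self.ups, self.dec_stages, self.dec_attn = [], [], []
        for s in reversed(range(stages)):
            w = base * 2 ** s
            self.ups.append(_Upsample(2 * w, w, config.upsample, rng=rng, dtype=dtype))
            self.dec_stages.append(Sequential(
                _conv_bn_relu(2 * w, w, rng=rng, dtype=dtype),
                _conv_bn_relu(w, w, rng=rng, dtype=dtype)))
            self.dec_attn.append(SCAttention(w, r, rng=rng, dtype=dtype) if dec_sc else None)
        self.head = Conv2d(base, config.num_classes, 1, rng=rng, dtype=dtype)
        # attention slots may be None; keep child discovery happy
        self.enc_attn = [a for a in self.enc_attn] if enc_sc else []
        self.dec_attn = [a for a in self.dec_attn] if dec_sc else []
        self._enc_sc, self._dec_sc = enc_sc, dec_sc

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        b, c, h, w = x.shape
        div = 2 ** self.config.stages
        if h % div or w % div:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by 2^stages = {div}")
        y = self.stem(x).relu()
        skips = []
        for s in range(self.config.stages):
            y = self.enc_stages[s](y)
            if self._enc_sc:
                y = self.enc_attn[s](y)
            skips.append(y)                       # tapped after attention
            y = self.downs[s](y).relu()
        y = self.bottleneck(y)
        for i, s in enumerate(reversed(range(self.config.stages))):
            y = self.ups[i](y)
            y = concat([y, skips[s]], axis=1)
            stage = self.dec_stages[i]
            y = stage[0](y).relu()
            y = stage[1](y).relu()
            if self._dec_sc:
                y = self.dec_attn[i](y)
        return self.head(y)

    def predict_slices(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Argmax labels for a stack of (N, H, W) normalised slices."""
        self.eval()
        out = []
        for i in range(0, len(images), batch_size):
            batch = images[i:i + batch_size][:, None, :, :].astype(np.float32)
            logits = self.forward(Tensor(batch)).data
            out.append(np.argmax(logits, axis=1))
        return np.concatenate(out, axis=0)


def build_scdunet(config: NetworkConfig, *, dtype=np.float32) -> SCDUNet:
    """Build the network from a config (seeded, reproducible)."""
    return SCDUNet(config, dtype=dtype)


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: SCDUNet, path) -> None:
    """Weights + full NetworkConfig in one ``.npz`` file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path, *, dtype=np.float32) -> SCDUNet:
    with np.load(Path(path)) as data:
        cfg_json = bytes(data["__config__"]).decode()
        state = {k: data[k] for k in data.files if k != "__config__"}
    config = NetworkConfig.from_dict(json.loads(cfg_json))
    model = build_scdunet(config, dtype=dtype)
    model.load_state_dict(state)
    return model
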