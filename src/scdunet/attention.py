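"""Spatial-channel dual attention (SC): channel squeeze-excitation fused
with coordinate attention by element-wise addition.

The channel branch (cSE) squeezes each channel to its global average and
learns per-channel gates through a reduce/expand pair of fully connected
layers.  The coordinate branch (CA) pools separately along height and
width, mixes the two pooled profiles through a shared 1x1 convolution,
and emits direction-aware gates alpha_h (length H) and alpha_w (length W)
whose outer product rescales the feature map.  Both branch gates pass
through a sigmoid, so they lie strictly in (0, 1).
"""

from __future__ import annotations

import numpy as np

from .nn import Linear, Module, Tensor, concat

__all__ = ["ChannelAttention", "CoordinateAttention", "SCAttention"]


def _hidden_width(channels: int, reduction: int) -> int:
    # floor the bottleneck, but never below 4 channels
    return max(channels // reduction, 4)


class ChannelAttention(Module):
    """Squeeze-and-excitation channel gating (cSE)."""

    def __init__(self, channels: int, reduction: int = 16, *, rng=None,
                 dtype=np.float32):
        super().__init__()
        hidden = _hidden_width(channels, reduction)
        self.fc1 = Linear(channels, hidden, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng=rng, dtype=dtype)

    def gates(self, x: Tensor) -> Tensor:
        z = x.mean(axis=(2, 3))                      # (B, C) global average
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        return x * self.gates(x).reshape(b, c, 1, 1)


class CoordinateAttention(Module):
    """Direction-aware gating from height- and width-pooled profiles.

    The pooled profiles are concatenated along the spatial axis (giving a
    (H+W)-long sequence of C-vectors), reduced by a shared 1x1 conv with
    ReLU, split back into the two directions, and expanded per direction
    to C channels with a sigmoid.
    """

    def __init__(self, channels: int, reduction: int = 16, *, rng=None,
                 dtype=np.float32):
        super().__init__()
        hidden = _hidden_width(channels, reduction)
        self.shared = Linear(channels, hidden, rng=rng, dtype=dtype)
        self.fc_h = Linear(hidden, channels, rng=rng, dtype=dtype)
        self.fc_w = Linear(hidden, channels, rng=rng, dtype=dtype)

    def gates(self, x: Tensor):
        b, c, h, w = x.shape
        zh = x.mean(axis=3)                          # (B, C, H): average over width
        zw = x.mean(axis=2)                          # (B, C, W): average over height
        z = concat([zh, zw], axis=2)                 # (B, C, H+W)
        y = self.shared(z.transpose(0, 2, 1)).relu()  # (B, H+W, hidden)
        alpha_h = self.fc_h(y[:, :h, :]).sigmoid()   # (B, H, C)
        alpha_w = self.fc_w(y[:, h:, :]).sigmoid()   # (B, W, C)
        return (alpha_h.transpose(0, 2, 1).reshape(b, c, h, 1),
                alpha_w.transpose(0, 2, 1).reshape(b, c, 1, w))

    def forward(self, x: Tensor) -> Tensor:
        alpha_h, alpha_w = self.gates(x)
        return x * alpha_h * alpha_w


class SCAttention(Module):
    """Element-wise sum of the cSE and CA branch outputs."""

    def __init__(self, channels: int, reduction: int = 16, *, rng=None,
                 dtype=np.float32):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng=rng, dtype=dtype)
        self.coordinate = CoordinateAttention(channels, reduction, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.channel(x) + self.coordinate(x)
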