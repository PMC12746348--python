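"""Selectively connected dense atrous spatial pyramid pooling.

Unlike a fully dense ASPP, each dilated branch consumes only the original
bottleneck feature map plus the outputs of branches with *strictly
smaller* dilation rates; the branch outputs and the input are finally
concatenated and projected back to the bottleneck width with a 1x1
convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Sequential, Tensor, concat

__all__ = ["DilationSchedule", "denseaspp_input_sets", "DenseASPP"]


@dataclass(frozen=True)
class DilationSchedule:
    """Dilations plus, per layer, the 1-based indices of the layers it reads."""

    dilations: tuple
    input_sets: tuple      # tuple of frozensets, S_l = {i : d_i < d_l}


def denseaspp_input_sets(dilations) -> DilationSchedule:
    """Connectivity of the pruned dense ASPP: S_l = {i | d_i < d_l}.

    Dilations must be strictly increasing: under sequential evaluation a
    repeated (or decreasing) rate would require the output of a layer not
    yet computed to be distinguishable from an already-computed equal
    rate, so such schedules are rejected.
    """
    dilations = tuple(int(d) for d in dilations)
    if not dilations:
        raise ValueError("need at least one dilation rate")
    if any(d <= 0 for d in dilations):
        raise ValueError("dilation rates must be positive")
    if any(b <= a for a, b in zip(dilations, dilations[1:])):
        raise ValueError(f"dilation rates must be strictly increasing, got {dilations}")
    sets = tuple(frozenset(i + 1 for i, di in enumerate(dilations) if di < dl)
                 for dl in dilations)
    return DilationSchedule(dilations=dilations, input_sets=sets)


class DenseASPP(Module):
    """Pruned dense ASPP bottleneck block.

    Each branch l is a 3x3 convolution with dilation d_l and "same"
    padding, followed by batch norm and ReLU, consuming the concatenation
    of the input with the outputs of all smaller-dilation branches.  The
    output projection restores the input channel count.
    """

    def __init__(self, channels: int, dilations=(1, 2, 3), growth: int | None = None,
                 *, rng=None, dtype=np.float32):
        super().__init__()
        self.schedule = denseaspp_input_sets(dilations)
        self.growth = growth if growth is not None else max(channels // 4, 1)
        self.branches = []
        for l, d in enumerate(self.schedule.dilations, start=1):
            in_ch = channels + len(self.schedule.input_sets[l - 1]) * self.growth
            self.branches.append(Sequential(
                Conv2d(in_ch, self.growth, 3, dilation=d, padding=d, rng=rng, dtype=dtype),
                BatchNorm2d(self.growth, dtype=dtype)))
        n = len(self.schedule.dilations)
        self.project = Sequential(
            Conv2d(channels + n * self.growth, channels, 1, rng=rng, dtype=dtype),
            BatchNorm2d(channels, dtype=dtype))

    def branch_input_channels(self, layer: int, channels: int) -> int:
        """Channel count entering branch `layer` (1-based)."""
        return channels + len(self.schedule.input_sets[layer - 1]) * self.growth

    def forward(self, x0: Tensor) -> Tensor:
        outputs: list[Tensor] = []
        for l, branch in enumerate(self.branches, start=1):
            feeds = [x0] + [outputs[i - 1] for i in sorted(self.schedule.input_sets[l - 1])]
            inp = feeds[0] if len(feeds) == 1 else concat(feeds, axis=1)
            outputs.append(branch(inp).relu())
        return self.project(concat([x0] + outputs, axis=1)).relu()
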