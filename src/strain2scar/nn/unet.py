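"""UNet encoder-decoder for binary infarct segmentation.

The default configuration follows the classic contracting/expansive
layout: four encoder stages of two 3x3 convolutions (ReLU, bias, no
normalization layers) with channel ladder 16-32-64-128, 2x2 max pooling
between stages, a 256-channel bottleneck, then four decoder stages of 2x2
transposed convolution, skip concatenation and two 3x3 convolutions, and
a final 1x1 convolution to one channel squashed by a sigmoid.  At the
default ladder this comes to exactly 1,941,105 trainable parameters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .core import (Conv2d, ConvBlock, ConvTranspose2d, MaxPool2d, Sigmoid,
                   concat_channels)


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``channels`` lists encoder stage widths ending with the bottleneck;
    the spatial resolution must be divisible by ``2 ** (len(channels)-1)``
    (16 for the default five-entry ladder).
    """

    input_resolution: int = 128
    input_channels: int = 3
    channels: tuple = (16, 32, 64, 128, 256)

    def __post_init__(self):
        depth = len(self.channels) - 1
        if depth < 1:
            raise ValueError("channels must list at least two stages")
        if self.input_resolution % (2 ** depth) != 0:
            raise ValueError(
                f"input_resolution {self.input_resolution} not divisible by "
                f"{2 ** depth}")


class UNet:
    """Base UNet; maps (N, C, H, W) inputs to (N, 1, H, W) probabilities."""

    def __init__(self, config: UNetConfig | None = None, seed: int = 0):
        self.config = config or UNetConfig()
        rng = np.random.default_rng(seed)
        chans = self.config.channels
        enc_chans = chans[:-1]
        self.enc_blocks = []
        cin = self.config.input_channels
        for i, c in enumerate(enc_chans):
            self.enc_blocks.append(ConvBlock(cin, c, rng, f"enc{i + 1}"))
            cin = c
        self.pools = [MaxPool2d() for _ in enc_chans]
        self.bottleneck = ConvBlock(enc_chans[-1], chans[-1], rng, "bottleneck")
        self.upconvs = []
        self.dec_blocks = []
        up_in = chans[-1]
        for i, c in enumerate(reversed(enc_chans)):
            self.upconvs.append(ConvTranspose2d(up_in, c, rng, f"up{i + 1}"))
            self.dec_blocks.append(ConvBlock(2 * c, c, rng, f"dec{i + 1}"))
            up_in = c
        self.final = Conv2d(enc_chans[0], 1, 1, rng, "final")
        self.sigmoid = Sigmoid()
        self._skips = None
        self.dtype = np.float32

    # -- API ---------------------------------------------------------------
    def to_double(self):
        """Promote parameters and activations to float64 (gradient checks)."""
        self.dtype = np.float64
        for p in self.parameters():
            p.data = p.data.astype(np.float64)
            p.grad = p.grad.astype(np.float64)
        return self

    def parameters(self):
        params = []
        for blk in self.enc_blocks:
            params += blk.parameters()
        params += self.bottleneck.parameters()
        for up, dec in zip(self.upconvs, self.dec_blocks):
            params += up.parameters() + dec.parameters()
        params += self.final.parameters()
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        for up, dec, skip in zip(self.upconvs, self.dec_blocks,
                                 reversed(skips)):
            h = up.forward(h)
            h = concat_channels(skip, h)
            h = dec.forward(h)
        logits = self.final.forward(h)
        self._skips = skips
        return self.sigmoid.forward(logits)

    def backward(self, dldp: np.ndarray) -> np.ndarray:
        d = self.sigmoid.backward(np.ascontiguousarray(dldp, dtype=self.dtype))
        d = self.final.backward(d)
        dskips = [None] * len(self.enc_blocks)
        for i, (up, dec) in enumerate(zip(reversed(self.upconvs),
                                          reversed(self.dec_blocks))):
            d = dec.backward(d)
            c = d.shape[1] // 2
            dskips[i] = d[:, :c]
            d = up.backward(np.ascontiguousarray(d[:, c:]))
        d = self.bottleneck.backward(d)
        # dskips were collected shallow-to-deep; encoder unwinds deep-to-shallow
        for blk, pool, dskip in zip(reversed(self.enc_blocks),
                                    reversed(self.pools), reversed(dskips)):
            d = pool.backward(d)
            d = blk.backward(d + dskip)
        return d

    # -- weights -----------------------------------------------------------
    def state_dict(self):
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state):
        for p in self.parameters():
            p.data[...] = state[p.name]

    def copy(self) -> "UNet":
        clone = UNet(self.config, seed=0)
        clone.load_state_dict(self.state_dict())
        return clone


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    """Construct a UNet; rejects resolutions the pooling ladder cannot halve."""
    return UNet(config, seed=seed)


def count_parameters(model) -> int:
    """Exact number of trainable scalars in a model."""
    return int(sum(p.data.size for p in model.parameters()))


def summarize(model) -> str:
    """Plain-text architecture summary: one line per parameter tensor."""
    lines = [f"{p.name:24s} {str(p.data.shape):22s} {p.data.size:>10d}"
             for p in model.parameters()]
    lines.append(f"{'total':24s} {'':22s} {count_parameters(model):>10d}")
    return "\n".join(lines)
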