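"""Standard UNet variants grafted onto the base channel ladder.

All variants keep the base encoder-decoder channel schedule and I/O
contract (H x W x 3 in, H x W x 1 probability out) and differ only in the
published mechanism they add:

* attention — additive attention gates on the skip connections;
* dense — dense (concatenative) connections inside the encoder blocks;
* residual_attention — residual encoder blocks combined with the
  attention gates.

Each adds parameters on top of the base UNet's count.
"""

from __future__ import annotations

import numpy as np

from .core import (Conv2d, ConvBlock, ConvTranspose2d, MaxPool2d, ReLU,
                   Sigmoid, concat_channels)
from .unet import UNet, UNetConfig


class AttentionGate:
    """Additive attention gate: skip' = skip * sigmoid(psi(relu(Wx x + Wg g)))."""

    def __init__(self, channels: int, rng, name: str):
        inter = max(channels // 2, 1)
        self.wx = Conv2d(channels, inter, 1, rng, f"{name}.wx")
        self.wg = Conv2d(channels, inter, 1, rng, f"{name}.wg")
        self.relu = ReLU()
        self.psi = Conv2d(inter, 1, 1, rng, f"{name}.psi")
        self.sig = Sigmoid()
        self._cache = None

    def parameters(self):
        return self.wx.parameters() + self.wg.parameters() + self.psi.parameters()

    def forward(self, skip, gate):
        a = self.relu.forward(self.wx.forward(skip) + self.wg.forward(gate))
        alpha = self.sig.forward(self.psi.forward(a))
        self._cache = (skip, alpha)
        return skip * alpha

    def backward(self, dy):
        skip, alpha = self._cache
        dskip = dy * alpha
        dalpha = (dy * skip).sum(axis=1, keepdims=True)
        da = self.relu.backward(self.psi.backward(self.sig.backward(dalpha)))
        dskip = dskip + self.wx.backward(da)
        dgate = self.wg.backward(da)
        return dskip.astype(dy.dtype), dgate.astype(dy.dtype)


class DenseBlock:
    """Encoder block with a dense connection: the second convolution sees
    the concatenation of the block input and the first convolution's output."""

    def __init__(self, cin: int, cout: int, rng, name: str):
        self.conv1 = Conv2d(cin, cout, 3, rng, f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cin + cout, cout, 3, rng, f"{name}.conv2")
        self.relu2 = ReLU()
        self._cin = cin

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()

    def forward(self, x):
        h1 = self.relu1.forward(self.conv1.forward(x))
        h2 = concat_channels(x, h1)
        return self.relu2.forward(self.conv2.forward(h2))

    def backward(self, dy):
        d = self.conv2.backward(self.relu2.backward(dy))
        dx = np.ascontiguousarray(d[:, :self._cin])
        dh1 = np.ascontiguousarray(d[:, self._cin:])
        dx = dx + self.conv1.backward(self.relu1.backward(dh1))
        return dx


class ResidualBlock:
    """Residual encoder block: out = relu(convblock(x) + proj(x))."""

    def __init__(self, cin: int, cout: int, rng, name: str):
        self.conv1 = Conv2d(cin, cout, 3, rng, f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng, f"{name}.conv2")
        self.proj = Conv2d(cin, cout, 1, rng, f"{name}.proj")
        self.relu_out = ReLU()

    def parameters(self):
        return (self.conv1.parameters() + self.conv2.parameters()
                + self.proj.parameters())

    def forward(self, x):
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(h + self.proj.forward(x))

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dx = self.proj.backward(d)
        dx = dx + self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return dx


class _VariantUNet(UNet):
    """UNet with pluggable encoder blocks and optional skip attention gates."""

    def __init__(self, config: UNetConfig | None = None, seed: int = 0,
                 encoder_block=ConvBlock, attention: bool = False):
        self.config = config or UNetConfig()
        rng = np.random.default_rng(seed)
        chans = self.config.channels
        enc_chans = chans[:-1]
        self.enc_blocks = []
        cin = self.config.input_channels
        for i, c in enumerate(enc_chans):
            self.enc_blocks.append(encoder_block(cin, c, rng, f"enc{i + 1}"))
            cin = c
        self.pools = [MaxPool2d() for _ in enc_chans]
        self.bottleneck = ConvBlock(enc_chans[-1], chans[-1], rng, "bottleneck")
        self.upconvs = []
        self.dec_blocks = []
        self.gates = []
        up_in = chans[-1]
        for i, c in enumerate(reversed(enc_chans)):
            self.upconvs.append(ConvTranspose2d(up_in, c, rng, f"up{i + 1}"))
            self.dec_blocks.append(ConvBlock(2 * c, c, rng, f"dec{i + 1}"))
            self.gates.append(AttentionGate(c, rng, f"gate{i + 1}")
                              if attention else None)
            up_in = c
        self.final = Conv2d(enc_chans[0], 1, 1, rng, "final")
        self.sigmoid = Sigmoid()
        self._skips = None
        self.dtype = np.float32

    def parameters(self):
        params = []
        for blk in self.enc_blocks:
            params += blk.parameters()
        params += self.bottleneck.parameters()
        for up, dec, gate in zip(self.upconvs, self.dec_blocks, self.gates):
            params += up.parameters() + dec.parameters()
            if gate is not None:
                params += gate.parameters()
        params += self.final.parameters()
        return params

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        for up, dec, gate, skip in zip(self.upconvs, self.dec_blocks,
                                       self.gates, reversed(skips)):
            h = up.forward(h)
            if gate is not None:
                skip = gate.forward(skip, h)
            h = dec.forward(concat_channels(skip, h))
        logits = self.final.forward(h)
        self._skips = skips
        return self.sigmoid.forward(logits)

    def backward(self, dldp):
        d = self.sigmoid.backward(np.ascontiguousarray(dldp, dtype=self.dtype))
        d = self.final.backward(d)
        dskips = [None] * len(self.enc_blocks)
        stages = list(zip(self.upconvs, self.dec_blocks, self.gates))
        for i, (up, dec, gate) in enumerate(reversed(stages)):
            d = dec.backward(d)
            c = d.shape[1] // 2
            dskip = np.ascontiguousarray(d[:, :c])
            dup = np.ascontiguousarray(d[:, c:])
            if gate is not None:
                dskip, dgate = gate.backward(dskip)
                dup = dup + dgate
            dskips[i] = dskip
            d = up.backward(dup)
        d = self.bottleneck.backward(d)
        for blk, pool, dskip in zip(reversed(self.enc_blocks),
                                    reversed(self.pools), reversed(dskips)):
            d = pool.backward(d)
            d = blk.backward(d + dskip)
        return d

    def copy(self):
        raise NotImplementedError("use state_dict/load_state_dict for variants")


VARIANT_KINDS = ("attention", "dense", "residual_attention")


def build_variant(kind: str, config: UNetConfig | None = None,
                  seed: int = 0) -> _VariantUNet:
    """Build a published UNet variant on the base channel schedule."""
    if kind == "attention":
        return _VariantUNet(config, seed, encoder_block=ConvBlock, attention=True)
    if kind == "dense":
        return _VariantUNet(config, seed, encoder_block=DenseBlock, attention=False)
    if kind == "residual_attention":
        return _VariantUNet(config, seed, encoder_block=ResidualBlock,
                            attention=True)
    raise ValueError(f"unknown variant kind {kind!r}")
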