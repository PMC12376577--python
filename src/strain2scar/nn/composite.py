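"""Composite multi-fidelity network: low-fidelity trunk plus correction heads.

Abundant simulated strain data train a UNet trunk; scarce high-fidelity
data train two small correction heads that map the trunk prediction onto
the high-fidelity domain,

    y_H = f_l(x_H, y_L) + f_nl(x_H, y_L),

where ``f_l`` is a single 10x10 convolution (a linear map rescaling and
re-centering the trunk output) and ``f_nl`` a 10x10 convolution followed
by a leaky ReLU (a nonlinear correction).  Both heads consume the channel
concatenation of the high-fidelity input image and the trunk prediction
y_L.  By default the head sum is squashed through a sigmoid so that it
compares to binary masks as a probability; the squash can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Conv2d, LeakyReLU, Sigmoid, concat_channels
from .unet import UNet


@dataclass(frozen=True)
class CompositeConfig:
    """Hyperparameters of the correction heads."""

    hf_kernel: int = 10
    leaky_slope: float = 0.01
    l2_rate: float = 1e-5
    output_sigmoid: bool = True
    #: "passthrough" starts the heads as a sharpened identity on y_L (the
    #: composite then reproduces the trunk's thresholded prediction before
    #: any high-fidelity training); "random" uses the standard He init.
    head_init: str = "passthrough"


class CompositeModel:
    """Trunk + linear and nonlinear high-fidelity correction heads."""

    def __init__(self, lf_model: UNet, config: CompositeConfig | None = None,
                 seed: int = 0):
        self.lf = lf_model
        self.config = config or CompositeConfig()
        rng = np.random.default_rng(seed)
        cin = lf_model.config.input_channels + 1
        k = self.config.hf_kernel
        self.head1 = Conv2d(cin, 1, k, rng, "hf1")       # linear map f_l
        self.head2 = Conv2d(cin, 1, k, rng, "hf2")       # nonlinear map f_nl
        self.leaky = LeakyReLU(self.config.leaky_slope)
        self.sigmoid = Sigmoid()
        self.last_head1 = None
        self.last_head2 = None
        self._cache = None
        if self.config.head_init == "passthrough":
            self._init_passthrough(rng)
        elif self.config.head_init != "random":
            raise ValueError(f"unknown head_init {self.config.head_init!r}")

    #: Logistic sharpening gain of the pass-through initialization:
    #: sigmoid(GAIN * (y_L - 1/2)) preserves the trunk's 0.5 threshold.
    PASSTHROUGH_GAIN = 8.0

    def _init_passthrough(self, rng):
        self.head1.W.data[...] = 0.0
        c_yl = self.head1.W.data.shape[1] - 1
        anchor = (self.config.hf_kernel - 1) // 2
        self.head1.W.data[0, c_yl, anchor, anchor] = self.PASSTHROUGH_GAIN
        self.head1.b.data[...] = -self.PASSTHROUGH_GAIN / 2.0
        # small symmetry-breaking noise so the nonlinear head can learn
        self.head2.W.data[...] = rng.normal(
            0.0, 1e-3, self.head2.W.data.shape).astype(np.float32)
        self.head2.b.data[...] = 0.0

    @property
    def dtype(self):
        return self.lf.dtype

    def to_double(self):
        """Promote trunk and heads to float64 (gradient checks)."""
        self.lf.to_double()
        for p in self.head_parameters():
            p.data = p.data.astype(np.float64)
            p.grad = p.grad.astype(np.float64)
        return self

    def parameters(self):
        return (self.lf.parameters() + self.head1.parameters()
                + self.head2.parameters())

    def head_parameters(self):
        return self.head1.parameters() + self.head2.parameters()

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        y_l = self.lf.forward(x)
        h = concat_channels(x, y_l)
        s1 = self.head1.forward(h)
        s2 = self.leaky.forward(self.head2.forward(h))
        s = s1 + s2
        self.last_head1, self.last_head2 = s1, s2
        self._cache = x.shape[1]
        if self.config.output_sigmoid:
            return self.sigmoid.forward(s)
        return s

    def backward(self, dldout: np.ndarray, trunk: bool = True) -> np.ndarray:
        """Backpropagate; ``trunk=False`` freezes the low-fidelity weights."""
        d = np.ascontiguousarray(dldout, dtype=self.dtype)
        if self.config.output_sigmoid:
            d = self.sigmoid.backward(d)
        dh = self.head1.backward(d) + self.head2.backward(self.leaky.backward(d))
        c_img = self._cache
        dx_direct = dh[:, :c_img]
        dy_l = np.ascontiguousarray(dh[:, c_img:])
        if trunk:
            dx_trunk = self.lf.backward(dy_l)
            return dx_direct + dx_trunk
        return dx_direct

    # -- weights -----------------------------------------------------------
    def state_dict(self):
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state):
        for p in self.parameters():
            p.data[...] = state[p.name]

    def calibrate_passthrough(self):
        """Set head1 to the identity on y_L and zero head2.

        With the output sigmoid disabled the composite then reproduces the
        trunk prediction exactly.
        """
        self.head1.W.data[...] = 0.0
        self.head1.b.data[...] = 0.0
        # delta kernel at the zero-padding anchor of the even kernel
        c_yl = self.head1.W.data.shape[1] - 1
        anchor = (self.config.hf_kernel - 1) // 2
        self.head1.W.data[0, c_yl, anchor, anchor] = 1.0
        self.head2.W.data[...] = 0.0
        self.head2.b.data[...] = 0.0


def build_composite(lf_model: UNet, config: CompositeConfig | None = None,
                    seed: int = 0) -> CompositeModel:
    """Wrap a built low-fidelity trunk with freshly initialized heads."""
    return CompositeModel(lf_model, config, seed=seed)
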