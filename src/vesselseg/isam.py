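"""Inter-stage spatial attention gate.

Between the coarse and fine stages of the cascade, the coarse stage's
probability map is re-weighted by a multi-scale spatial attention map:
channel-wise average and max pooling produce two spatial descriptors,
which are concatenated and passed through three parallel 3x3 convolutions
with dilation rates 1, 2 and 3 (padding = rate, so resolution is kept);
the branch outputs are summed, batch-normalised and squashed by a sigmoid
into a per-pixel gate in (0, 1) that multiplies every input channel.
The dilated branches integrate context up to a 7x7 footprint, so the gate
can emphasise coherent vessel regions rather than isolated pixels.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .nn import BatchNorm2d, Conv2d, Module, Tensor, as_tensor, concat

__all__ = ["spatial_descriptors", "InterStageAttention"]


def spatial_descriptors(f_in):
    """Channel-wise average and max pooling of an NCHW feature map.

    Returns ``(f_avg, f_max)``, each N x 1 x H x W.  Accepts a Tensor (kept
    on the autodiff tape) or a plain array (arrays returned).
    """
    return_np = not isinstance(f_in, Tensor)
    t = as_tensor(f_in)
    if t.ndim != 4 or t.shape[1] < 1:
        raise ValueError("expected NCHW input with at least one channel")
    f_avg = t.mean(axis=1, keepdims=True)
    f_max = t.max(axis=1, keepdims=True)
    if return_np:
        return f_avg.data, f_max.data
    return f_avg, f_max


class InterStageAttention(Module):
    """Multi-scale spatial attention over an NCHW feature map.

    Parameters
    ----------
    dilation_rates:
        Dilation rate of each independent 3x3 branch (default ``(1, 2, 3)``).
        Padding equals the rate so spatial size is preserved.  Branch
        convolutions carry no bias (batch norm follows).
    """

    def __init__(self, dilation_rates=(1, 2, 3), rng: np.random.Generator | None = None):
        super().__init__()
        if len(dilation_rates) == 0 or any(int(r) <= 0 for r in dilation_rates):
            raise ConfigurationError("dilation rates must be positive integers")
        self.dilation_rates = tuple(int(r) for r in dilation_rates)
        if rng is None:
            rng = np.random.default_rng(0)
        self._branches = []
        for i, rate in enumerate(self.dilation_rates):
            conv = Conv2d(2, 1, 3, padding=rate, dilation=rate, bias=False, rng=rng)
            setattr(self, f"branch{i}", conv)
            self._branches.append(conv)
        self.bn = BatchNorm2d(1)

    def forward(self, f_in) -> tuple[Tensor, Tensor]:
        """Return ``(f_out, attention)`` with ``f_out = attention * f_in``."""
        f_in = as_tensor(f_in)
        f_avg, f_max = spatial_descriptors(f_in)
        desc = concat([f_avg, f_max], axis=1)
        summed = self._branches[0](desc)
        for conv in self._branches[1:]:
            summed = summed + conv(desc)
        att = self.bn(summed).sigmoid()
        return f_in * att, att
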