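"""The inter-stage attention gate on a coarse probability map.

Channel-pooled descriptors pass through three dilated 3x3 convolutions
(rates 1, 2, 3), are summed, batch-normalised and squashed to a per-pixel
gate in (0, 1) that rescales the coarse stage's output before the fine
stage re-reads it.
"""

import numpy as np

from vesselseg import InterStageAttention
from vesselseg.nn import Tensor

rng = np.random.default_rng(0)
coarse_map = rng.beta(0.4, 2.0, size=(1, 1, 32, 32)).astype(np.float32)

isam = InterStageAttention(dilation_rates=(1, 2, 3))
enhanced, attention = isam(Tensor(coarse_map))

print(f"input  shape {coarse_map.shape}, mean {coarse_map.mean():.3f}")
print(f"gate   shape {attention.shape}, range ({attention.data.min():.3f}, {attention.data.max():.3f})")
print(f"output shape {enhanced.shape}, |out| <= |in|: {(np.abs(enhanced.data) <= np.abs(coarse_map)).all()}")
# The gate is strictly inside (0, 1) — it can only attenuate, never amplify;
# training shapes it to pass vessel regions through and damp background.
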