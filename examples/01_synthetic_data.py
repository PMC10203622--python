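"""Generate a synthetic fundus-like image with its vessel annotation.

The generator reproduces the structures that make real fundus images hard:
thin low-contrast branches, a bright disc region, and a strong
vessel/background class imbalance.
"""

import numpy as np

from vesselseg import SyntheticSpec, generate_sample

spec = SyntheticSpec(height=64, width=64, seed=7)
sample = generate_sample(spec)

frac = sample.mask.mean()
thin = ((sample.width_map > 0) & (sample.width_map <= 2)).sum()
thick = (sample.width_map > 2).sum()
vessel_mean = sample.image[..., 1][sample.mask == 1].mean()
bg = (sample.mask == 0) & (sample.fov == 1)
bg_mean = sample.image[..., 1][bg].mean()

print(f"image {sample.image.shape}, intensities [{sample.image.min():.2f}, {sample.image.max():.2f}]")
print(f"vessel fraction      {frac:.3f}  (background:vessel ~ {(1 - frac) / frac:.1f}:1)")
print(f"thin / thick pixels  {thin} / {thick}")
print(f"green-channel mean   vessels {vessel_mean:.3f} vs background {bg_mean:.3f}")
# The fraction shows the imbalance the weighted loss corrects; the mean gap
# shows vessels are darker than background, i.e. there is signal to learn.
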