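"""Inspect the channel and spatial attention gates of a CBAM block.

The block multiplies a feature map by a per-channel gate (from pooled channel
statistics) and then by a per-position gate (from channel-pooled maps); every
gate lies strictly in (0, 1), so attention can only re-weight, never amplify.
"""

import numpy as np

from petcycle.attention import CBAM, CBAMConfig
from petcycle.autodiff import Tensor

rng = np.random.default_rng(0)
block = CBAM(CBAMConfig(channels=8, reduction=4, spatial_kernel=7), rng=rng)

x = rng.normal(size=(1, 8, 16, 16))
channel_gate = block.channel(Tensor(x)).data[0, :, 0, 0]
spatial_gate = block.spatial(Tensor(x)).data[0, 0]
refined = block(Tensor(x)).data

print("channel gate (one value per channel):")
print(np.array2string(channel_gate, precision=3))
print(f"\nspatial gate: {spatial_gate.shape[0]}x{spatial_gate.shape[1]} map, "
      f"range [{spatial_gate.min():.3f}, {spatial_gate.max():.3f}]")
print(f"refined map range vs input: |out| <= |in| everywhere: "
      f"{bool(np.all(np.abs(refined) <= np.abs(x) + 1e-12))}")
print("\nAll gates are sigmoid outputs in (0,1): the block suppresses "
      "uninformative\nchannels and positions instead of creating new signal.")
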