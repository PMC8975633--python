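"""Generate synthetic paired PET slices and show how image degradation
scales with effective scanner sensitivity.

The high-quality (HQ) slice is a noise-free activity phantom; its low-quality
(LQ) partner is blurred and count-starved. Sensitivity ~ axial field of view:
1.0 plays the role of a total-body scanner, small values a short-axis one.
"""

import numpy as np

from petcycle import DegradationSpec, PhantomSpec, degrade, generate_phantom

hq = generate_phantom(PhantomSpec(grid_size=64, n_organs=4, n_lesions=2, seed=7))
print(f"HQ phantom: {hq.shape[0]}x{hq.shape[1]}, "
      f"activity range [{hq.pixels.min():.2f}, {hq.pixels.max():.2f}]")

print(f"\n{'sensitivity':>12s} {'MSE(LQ,HQ)':>12s}")
for sensitivity in (1.0, 0.5, 0.3, 0.15, 0.1):
    lq = degrade(hq, DegradationSpec(sensitivity=sensitivity, seed=1))
    mse = float(np.mean((lq.pixels - hq.pixels) ** 2))
    print(f"{sensitivity:12.2f} {mse:12.5f}")

print("\nMSE grows as sensitivity drops: fewer detected counts mean noisier "
      "slices,\nmirroring shorter axial fields of view.")
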