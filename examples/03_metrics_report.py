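"""Score degraded slices against ground truth with NRMSE, PSNR and SSIM.

NRMSE (x100) and PSNR (dB, peak of the reference) measure pixel error;
SSIM measures local structural agreement on an 11x11 Gaussian window and is
1 exactly for identical images.
"""

from petcycle import (DegradationSpec, MetricConfig, PhantomSpec, degrade,
                      evaluate_pairs, generate_phantom)

pairs = []
for seed in range(8):
    hq = generate_phantom(PhantomSpec(grid_size=64, seed=seed))
    lq = degrade(hq, DegradationSpec(sensitivity=0.15, seed=seed))
    pairs.append((lq, hq))

report = evaluate_pairs([lq for lq, _ in pairs], [hq for _, hq in pairs],
                        MetricConfig())
s = report.summary()
print(f"{'metric':>10s} {'mean':>10s} {'sd':>10s}")
print(f"{'NRMSE':>10s} {s['nrmse']['mean']:10.3f} {s['nrmse']['sd']:10.3f}")
print(f"{'PSNR dB':>10s} {s['psnr_db']['mean']:10.3f} {s['psnr_db']['sd']:10.3f}")
print(f"{'SSIM':>10s} {s['ssim']['mean']:10.4f} {s['ssim']['sd']:10.4f}")
print("\nThese are the 'before' numbers a trained translator must beat: "
      "lower NRMSE,\nhigher PSNR and SSIM against the same references.")
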