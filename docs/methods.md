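# Methods

## Problem and model

PET image quality rises with scanner sensitivity, which is tied to the axial
field of view (FOV): a total-body scanner (~1940 mm axial FOV) collects far
more coincidence events than a conventional short-axis scanner (200–350 mm)
and produces visibly cleaner images in the same acquisition time. `petcycle`
learns a mapping from low-quality (LQ, short-FOV-like) axial slices to
high-quality (HQ, total-body-like) slices using a cycle-consistent
adversarial framework with attention and a supervised pairing term.

Four networks are trained simultaneously: generators G_AB (LQ→HQ) and
G_BA (HQ→LQ), and critics D_B and D_A that judge realism in each target
domain. The training objective is

    L = L_adv + λ_c·L_cyc + λ_i·L_id + λ_s·L_sup,   (λ_c, λ_i, λ_s) = (10, 0.5, 0.5)

with

* **L_adv** — a gradient-penalised critic (Wasserstein-style) objective,
  averaged over the two directions. For one direction the critic minimises
  `−E[D(real)] + E[D(fake)] + λ·E[(‖∇_ŷ D(ŷ)‖₂ − 1)²]` where ŷ is a
  per-sample convex combination `ε·real + (1−ε)·fake`, ε ~ U(0,1); the
  generator minimises `−E[D(fake)]`. The critic head is a raw (unsquashed)
  patch score map.
* **L_cyc** — mean-absolute error of both round trips
  `G_BA(G_AB(x_A)) ≈ x_A` and `G_AB(G_BA(x_B)) ≈ x_B`.
* **L_id** — mean-absolute error of each generator applied to an image
  already in its *output* domain (`G_BA(x_A) ≈ x_A`, `G_AB(x_B) ≈ x_B`).
* **L_sup** — because the slice pairs are pixel-aligned, a direct paired L1
  term `‖G_AB(x_A) − x_B‖₁ + ‖G_BA(x_B) − x_A‖₁`.

All L1 terms use the **mean** over pixels (not the sum) so loss magnitudes
are independent of slice resolution. Identity loss is computed on normalized
tensors like every other term.

### Generator

A residual image-to-image network with a convolutional block attention
module (CBAM) after the first convolution and before the last one:
7×7 conv (reflection padding) → CBAM → two 3×3 stride-2 down-sampling convs
→ nine residual blocks → two 3×3 stride-2 transposed convs → CBAM → 7×7
conv → tanh. Six convolutions sit outside the residual blocks and attention.
Channel widths are 64/128/256 at the default `base_channels=64`; the
parameter scales the whole family (the desk preset uses 8). Normalisation is
batch normalisation throughout, and residual blocks apply ReLU after the
first convolution *and after the skip addition* — both deliberate,
documented choices (the common CycleGAN convention would be instance norm
and no post-addition activation). Up-sampling is a stride-2 transposed
convolution with output padding chosen to invert the down-sampling shape
exactly. tanh bounds the output to (−1, 1), matching the input scale.

### CBAM

Channel gate: global average- and max-pooled channel descriptors pass
through one shared bottleneck (C → C/r → C, two 1×1 convolutions with ReLU,
biases enabled), are summed and squashed by a sigmoid. Spatial gate:
channel-wise mean and max maps are concatenated and convolved (k×k, sigmoid).
Gates multiply the map they were computed from, channel first, then spatial.
Defaults r = 16 and k = 7 follow the reference CBAM settings.

### Critic

Patch critic `C4S2-64 → C4S2-128 → C4S2-256 → C4S1-512` (4×4 kernels,
LeakyReLU slope 0.2, batch norm on every stage except the first) followed by
a 4×4 stride-1 convolution to a one-channel score map. The prediction head
is convolutional (a patch map), not a fully connected layer, and carries no
sigmoid — required by the gradient-penalty form. Inputs must survive the
stride trace; the forward pass rejects anything smaller (≲ 24 px with
padding 1 at every stage).

## Optimisation

Adam (β₁ = 0.5, β₂ = 0.999); reference schedule 200 epochs, batch 32,
learning rate 2e−4 held for the first half of training, then linearly
decayed to zero at the final epoch boundary. Each iteration updates both
critics on the penalty objective (`n_critic` = 1 by default, read from the
"trained simultaneously" protocol as strict alternation), then both
generators jointly on the full objective, so gradients flow through both
cycle directions in one step. No replay buffer of historical fakes is used.
The generator step backpropagates the combined loss path by path
(A→B→A, B→A→B, and the two identity mappings) with gradient accumulation;
this is algebraically identical to a single combined backward pass but holds
at most two network tapes in memory at once.

Training aborts with the offending component and iteration index if any
loss component becomes non-finite. Every run is reproducible from the config
seed: model initialisation, batch order and the penalty's interpolation
draws all derive from it.

## Numerical engine

No deep-learning framework is part of the dependency set; the networks run
on a compact reverse-mode autodiff engine over numpy (`petcycle.autodiff`).
Its design constraint is the gradient penalty, which differentiates the
critic's input-gradient norm with respect to the critic's parameters: VJP
closures are themselves built from primitives, so `grad(..., create_graph=True)`
yields gradients that can be differentiated again. Second-order correctness
is verified against finite differences in the test suite. Convolutions use
a single-GEMM im2col layout for strided layers and a direct
einsum-on-strided-view path for stride-1 layers; the stride-1 operators form
a closed adjoint set (conv / transposed conv / weight gradient), keeping
arbitrary-order derivatives exact. Tensors default to float64 so oracle
comparisons are tight; training runs in float32 (`TrainConfig.dtype`) for
throughput. Piecewise-linear activations (ReLU/LeakyReLU) and max-pooling
use the standard almost-everywhere subgradients, with gradient shared
equally among ties in a max.

## Intensity convention

All voxel values are scaled linearly to [−1, 1] for training. The window is
**per pair**: the minimum and maximum of the HQ member, shared by its LQ
member so both sit on one scale; windows are recorded so denormalisation is
exact. (Whether the original protocol normalized per-slice, per-volume or
per-dataset is not stated; per-pair/per-volume is the implemented choice.)
At inference on LQ data alone, no HQ window exists, so the LQ volume's own
min/max is used. Metrics are always computed on denormalized,
physical-scale intensities because all three depend on the reference scale.

## Metrics

* `NRMSE = √(Σ(x−y)² / Σy²) × 100` — implemented with the ×100 factor as
  printed in the defining formula. Published tables for this task show NRMSE
  magnitudes of ~0.2–0.3, which is inconsistent with the ×100 factor by two
  orders of magnitude; the factor is kept as written and
  `MetricConfig(nrmse_percent=False)` exposes the unscaled variant.
* `PSNR = 20·log10(MAX/√MSE)` in dB with MAX the peak of the reference image
  (a fixed dynamic range is available via config). Identical images report a
  +inf sentinel, counted separately in the aggregate.
* `SSIM` — the local statistic
  `(2μxμy+C1)(2σxy+C2) / ((μx²+μy²+C1)(σx²+σy²+C2))` on a window centred at
  each pixel, averaged over all valid centres. Window settings are not fixed
  by the defining formula; the standard reference settings are used: 11×11
  Gaussian window with σ = 1.5 (a uniform window via `ssim_sigma=0`),
  k1 = 0.01, k2 = 0.03, dynamic range L = reference max − min. Moments are
  window-weighted population moments.

All three are validated against independent double-loop oracles.

## Synthetic paired phantoms

The real dataset for this problem (paired short-FOV / total-body
reconstructions of the same acquisitions) is hospital-restricted, so the
package ships a simulator that reproduces its *structure*, not its anatomy:

* **HQ**: uniform background activity plus `n_organs` random ellipses with
  additive activities (overlaps allowed, as organs overlap in projection)
  and `n_lesions` small discs that multiply local activity by a contrast
  factor > 1. Noise-free by design — a clean target makes metric behaviour
  sharper at desk scale, whereas real HQ images retain some noise.
* **LQ**: `Poisson(s·κ·blur(HQ))/(s·κ) + N(0, σ)` — Gaussian PSF blur,
  scaled-Poisson counting noise whose variance grows as 1/s, and additive
  electronic noise. The effective sensitivity s ∈ (0,1] is the single knob
  standing in for axial FOV (1 ≈ total-body; the 0.15 default ≈ a heavily
  count-starved short-axis acquisition). The mapping s ↔ FOV(mm) is
  illustrative only; no published noise level exists to calibrate it.

Pairs are split 9:1 into train and test by pair; a `group_of` hook allows
patient-style grouped splits but is unused by default. Everything is
bit-reproducible from the specs' seeds.

What passing tests on these phantoms shows: the full optimisation loop,
attention, losses and metrics interact correctly, and the trained mapping
genuinely denoises structured count-limited images it has not seen. What it
does not show: performance on real anatomy, scanner-specific texture, or
inter-scanner attenuation differences.

## Desk-scale study configuration

The reference recipe (three beds × ~60–80k pairs of 150×150 or 192×192
slices, 200 epochs, batch 32) is a multi-week GPU job and is out of scope.
The desk preset (`petcycle.presets`) keeps the architecture family and the
objective and shrinks everything else: 200 pairs of 32×32 phantoms at
sensitivity 0.15, 30 epochs, batch 32, base width 8 (critic ladder
8-16-32-64, attention ratio 4). With only ~180 optimisation steps the
reference learning rate barely moves the weights, so the preset uses 1e−3,
constant for the first 15 epochs then decayed linearly — the same two-phase
shape as the reference schedule. The headline check trains this preset for
three fixed seeds and requires the translated held-out slices to beat the
raw LQ input on mean SSIM for a majority of seeds. At this scale the gain
is structural: SSIM improves decisively while pixel-wise NRMSE/PSNR may
still trail the input — ~180 optimisation steps buys noise suppression and
local-structure recovery, not yet unbiased absolute intensities.

## Degenerate inputs and edge rules

* `normalize` with vmin == vmax (constant slice) returns zeros and logs a
  warning instead of raising; constant slices occur at FOV edges.
* `nrmse` is undefined for an all-zero reference and raises.
* `ssim` requires the image to be at least window-sized; a constant
  reference falls back to dynamic range 1 so the statistic stays defined.
* Generator inputs must have height and width divisible by 4 (two stride-2
  stages each way); there is no silent padding.
* `make_dataset` requires at least 10 pairs so the 9:1 split is non-empty.

## Known limitations

* 2D slice-wise only; no volumetric networks or multi-bed joint models.
* The simulator does not model sinograms, OSEM/TOF reconstruction,
  attenuation maps or anatomical realism.
* Desk-scale training demonstrates relative improvement, not the absolute
  quality reported for the full clinical dataset.
* float32 training on a different BLAS may round differently; bit-exact
  reproducibility is guaranteed within one environment, not across them.
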