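"""Desk-scale study configuration shared by the demo and the test suite.

The reference training recipe (200 epochs, batch 32, tens of thousands of
150x150 slice pairs, full-width networks) is a multi-week GPU job. The
desk-scale preset keeps the architecture family and objective identical but
shrinks the problem so the whole pipeline runs end-to-end on one CPU in
minutes: 32x32 phantoms, 200 pairs, 30 epochs, eighth-width networks
(base 8 channels, 3 residual blocks, attention bottleneck ratio 4, critic
ladder 8-16-32-64), and an effective sensitivity of 0.15 for the
low-quality branch — heavily count-starved, the regime where translation has
the most to gain. With only ~200 optimisation steps the reference learning
rate of 2e-4 barely moves the weights, so the preset raises it to 1e-3
(constant for 15 epochs, then linear decay to zero as usual).
"""

from __future__ import annotations

from .losses import LossWeights
from .networks import DiscriminatorConfig, GeneratorConfig
from .phantom import DegradationSpec, PhantomSpec
from .training import TrainConfig

DESK_GRID = 32
DESK_N_PAIRS = 200
DESK_SENSITIVITY = 0.15


def desk_phantom_spec(seed: int = 0) -> PhantomSpec:
    return PhantomSpec(grid_size=DESK_GRID, n_organs=3, n_lesions=1, seed=seed)


def desk_degradation_spec(seed: int = 0,
                          sensitivity: float = DESK_SENSITIVITY) -> DegradationSpec:
    return DegradationSpec(sensitivity=sensitivity, seed=seed)


def desk_generator_config() -> GeneratorConfig:
    return GeneratorConfig(base_channels=8, n_res_blocks=3, cbam_reduction=4)


def desk_discriminator_config() -> DiscriminatorConfig:
    return DiscriminatorConfig(channel_ladder=(8, 16, 32, 64))


def desk_train_config(seed: int = 0, epochs: int = 30) -> TrainConfig:
    return TrainConfig(epochs=epochs, batch_size=32, lr_initial=1e-3, seed=seed)


def desk_loss_weights() -> LossWeights:
    return LossWeights()
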