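"""Training objectives: gradient-penalised adversarial, cycle, identity,
supervised, and their weighted total.

The full objective for the pair of generators is

    L = L_adv + lambda_c * L_cyc + lambda_i * L_id + lambda_s * L_sup

with default weights (10, 0.5, 0.5). The adversarial part is a Wasserstein
critic with gradient penalty: for each direction the critic D minimises

    -E[D(real)] + E[D(fake)] + lambda_gp * E[(||grad_y D(y)||_2 - 1)^2],

where y is a per-sample convex combination eps*real + (1-eps)*fake,
eps ~ U(0,1), and the generator maximises E[D(fake)] (minimises -E[D(fake)]).
The two directions are averaged (factor 1/2). All L1 losses use the *mean*
over pixels so magnitudes are resolution-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, grad


@dataclass(frozen=True)
class LossWeights:
    lambda_c: float = 10.0
    lambda_i: float = 0.5
    lambda_s: float = 0.5
    lambda_gp: float = 10.0

    def validate(self) -> None:
        for name in ("lambda_c", "lambda_i", "lambda_s", "lambda_gp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class LossBreakdown:
    """Per-batch components; total == adv + λc·cyc + λi·id + λs·sup exactly."""

    adv: float
    cyc: float
    id: float
    sup: float
    total: float

    def as_dict(self) -> dict:
        return {"adv": self.adv, "cyc": self.cyc, "id": self.id,
                "sup": self.sup, "total": self.total}


def _check_shapes(a: Tensor, b: Tensor, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")


def _abs_mean(diff: Tensor) -> Tensor:
    # |x| via relu(x) + relu(-x): exact, with the standard a.e. subgradient
    return (ad.relu(diff) + ad.relu(-diff)).mean()


def gradient_penalty(D, real: Tensor, fake: Tensor, rng: np.random.Generator) -> Tensor:
    """lambda-free penalty term E[(||grad_y D(y)|| - 1)^2] on interpolates."""
    _check_shapes(real, fake, "gradient_penalty")
    n = real.shape[0]
    eps = rng.uniform(0.0, 1.0, size=(n,) + (1,) * (real.ndim - 1))
    y = Tensor(eps * real.data + (1.0 - eps) * fake.data, requires_grad=True)
    score = D(y).sum()
    (gy,) = grad(score, [y], create_graph=True)
    sq = (gy * gy).sum(axis=tuple(range(1, real.ndim)))
    norm = ad.sqrt(sq + 1e-12)
    return ((norm - 1.0) ** 2).mean()


def critic_loss(D, real: Tensor, fake: Tensor, weights: LossWeights,
                rng: np.random.Generator) -> Tensor:
    """One-direction critic objective per the gradient-penalty form."""
    _check_shapes(real, fake, "critic_loss")
    gp = gradient_penalty(D, real, fake, rng)
    return -D(real).mean() + D(fake).mean() + weights.lambda_gp * gp


def generator_adversarial_term(D, fake: Tensor) -> Tensor:
    """The generator's adversarial objective for one direction: -E[D(fake)]."""
    return -D(fake).mean()


def adversarial_loss(D, real_batch: Tensor, fake_batch: Tensor,
                     weights: LossWeights, rng: np.random.Generator):
    """(critic_loss, generator_term) for one translation direction.

    The two directions of the cycle are combined by the caller with the
    averaging factor 1/2 (see :func:`combine_directions`).
    """
    return (critic_loss(D, real_batch, fake_batch, weights, rng),
            generator_adversarial_term(D, fake_batch))


def combine_directions(term_ab: Tensor, term_ba: Tensor) -> Tensor:
    """Average the two cycle directions: L_adv = (L(G_AB,D_B) + L(G_BA,D_A))/2."""
    return 0.5 * (term_ab + term_ba)


def cycle_loss(x_a: Tensor, x_a_cycled: Tensor,
               x_b: Tensor, x_b_cycled: Tensor) -> Tensor:
    """Mean-absolute cycle-consistency penalty, summed over both directions."""
    _check_shapes(x_a, x_a_cycled, "cycle_loss (A)")
    _check_shapes(x_b, x_b_cycled, "cycle_loss (B)")
    return _abs_mean(x_a_cycled - x_a) + _abs_mean(x_b_cycled - x_b)


def identity_loss(x_a: Tensor, g_ba_of_a: Tensor,
                  x_b: Tensor, g_ab_of_b: Tensor) -> Tensor:
    """Penalty for generators altering an image already in their target domain."""
    _check_shapes(x_a, g_ba_of_a, "identity_loss (A)")
    _check_shapes(x_b, g_ab_of_b, "identity_loss (B)")
    return _abs_mean(g_ba_of_a - x_a) + _abs_mean(g_ab_of_b - x_b)


def supervised_loss(gen_b_from_a: Tensor, x_b: Tensor,
                    gen_a_from_b: Tensor, x_a: Tensor) -> Tensor:
    """Paired L1 against the aligned ground truth, both directions."""
    _check_shapes(gen_b_from_a, x_b, "supervised_loss (A->B)")
    _check_shapes(gen_a_from_b, x_a, "supervised_loss (B->A)")
    return _abs_mean(gen_b_from_a - x_b) + _abs_mean(gen_a_from_b - x_a)


def total_loss(adv: Tensor, cyc: Tensor, id_: Tensor, sup: Tensor,
               weights: LossWeights) -> tuple[Tensor, LossBreakdown]:
    """Weighted total objective plus its per-component report."""
    weights.validate()
    components = {"adv": adv, "cyc": cyc, "id": id_, "sup": sup}
    for name, t in components.items():
        val = float(t.data) if isinstance(t, Tensor) else float(t)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite loss component {name!r}: {val}")
    adv, cyc, id_, sup = (ad.as_tensor(t) for t in (adv, cyc, id_, sup))
    total = adv + weights.lambda_c * cyc + weights.lambda_i * id_ \
        + weights.lambda_s * sup
    breakdown = LossBreakdown(
        adv=float(adv.data), cyc=float(cyc.data), id=float(id_.data),
        sup=float(sup.data), total=float(total.data),
    )
    return total, breakdown
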