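"""Objective terms: critic form with gradient penalty, the three L1 terms,
and the weighted-total identity."""

import numpy as np
import pytest

from petcycle import autodiff as ad
from petcycle.autodiff import Tensor, grad
from petcycle import nn
from petcycle.losses import (LossWeights, adversarial_loss, combine_directions,
                             critic_loss, cycle_loss, generator_adversarial_term,
                             gradient_penalty, identity_loss, supervised_loss,
                             total_loss)


class _ConstantCritic:
    def __init__(self, c):
        self.c = c

    def __call__(self, t):
        return Tensor(np.full((t.shape[0], 1, 1, 1), self.c)) + 0.0 * t.mean()


class _LinearCritic:
    """D(y) = <w, y> per sample, with configurable gradient norm ||w||."""

    def __init__(self, shape, norm, rng):
        w = rng.normal(size=shape)
        self.w = Tensor(w * (norm / np.linalg.norm(w)))

    def __call__(self, t):
        return (t * self.w).sum(axis=(1, 2, 3))


@pytest.fixture
def batches(rng):
    real = Tensor(rng.normal(size=(4, 1, 8, 8)))
    fake = Tensor(rng.normal(size=(4, 1, 8, 8)))
    return real, fake


class TestAdversarial:
    def test_constant_critic_scores_cancel_leaving_lambda(self, batches, rng):
        """-E[D(real)] + E[D(fake)] = 0 and the penalty is (0-1)^2 = 1."""
        real, fake = batches
        w = LossWeights(lambda_gp=10.0)
        loss = critic_loss(_ConstantCritic(3.7), real, fake, w,
                           np.random.default_rng(0))
        assert loss.item() == pytest.approx(w.lambda_gp, abs=1e-4)

    def test_unit_norm_linear_critic_has_zero_penalty(self, batches, rng):
        real, fake = batches
        gp = gradient_penalty(_LinearCritic(real.shape[1:], 1.0, rng),
                              real, fake, np.random.default_rng(0))
        assert gp.item() == pytest.approx(0.0, abs=1e-12)

    def test_penalty_for_linear_critic_is_closed_form(self, batches, rng):
        """For D = <w, .>, every interpolate has gradient w, so the penalty
        equals (||w|| - 1)^2 regardless of the data."""
        real, fake = batches
        for norm in (0.5, 2.0):
            gp = gradient_penalty(_LinearCritic(real.shape[1:], norm, rng),
                                  real, fake, np.random.default_rng(1))
            assert gp.item() == pytest.approx((norm - 1.0) ** 2, rel=1e-9)

    def test_penalty_invariant_to_critic_offset(self, batches, rng):
        real, fake = batches
        lin = _LinearCritic(real.shape[1:], 1.7, rng)
        shifted = lambda t: lin(t) + 123.0
        a = gradient_penalty(lin, real, fake, np.random.default_rng(5)).item()
        b = gradient_penalty(shifted, real, fake, np.random.default_rng(5)).item()
        assert a == pytest.approx(b, rel=1e-12)

    def test_gradient_norm_matches_finite_differences(self, rng):
        """The penalty's interior gradient norm agrees with an FD probe of a
        small nonlinear critic."""
        conv = nn.Conv2d(1, 2, 3, stride=1, padding=1, rng=rng)
        head = nn.Conv2d(2, 1, 3, stride=1, padding=1, rng=rng)

        def D(t):
            return head(ad.tanh(conv(t))).sum(axis=(1, 2, 3))

        y = rng.normal(size=(2, 1, 6, 6))

        # analytic norm via the same double-backprop path the penalty uses
        yy = Tensor(y, requires_grad=True)
        (gy,) = grad(D(yy).sum(), [yy], create_graph=True)
        analytic = np.sqrt((gy.data ** 2).sum(axis=(1, 2, 3)))

        eps = 1e-6
        for n in range(y.shape[0]):
            fd_sq = 0.0
            for i in range(6):
                for j in range(6):
                    y[n, 0, i, j] += eps
                    hi = D(Tensor(y)).data[n]
                    y[n, 0, i, j] -= 2 * eps
                    lo = D(Tensor(y)).data[n]
                    y[n, 0, i, j] += eps
                    fd_sq += ((hi - lo) / (2 * eps)) ** 2
            assert np.sqrt(fd_sq) == pytest.approx(analytic[n], abs=1e-4)

    def test_direction_pair_and_averaging(self, batches, rng):
        real, fake = batches
        D = _LinearCritic(real.shape[1:], 1.0, rng)
        crit, gen_term = adversarial_loss(D, real, fake, LossWeights(),
                                          np.random.default_rng(2))
        assert gen_term.item() == pytest.approx(-float(np.mean(D(fake).data)))
        assert crit.item() == pytest.approx(
            float(np.mean(D(fake).data)) - float(np.mean(D(real).data)),
            abs=1e-9)  # zero penalty for the unit-norm critic
        both = combine_directions(Tensor(2.0), Tensor(4.0))
        assert both.item() == pytest.approx(3.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            critic_loss(_ConstantCritic(0.0), Tensor(np.zeros((2, 1, 8, 8))),
                        Tensor(np.zeros((2, 1, 6, 6))), LossWeights(),
                        np.random.default_rng(0))


class TestL1Losses:
    def test_cycle_zero_at_identity(self, rng):
        x_a = Tensor(rng.normal(size=(2, 1, 4, 4)))
        x_b = Tensor(rng.normal(size=(2, 1, 4, 4)))
        assert cycle_loss(x_a, x_a, x_b, x_b).item() == 0.0

    def test_cycle_uniform_offsets_add(self, rng):
        x_a = Tensor(rng.normal(size=(2, 1, 4, 4)))
        x_b = Tensor(rng.normal(size=(2, 1, 4, 4)))
        assert cycle_loss(x_a, x_a + 0.1, x_b, x_b).item() == pytest.approx(0.1)
        assert cycle_loss(x_a, x_a + 0.05, x_b, x_b - 0.05).item() \
            == pytest.approx(0.1)

    def test_identity_matches_cycle_on_same_tensors(self, rng):
        a = Tensor(rng.normal(size=(3, 1, 5, 5)))
        b = Tensor(rng.normal(size=(3, 1, 5, 5)))
        c = Tensor(rng.normal(size=(3, 1, 5, 5)))
        d = Tensor(rng.normal(size=(3, 1, 5, 5)))
        assert identity_loss(a, b, c, d).item() == \
            pytest.approx(cycle_loss(a, b, c, d).item(), rel=1e-15)

    def test_supervised_perfect_generator_and_bias(self, rng):
        x_a = Tensor(rng.normal(size=(2, 1, 4, 4)))
        x_b = Tensor(rng.normal(size=(2, 1, 4, 4)))
        assert supervised_loss(x_b, x_b, x_a, x_a).item() == 0.0
        assert supervised_loss(x_b + 0.2, x_b, x_a, x_a).item() \
            == pytest.approx(0.2)

    def test_supervised_matches_loop_oracle(self, rng):
        gb = rng.normal(size=(2, 1, 3, 3))
        xb = rng.normal(size=(2, 1, 3, 3))
        ga = rng.normal(size=(2, 1, 3, 3))
        xa = rng.normal(size=(2, 1, 3, 3))
        expected = 0.0
        for arr, ref in ((gb, xb), (ga, xa)):
            acc = 0.0
            for n in range(2):
                for i in range(3):
                    for j in range(3):
                        acc += abs(arr[n, 0, i, j] - ref[n, 0, i, j])
            expected += acc / arr.size
        got = supervised_loss(Tensor(gb), Tensor(xb), Tensor(ga), Tensor(xa))
        assert got.item() == pytest.approx(expected, abs=1e-10)

    def test_l1_scales_linearly_with_perturbation(self, rng):
        x = Tensor(rng.normal(size=(2, 1, 4, 4)))
        y = Tensor(rng.normal(size=(2, 1, 4, 4)))
        base = cycle_loss(x, x + 1.0, y, y).item()
        assert cycle_loss(x, x + 2.0, y, y).item() == pytest.approx(2 * base)


class TestTotalLoss:
    def test_reference_weights_give_twelve_for_unit_components(self):
        one = Tensor(1.0)
        total, br = total_loss(one, one, one, one,
                               LossWeights(lambda_c=10, lambda_i=0.5,
                                           lambda_s=0.5))
        assert total.item() == pytest.approx(12.0)
        assert br.total == pytest.approx(12.0)

    def test_zero_components_and_zero_weights(self):
        z = Tensor(0.0)
        total, _ = total_loss(z, z, z, z, LossWeights())
        assert total.item() == 0.0
        adv = Tensor(3.25)
        total, _ = total_loss(adv, Tensor(9.0), Tensor(9.0), Tensor(9.0),
                              LossWeights(lambda_c=0, lambda_i=0, lambda_s=0,
                                          lambda_gp=0))
        assert total.item() == pytest.approx(3.25)

    def test_breakdown_recomposition_identity(self, rng):
        w = LossWeights()
        vals = rng.uniform(0, 2, size=4)
        total, br = total_loss(*(Tensor(v) for v in vals), w)
        recomposed = br.adv + w.lambda_c * br.cyc + w.lambda_i * br.id \
            + w.lambda_s * br.sup
        assert br.total == recomposed   # exact float identity

    def test_non_finite_component_named(self):
        with pytest.raises(FloatingPointError, match="cyc"):
            total_loss(Tensor(1.0), Tensor(np.nan), Tensor(1.0), Tensor(1.0),
                       LossWeights())

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="lambda_c"):
            LossWeights(lambda_c=-1.0).validate()
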