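"""Schedule, optimisation-loop bookkeeping, reproducibility, checkpointing
and slice-wise inference."""

import dataclasses

import numpy as np
import pytest

from petcycle.imaging import ImageSlice, PairedSample
from petcycle.losses import LossWeights
from petcycle.training import (CycleModel, TrainConfig, build_model, infer,
                               load_checkpoint, lr_schedule, save_checkpoint,
                               train, translate_slices)

FAST = LossWeights()


def _fast_cfg(**kw):
    base = dict(epochs=2, batch_size=8, lr_initial=1e-3, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestLrSchedule:
    def test_constant_phase_at_initial_rate(self):
        cfg = TrainConfig()   # 200 epochs, constant for 100
        for epoch in (0, 50, 99):
            assert lr_schedule(epoch, cfg) == 2e-4

    def test_linear_decay_reaches_zero(self):
        cfg = TrainConfig()
        assert lr_schedule(150, cfg) == pytest.approx(1e-4)
        assert lr_schedule(199, cfg) == pytest.approx(2e-4 / 100)
        # one more linear step would land exactly on zero
        assert lr_schedule(199, cfg) - (lr_schedule(198, cfg)
                                        - lr_schedule(199, cfg)) \
            == pytest.approx(0.0, abs=1e-20)

    def test_nonincreasing_over_all_epochs(self):
        cfg = TrainConfig(epochs=40, lr_constant_epochs=10)
        rates = [lr_schedule(e, cfg) for e in range(40)]
        assert all(b <= a for a, b in zip(rates, rates[1:]))
        assert rates[:10] == [cfg.lr_initial] * 10

    @pytest.mark.parametrize("epoch", [-1, 200, 1000])
    def test_out_of_range_epoch_rejected(self, epoch):
        with pytest.raises(ValueError, match="out of range"):
            lr_schedule(epoch, TrainConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=1).validate()
        with pytest.raises(ValueError, match="lr_constant_epochs"):
            TrainConfig(epochs=10, lr_constant_epochs=10).validate()
        with pytest.raises(ValueError, match="batch_size"):
            TrainConfig(batch_size=0).validate()


class TestTrainLoop:
    def test_two_epoch_bookkeeping(self, small_norm_pairs, tiny_gen_cfg,
                                   tiny_disc_cfg):
        cfg = _fast_cfg(batch_size=4)
        model, history = train(small_norm_pairs, cfg, FAST,
                               tiny_gen_cfg, tiny_disc_cfg)
        assert isinstance(model, CycleModel)
        assert len(history) == 2 * int(np.ceil(8 / 4))
        for rec in history:
            assert rec["total"] == pytest.approx(
                rec["adv"] + FAST.lambda_c * rec["cyc"]
                + FAST.lambda_i * rec["id"] + FAST.lambda_s * rec["sup"],
                rel=1e-6)

    def test_same_seed_reproduces_history(self, small_norm_pairs, tiny_gen_cfg,
                                          tiny_disc_cfg):
        cfg = _fast_cfg()
        _, h1 = train(small_norm_pairs, cfg, FAST, tiny_gen_cfg, tiny_disc_cfg)
        _, h2 = train(small_norm_pairs, cfg, FAST, tiny_gen_cfg, tiny_disc_cfg)
        assert h1 == h2

    def test_different_seed_changes_history(self, small_norm_pairs,
                                            tiny_gen_cfg, tiny_disc_cfg):
        _, h1 = train(small_norm_pairs, _fast_cfg(seed=0), FAST,
                      tiny_gen_cfg, tiny_disc_cfg)
        _, h2 = train(small_norm_pairs, _fast_cfg(seed=1), FAST,
                      tiny_gen_cfg, tiny_disc_cfg)
        assert h1 != h2

    def test_input_pairs_not_mutated(self, small_norm_pairs, tiny_gen_cfg,
                                     tiny_disc_cfg):
        before = [(p.lq.pixels.copy(), p.hq.pixels.copy())
                  for p in small_norm_pairs]
        train(small_norm_pairs, _fast_cfg(), FAST, tiny_gen_cfg, tiny_disc_cfg)
        for p, (lq0, hq0) in zip(small_norm_pairs, before):
            np.testing.assert_array_equal(p.lq.pixels, lq0)
            np.testing.assert_array_equal(p.hq.pixels, hq0)

    def test_empty_dataset_rejected(self, tiny_gen_cfg, tiny_disc_cfg):
        with pytest.raises(ValueError, match="empty"):
            train([], _fast_cfg(), FAST, tiny_gen_cfg, tiny_disc_cfg)

    def test_unnormalized_input_rejected(self, tiny_gen_cfg, tiny_disc_cfg,
                                         rng):
        raw = [PairedSample(lq=ImageSlice(rng.uniform(0, 10, size=(32, 32))),
                            hq=ImageSlice(rng.uniform(0, 10, size=(32, 32))))]
        with pytest.raises(ValueError, match="normalized"):
            train(raw, _fast_cfg(), FAST, tiny_gen_cfg, tiny_disc_cfg)

    def test_checkpoints_written(self, small_norm_pairs, tiny_gen_cfg,
                                 tiny_disc_cfg, tmp_path):
        cfg = _fast_cfg(epochs=2, checkpoint_every=1)
        train(small_norm_pairs, cfg, FAST, tiny_gen_cfg, tiny_disc_cfg,
              out_dir=tmp_path)
        assert (tmp_path / "checkpoint_epoch1.npz").exists()
        assert (tmp_path / "checkpoint_epoch2.npz").exists()
        assert (tmp_path / "checkpoint_final.npz").exists()


class TestCheckpointRoundTrip:
    def test_model_state_survives_save_load(self, tiny_gen_cfg, tiny_disc_cfg,
                                            tmp_path, rng):
        model = build_model(tiny_gen_cfg, tiny_disc_cfg, seed=3)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, epoch=7)
        loaded, meta = load_checkpoint(path)
        assert meta["epoch"] == 7
        x = rng.uniform(-1, 1, size=(1, 1, 32, 32))
        from petcycle.autodiff import Tensor, no_grad
        model.eval(), loaded.eval()
        with no_grad():
            a = model.g_ab(Tensor(x)).data
            b = loaded.g_ab(Tensor(x)).data
        np.testing.assert_array_equal(a, b)


class TestInference:
    def _zero_model(self, tiny_gen_cfg, tiny_disc_cfg):
        model = build_model(tiny_gen_cfg, tiny_disc_cfg, seed=0)
        for net in (model.g_ab, model.g_ba):
            for p in net.parameters():
                p.data[...] = 0.0
        return model.eval()

    def test_zero_weight_generator_maps_to_window_midpoint(
            self, tiny_gen_cfg, tiny_disc_cfg, rng):
        """tanh(0) = 0 everywhere, which denormalizes to (vmin+vmax)/2."""
        model = self._zero_model(tiny_gen_cfg, tiny_disc_cfg)
        slices = [ImageSlice(rng.uniform(0, 4, size=(32, 32)))]
        out = infer(model, slices, window=(1.0, 3.0))
        np.testing.assert_allclose(out[0].pixels, 2.0, atol=1e-12)

    def test_slice_count_preserved_and_deterministic(
            self, tiny_gen_cfg, tiny_disc_cfg, rng):
        model = build_model(tiny_gen_cfg, tiny_disc_cfg, seed=1).eval()
        slices = [ImageSlice(rng.uniform(0, 1, size=(32, 32)))
                  for _ in range(23)]
        a = infer(model, slices)
        b = infer(model, slices)
        assert len(a) == 23
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.pixels, s2.pixels)

    def test_incompatible_shape_rejected(self, tiny_gen_cfg, tiny_disc_cfg):
        model = build_model(tiny_gen_cfg, tiny_disc_cfg, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            infer(model, [ImageSlice(np.zeros((30, 30)))])

    def test_checkpoint_path_accepted(self, tiny_gen_cfg, tiny_disc_cfg,
                                      tmp_path, rng):
        model = build_model(tiny_gen_cfg, tiny_disc_cfg, seed=2)
        path = tmp_path / "m.npz"
        save_checkpoint(model, path)
        slices = [ImageSlice(rng.uniform(0, 1, size=(32, 32)))]
        out_direct = infer(model.eval(), slices)
        out_loaded = infer(path, slices)
        np.testing.assert_allclose(out_loaded[0].pixels,
                                   out_direct[0].pixels, atol=1e-12)
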