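"""Optimisation loop for the cycle translation model, plus inference.

Both generators and both critics are trained simultaneously with Adam
(beta1 = 0.5, beta2 = 0.999) under a two-phase learning-rate schedule: a
constant phase at the initial rate for the first half of training, then a
linear decay reaching zero at the final epoch boundary. Each iteration first
updates the two critics on the gradient-penalty objective (``n_critic``
times), then updates the two generators jointly on the full weighted
objective, so gradients flow through both cycle directions in one combined
step. Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from . import losses as L
from . import nn
from .autodiff import Tensor, grad
from .imaging import ImageSlice, PairedSample, denormalize, normalize
from .losses import LossBreakdown, LossWeights
from .networks import (Discriminator, DiscriminatorConfig, Generator,
                       GeneratorConfig, build_discriminator, build_generator)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    lr_initial: float = 2e-4
    lr_constant_epochs: Optional[int] = None   # default: epochs // 2
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    n_critic: int = 1
    seed: int = 0
    checkpoint_every: int = 0                  # 0 = final checkpoint only
    dtype: str = "float32"                     # compute precision for training

    def validate(self) -> None:
        if self.epochs < 2:
            raise ValueError(f"epochs must be >= 2, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        ce = self.constant_epochs
        if not 0 < ce < self.epochs:
            raise ValueError(
                f"lr_constant_epochs must be in (0, epochs), got {ce}"
            )
        if self.n_critic < 1:
            raise ValueError(f"n_critic must be >= 1, got {self.n_critic}")
        if self.dtype not in ("float32", "float64"):
            raise ValueError(f"dtype must be float32 or float64, got {self.dtype}")

    @property
    def constant_epochs(self) -> int:
        return self.lr_constant_epochs if self.lr_constant_epochs is not None \
            else self.epochs // 2


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Constant then linearly decaying learning rate.

    ``lr_initial`` through the constant phase, then linear interpolation to 0
    at the final epoch boundary (epoch == cfg.epochs).
    """
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} out of range [0, {cfg.epochs})")
    ce = cfg.constant_epochs
    if epoch < ce:
        return cfg.lr_initial
    return cfg.lr_initial * (cfg.epochs - epoch) / (cfg.epochs - ce)


@dataclass
class CycleModel:
    """The four networks of the framework plus the configs that built them."""

    g_ab: Generator
    g_ba: Generator
    d_a: Discriminator
    d_b: Discriminator
    gen_cfg: GeneratorConfig
    disc_cfg: DiscriminatorConfig

    def eval(self) -> "CycleModel":
        for m in (self.g_ab, self.g_ba, self.d_a, self.d_b):
            m.eval()
        return self

    def train(self) -> "CycleModel":
        for m in (self.g_ab, self.g_ba, self.d_a, self.d_b):
            m.train()
        return self


def build_model(gen_cfg: GeneratorConfig, disc_cfg: DiscriminatorConfig,
                seed: int) -> CycleModel:
    ss = np.random.SeedSequence(seed).spawn(4)
    return CycleModel(
        g_ab=build_generator(gen_cfg, rng=np.random.default_rng(ss[0])),
        g_ba=build_generator(gen_cfg, rng=np.random.default_rng(ss[1])),
        d_a=build_discriminator(disc_cfg, rng=np.random.default_rng(ss[2])),
        d_b=build_discriminator(disc_cfg, rng=np.random.default_rng(ss[3])),
        gen_cfg=gen_cfg,
        disc_cfg=disc_cfg,
    )


def save_checkpoint(model: CycleModel, path, epoch: int = -1,
                    optim_state: Optional[dict] = None) -> None:
    """Persist the four networks, configs and (optionally) optimizer state."""
    arrays = {}
    for name, net in (("g_ab", model.g_ab), ("g_ba", model.g_ba),
                      ("d_a", model.d_a), ("d_b", model.d_b)):
        for key, val in net.state_dict().items():
            arrays[f"{name}/{key}"] = val
    meta = {
        "epoch": epoch,
        "gen_cfg": asdict(model.gen_cfg),
        "disc_cfg": asdict(model.disc_cfg),
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if optim_state is not None:
        for oname, ostate in optim_state.items():
            arrays[f"optim/{oname}/t"] = np.array(ostate["t"])
            arrays[f"optim/{oname}/lr"] = np.array(ostate["lr"])
            for i, m in enumerate(ostate["m"]):
                arrays[f"optim/{oname}/m/{i}"] = m
            for i, v in enumerate(ostate["v"]):
                arrays[f"optim/{oname}/v/{i}"] = v
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[CycleModel, dict]:
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(arrays.pop("__meta__").tobytes().decode())
    gen_cfg = GeneratorConfig(**meta["gen_cfg"])
    disc_cfg = DiscriminatorConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in meta["disc_cfg"].items()
    })
    model = build_model(gen_cfg, disc_cfg, seed=0)
    for name, net in (("g_ab", model.g_ab), ("g_ba", model.g_ba),
                      ("d_a", model.d_a), ("d_b", model.d_b)):
        prefix = f"{name}/"
        state = {k[len(prefix):]: v for k, v in arrays.items()
                 if k.startswith(prefix)}
        net.load_state_dict(state)
    return model, meta


def _batch_tensor(pairs: Sequence[PairedSample], idx, member: str) -> Tensor:
    arrs = [getattr(pairs[i], member).pixels for i in idx]
    return Tensor(np.stack(arrs)[:, None, :, :])


def _check_normalized(pairs: Sequence[PairedSample]) -> None:
    for i, p in enumerate(pairs):
        for member in (p.lq, p.hq):
            lo, hi = member.pixels.min(), member.pixels.max()
            if lo < -1.0 - 1e-9 or hi > 1.0 + 1e-9:
                raise ValueError(
                    f"pair {i}: slices must be normalized to [-1, 1] before "
                    f"training (found range [{lo:.3g}, {hi:.3g}])"
                )


def train(
    train_pairs: Sequence[PairedSample],
    cfg: TrainConfig = TrainConfig(),
    weights: LossWeights = LossWeights(),
    gen_cfg: GeneratorConfig = GeneratorConfig(),
    disc_cfg: DiscriminatorConfig = DiscriminatorConfig(),
    out_dir=None,
) -> tuple[CycleModel, list[dict]]:
    """Train the full cycle model on normalized aligned pairs.

    Returns the trained model and a history with one record per iteration:
    epoch, iteration, learning rate, the generator-objective breakdown and
    the two critic losses. If ``out_dir`` is given, checkpoints are written
    there every ``cfg.checkpoint_every`` epochs and at the end.
    """
    if len(train_pairs) == 0:
        raise ValueError("training set is empty")
    cfg.validate()
    weights.validate()
    _check_normalized(train_pairs)
    with ad.use_dtype(np.dtype(cfg.dtype)):
        return _train_loop(train_pairs, cfg, weights, gen_cfg, disc_cfg, out_dir)


def _train_loop(train_pairs, cfg, weights, gen_cfg, disc_cfg, out_dir):
    model = build_model(gen_cfg, disc_cfg, seed=cfg.seed).train()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))

    gen_params = model.g_ab.parameters() + model.g_ba.parameters()
    opt_g = nn.Adam(gen_params, lr=cfg.lr_initial,
                    beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    opt_da = nn.Adam(model.d_a.parameters(), lr=cfg.lr_initial,
                     beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    opt_db = nn.Adam(model.d_b.parameters(), lr=cfg.lr_initial,
                     beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)

    n = len(train_pairs)
    history: list[dict] = []
    iteration = 0
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        opt_g.lr = opt_da.lr = opt_db.lr = lr
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x_a = _batch_tensor(train_pairs, idx, "lq")
            x_b = _batch_tensor(train_pairs, idx, "hq")

            # --- critic updates -------------------------------------------
            with ad.no_grad():
                fake_b_d = model.g_ab(x_a)
                fake_a_d = model.g_ba(x_b)
            crit_b_val = crit_a_val = float("nan")
            for _ in range(cfg.n_critic):
                crit_b = L.critic_loss(model.d_b, x_b, fake_b_d, weights, rng)
                opt_db.step(grad(crit_b, model.d_b.parameters()))
                crit_a = L.critic_loss(model.d_a, x_a, fake_a_d, weights, rng)
                opt_da.step(grad(crit_a, model.d_a.parameters()))
                crit_b_val, crit_a_val = float(crit_b.data), float(crit_a.data)
                for name, val in (("critic_B", crit_b_val), ("critic_A", crit_a_val)):
                    if not np.isfinite(val):
                        raise RuntimeError(
                            f"non-finite {name} loss at iteration {iteration}"
                        )

            # --- generator update -----------------------------------------
            # The objective is one combined loss over both cycle directions;
            # it is backpropagated path by path (A->B->A, B->A->B, the two
            # identity mappings) with gradient accumulation, which computes
            # the same total gradient while holding at most two network
            # tapes in memory at a time.
            acc = [np.zeros_like(p.data) for p in gen_params]

            def _accumulate(loss_t):
                for buf, g in zip(acc, grad(loss_t, gen_params)):
                    buf += g.data

            fake_b = model.g_ab(x_a)
            cycled_a = model.g_ba(fake_b)
            adv_ab = L.generator_adversarial_term(model.d_b, fake_b)
            cyc_a = L._abs_mean(cycled_a - x_a)
            sup_ab = L._abs_mean(fake_b - x_b)
            _accumulate(0.5 * adv_ab + weights.lambda_c * cyc_a
                        + weights.lambda_s * sup_ab)
            adv_ab, cyc_a, sup_ab = (t.item() for t in (adv_ab, cyc_a, sup_ab))
            fake_b = cycled_a = None

            fake_a = model.g_ba(x_b)
            cycled_b = model.g_ab(fake_a)
            adv_ba = L.generator_adversarial_term(model.d_a, fake_a)
            cyc_b = L._abs_mean(cycled_b - x_b)
            sup_ba = L._abs_mean(fake_a - x_a)
            _accumulate(0.5 * adv_ba + weights.lambda_c * cyc_b
                        + weights.lambda_s * sup_ba)
            adv_ba, cyc_b, sup_ba = (t.item() for t in (adv_ba, cyc_b, sup_ba))
            fake_a = cycled_b = None

            ident_a = model.g_ba(x_a)
            id_a_t = L._abs_mean(ident_a - x_a)
            _accumulate(weights.lambda_i * id_a_t)
            id_a, ident_a, id_a_t = id_a_t.item(), None, None

            ident_b = model.g_ab(x_b)
            id_b_t = L._abs_mean(ident_b - x_b)
            _accumulate(weights.lambda_i * id_b_t)
            id_b, ident_b, id_b_t = id_b_t.item(), None, None

            adv = Tensor(0.5 * (adv_ab + adv_ba))
            cyc = Tensor(cyc_a + cyc_b)
            ident = Tensor(id_a + id_b)
            sup = Tensor(sup_ab + sup_ba)
            try:
                total, breakdown = L.total_loss(adv, cyc, ident, sup, weights)
            except FloatingPointError as exc:
                raise RuntimeError(f"iteration {iteration}: {exc}") from exc

            opt_g.step([Tensor(g) for g in acc])

            history.append({
                "epoch": epoch,
                "iteration": iteration,
                "lr": lr,
                "critic_A": crit_a_val,
                "critic_B": crit_b_val,
                **breakdown.as_dict(),
            })
            iteration += 1

        if out_dir is not None and cfg.checkpoint_every > 0 \
                and (epoch + 1) % cfg.checkpoint_every == 0:
            save_checkpoint(model, out_dir / f"checkpoint_epoch{epoch + 1}.npz",
                            epoch=epoch)

    if out_dir is not None:
        save_checkpoint(model, out_dir / "checkpoint_final.npz",
                        epoch=cfg.epochs - 1)
    return model, history


def translate_slices(generator: Generator, slices: Sequence[ImageSlice],
                     window: tuple[float, float],
                     batch_size: int = 16) -> list[ImageSlice]:
    """Apply an A->B generator slice-by-slice, returning physical-scale output.

    Slices are normalized with ``window``, pushed through the generator in
    evaluation mode (batch norm uses stored statistics, so repeated calls are
    bit-identical), and denormalized back.
    """
    vmin, vmax = window
    generator.eval()
    params = generator.parameters()
    dtype = params[0].data.dtype if params else np.float64
    out: list[ImageSlice] = []
    with ad.no_grad(), ad.use_dtype(dtype):
        for start in range(0, len(slices), batch_size):
            chunk = slices[start:start + batch_size]
            arr = np.stack([normalize(s, vmin, vmax).pixels for s in chunk])
            pred = generator(Tensor(arr[:, None])).data[:, 0]
            for s, p in zip(chunk, pred):
                out.append(denormalize(ImageSlice(np.asarray(p, dtype=np.float64),
                                                  s.spacing, s.label), vmin, vmax))
    return out


def infer(checkpoint, lq_slices: Sequence[ImageSlice],
          window: Optional[tuple[float, float]] = None) -> list[ImageSlice]:
    """Estimate high-quality slices from low-quality ones.

    ``checkpoint`` is a path to a saved model or a :class:`CycleModel`. The
    normalization window defaults to the min/max of the input volume itself
    (at inference time no high-quality reference exists to window against).
    """
    if isinstance(checkpoint, CycleModel):
        model = checkpoint
    else:
        model, _ = load_checkpoint(checkpoint)
    if len(lq_slices) == 0:
        raise ValueError("no slices to translate")
    shape = lq_slices[0].shape
    if shape[0] % 4 or shape[1] % 4:
        raise ValueError(
            f"slice shape {shape} incompatible with the generator "
            "(height/width must be divisible by 4)"
        )
    if window is None:
        lo = min(float(s.pixels.min()) for s in lq_slices)
        hi = max(float(s.pixels.max()) for s in lq_slices)
        window = (lo, hi)
    return translate_slices(model.g_ab, lq_slices, window)
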