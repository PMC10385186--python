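"""Training and inference for the cycleGAN and pix2pix translation modes.

cycleGAN trains a forward generator G_A (amyloid -> FDG), a backward
generator G_B, and two least-squares discriminators on *unpaired* slice
streams (independent epoch-wise shuffles of the two domains); the generator
objective is the six-term additive loss. pix2pix trains only G_A and D_A on
index-paired slices with the forward adversarial term plus a forward L1
reconstruction against the paired target.

All randomness — weight initialisation, shuffling, augmentation — is
governed by one seed, so a fixed seed reproduces the loss history exactly
in single-threaded execution.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import DTYPE, Adam
from .gan_losses import (DEFAULT_WEIGHTS, ConfigurationError, LossBreakdown,
                         adversarial_mse, adversarial_mse_grad, l1_grad,
                         l1_term)
from .networks import (Discriminator, DiscriminatorConfig, Generator,
                       GeneratorConfig, build_discriminator, build_generator,
                       save_checkpoint)
from .pet_io import UnitSlice

__all__ = ["TrainConfig", "TrainResult", "train", "translate",
           "TrainingDivergedError"]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; the last checkpoint (if any) is on disk."""


@dataclass
class TrainConfig:
    mode: str = "cyclegan"            # or "pix2pix"
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 2e-4
    adam_betas: tuple = (0.5, 0.999)
    seed: int = 0
    levels: int = 4
    base_filters: int = 32
    instance_norm: bool = True
    weights: tuple = DEFAULT_WEIGHTS
    augment_flip: bool = False
    augment_patch: bool = False
    augment_resize: bool = False
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None
    loss_log: str | None = None       # per-iteration CSV

    def validate(self):
        if self.mode not in ("cyclegan", "pix2pix"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainResult:
    G_A: Generator
    G_B: Generator | None
    D_A: Discriminator
    D_B: Discriminator | None
    loss_history: list          # per-epoch mean LossBreakdown
    steps_per_epoch: int
    wall_seconds: float
    config: TrainConfig


def _as_batch_array(slices) -> np.ndarray:
    """Stack slices (UnitSlice or 2-D arrays) into an (N,1,H,W) array."""
    arrs = [np.asarray(getattr(s, "values", s), dtype=DTYPE) for s in slices]
    x = np.stack(arrs)[:, None, :, :]
    if x.ndim != 4:
        raise ValueError("expected a list of 2-D slices")
    return x


def _augment(batch: np.ndarray, rng: np.random.Generator,
             cfg: TrainConfig, paired: np.ndarray | None = None):
    """Apply the enabled augmentations; paired batches share parameters."""
    out = [batch] if paired is None else [batch, paired]
    if cfg.augment_flip:
        flips = rng.random(batch.shape[0]) < 0.5
        for b in out:
            b[flips] = b[flips, :, :, ::-1]
    if cfg.augment_patch or cfg.augment_resize:
        from scipy import ndimage

        h, w = batch.shape[2:]
        if cfg.augment_patch:
            ch = int(h * 0.875)
            i0 = rng.integers(0, h - ch + 1)
            j0 = rng.integers(0, w - ch + 1)
        else:
            ch, i0, j0 = int(h * rng.uniform(0.8, 1.0)), 0, 0
        for b in out:
            crop = b[:, :, i0:i0 + ch, j0:j0 + ch]
            z = np.clip(ndimage.zoom(crop, (1, 1, h / ch, w / ch), order=1,
                                     grid_mode=True, mode="nearest"), 0, 1)
            z = z[:, :, :h, :w]
            ph, pw = h - z.shape[2], w - z.shape[3]
            if ph or pw:
                z = np.pad(z, ((0, 0), (0, 0), (0, ph), (0, pw)),
                           mode="edge")
            b[...] = z
    return (out[0], out[1]) if paired is not None else out[0]


def _check_finite(breakdown: LossBreakdown, nets, cfg: TrainConfig):
    if not np.isfinite(breakdown.total):
        if cfg.checkpoint_dir:
            ckdir = Path(cfg.checkpoint_dir)
            ckdir.mkdir(parents=True, exist_ok=True)
            for name, net in nets.items():
                if net is not None:
                    save_checkpoint(net, ckdir / f"diverged_{name}.npz")
        raise TrainingDivergedError("non-finite training loss")


def _mean_breakdown(items: list[LossBreakdown]) -> LossBreakdown:
    w = items[0].weights
    means = {t: float(np.mean([getattr(i, t) for i in items]))
             for t in ("adv_forward", "adv_backward", "cycle_A", "cycle_B",
                       "identity_B", "identity_A")}
    return LossBreakdown(weights=w, **means)


def _cyclegan_step(a, b, G_A, G_B, D_A, D_B, opt_g, opt_d, w):
    """One alternating generator/discriminator update on unpaired batches."""
    # --- generator update -------------------------------------------------
    opt_g.zero_grad()
    opt_d.zero_grad()
    fake_b, t_gab = G_A.forward(a)
    fake_a, t_gba = G_B.forward(b)
    rec_a, t_rec_a = G_B.forward(fake_b)
    rec_b, t_rec_b = G_A.forward(fake_a)
    idt_b, t_idb = G_A.forward(b)
    idt_a, t_ida = G_B.forward(a)
    s_fb, t_dfb = D_A.forward(fake_b)
    s_fa, t_dfa = D_B.forward(fake_a)

    bd = LossBreakdown(
        adv_forward=adversarial_mse(s_fb, 1.0),
        adv_backward=adversarial_mse(s_fa, 1.0),
        cycle_A=l1_term(rec_a, a),
        cycle_B=l1_term(rec_b, b),
        identity_B=l1_term(idt_b, b),
        identity_A=l1_term(idt_a, a),
        weights=w)

    g_fake_b = np.zeros_like(fake_b)
    g_fake_a = np.zeros_like(fake_a)
    if w[0]:
        g_fake_b += w[0] * D_A.backward(adversarial_mse_grad(s_fb, 1.0), t_dfb)
    if w[1]:
        g_fake_a += w[1] * D_B.backward(adversarial_mse_grad(s_fa, 1.0), t_dfa)
    if w[2]:
        g_fake_b += G_B.backward(w[2] * l1_grad(rec_a, a), t_rec_a)
    if w[3]:
        g_fake_a += G_A.backward(w[3] * l1_grad(rec_b, b), t_rec_b)
    G_A.backward(g_fake_b, t_gab)
    G_B.backward(g_fake_a, t_gba)
    if w[4]:
        G_A.backward(w[4] * l1_grad(idt_b, b), t_idb)
    if w[5]:
        G_B.backward(w[5] * l1_grad(idt_a, a), t_ida)
    opt_g.step()

    # --- discriminator update (fakes detached) ----------------------------
    opt_d.zero_grad()
    for D, real, fake in ((D_A, b, fake_b), (D_B, a, fake_a)):
        s_r, t_r = D.forward(real)
        s_f, t_f = D.forward(fake)
        D.backward(0.5 * adversarial_mse_grad(s_r, 1.0), t_r)
        D.backward(0.5 * adversarial_mse_grad(s_f, 0.0), t_f)
    opt_d.step()
    return bd


def _pix2pix_step(a, b, G_A, D_A, opt_g, opt_d, w):
    """One paired forward-only update: adversarial + L1 reconstruction."""
    opt_g.zero_grad()
    opt_d.zero_grad()
    fake_b, t_g = G_A.forward(a)
    s_f, t_df = D_A.forward(fake_b)
    bd = LossBreakdown(
        adv_forward=adversarial_mse(s_f, 1.0),
        cycle_A=l1_term(fake_b, b),   # forward reconstruction slot
        weights=w)
    g = np.zeros_like(fake_b)
    if w[0]:
        g += w[0] * D_A.backward(adversarial_mse_grad(s_f, 1.0), t_df)
    if w[2]:
        g += w[2] * l1_grad(fake_b, b)
    G_A.backward(g, t_g)
    opt_g.step()

    opt_d.zero_grad()
    s_r, t_r = D_A.forward(b)
    s_f2, t_f2 = D_A.forward(fake_b)
    D_A.backward(0.5 * adversarial_mse_grad(s_r, 1.0), t_r)
    D_A.backward(0.5 * adversarial_mse_grad(s_f2, 0.0), t_f2)
    opt_d.step()
    return bd


def train(a_slices, b_slices, config: TrainConfig) -> TrainResult:
    """Train the selected mode on domain-A (FBB) and domain-B (FDG) slices.

    pix2pix requires index-paired slice lists of equal length; cycleGAN
    streams the two domains through independent shuffles.
    """
    config.validate()
    t0 = time.perf_counter()
    A = _as_batch_array(a_slices)
    B = _as_batch_array(b_slices)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both domains must be non-empty")
    if config.mode == "pix2pix" and len(A) != len(B):
        raise ConfigurationError(
            "pix2pix mode requires index-paired A/B slices of equal length")

    h, w_ = A.shape[2], A.shape[3]
    gcfg = GeneratorConfig(levels=config.levels,
                           base_filters=config.base_filters,
                           instance_norm=config.instance_norm,
                           input_shape=(h, w_, 1))
    dcfg = DiscriminatorConfig(levels=config.levels,
                               base_filters=config.base_filters,
                               instance_norm=config.instance_norm,
                               input_shape=(h, w_, 1))
    seed = int(config.seed)
    G_A = build_generator(gcfg, seed=seed, role="A->B")
    D_A = build_discriminator(dcfg, seed=seed + 1)
    if config.mode == "cyclegan":
        G_B = build_generator(gcfg, seed=seed + 2, role="B->A")
        D_B = build_discriminator(dcfg, seed=seed + 3)
        gen_params = G_A.parameters() + G_B.parameters()
        disc_params = D_A.parameters() + D_B.parameters()
    else:
        G_B = D_B = None
        gen_params = G_A.parameters()
        disc_params = D_A.parameters()
    opt_g = Adam(gen_params, lr=config.learning_rate, betas=config.adam_betas)
    opt_d = Adam(disc_params, lr=config.learning_rate, betas=config.adam_betas)

    rng = np.random.default_rng(seed + 10)
    n = min(len(A), len(B))
    bs = min(config.batch_size, n)
    steps_per_epoch = int(np.ceil(n / bs))
    weights = tuple(config.weights)

    log_rows = []
    history: list[LossBreakdown] = []
    for epoch in range(config.epochs):
        perm_a = rng.permutation(len(A))[:n]
        perm_b = (perm_a if config.mode == "pix2pix"
                  else rng.permutation(len(B))[:n])
        epoch_losses = []
        for s in range(steps_per_epoch):
            ia = perm_a[s * bs:(s + 1) * bs]
            ib = perm_b[s * bs:(s + 1) * bs]
            a, b = A[ia].copy(), B[ib].copy()
            if config.mode == "pix2pix":
                a, b = _augment(a, rng, config, paired=b)
                bd = _pix2pix_step(a, b, G_A, D_A, opt_g, opt_d, weights)
            else:
                a = _augment(a, rng, config)
                b = _augment(b, rng, config)
                bd = _cyclegan_step(a, b, G_A, G_B, D_A, D_B,
                                    opt_g, opt_d, weights)
            _check_finite(bd, {"G_A": G_A, "G_B": G_B,
                               "D_A": D_A, "D_B": D_B}, config)
            epoch_losses.append(bd)
            row = {"epoch": epoch, "iteration": s, "mode": config.mode}
            row.update(bd.as_dict())
            log_rows.append(row)
        history.append(_mean_breakdown(epoch_losses))
        if (config.checkpoint_every and config.checkpoint_dir
                and (epoch + 1) % config.checkpoint_every == 0):
            ckdir = Path(config.checkpoint_dir)
            ckdir.mkdir(parents=True, exist_ok=True)
            save_checkpoint(G_A, ckdir / f"G_A_epoch{epoch + 1:04d}.npz")
            if G_B is not None:
                save_checkpoint(G_B, ckdir / f"G_B_epoch{epoch + 1:04d}.npz")

    if config.loss_log:
        path = Path(config.loss_log)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(log_rows[0]))
            writer.writeheader()
            writer.writerows(log_rows)

    return TrainResult(G_A=G_A, G_B=G_B, D_A=D_A, D_B=D_B,
                       loss_history=history, steps_per_epoch=steps_per_epoch,
                       wall_seconds=time.perf_counter() - t0, config=config)


def translate(generator: Generator, slices, batch_size: int = 32):
    """Run inference: one output slice per input, order preserved.

    No parameters are updated; outputs stay in [0, 1] by construction of
    the generator's output activation.
    """
    out = []
    items = list(slices)
    for start in range(0, len(items), batch_size):
        chunk = items[start:start + batch_size]
        x = _as_batch_array(chunk)
        y = generator(x)
        for src, img in zip(chunk, y[:, 0]):
            if isinstance(src, UnitSlice):
                out.append(UnitSlice(np.asarray(img, dtype=np.float64),
                                     participant_id=src.participant_id,
                                     subset_index=src.subset_index,
                                     slice_index=src.slice_index,
                                     tracer=src.tracer))
            else:
                out.append(np.asarray(img, dtype=np.float64))
    return out
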