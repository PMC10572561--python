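"""Alternating generator/discriminator optimization.

Both networks are trained with Adam (lr0 = 2·10⁻⁴, β₁ = 0.5, β₂ = 0.999);
the learning rate at epoch e is lr0·0.98^e.  Each step updates the
discriminator first — on (early, delayed ground truth) as real and
(early, G(early)) with a detached generator output as fake — and then the
generator through the total objective with the discriminator fixed.  All
randomness (weight init, shuffling, gradient-penalty interpolation) derives
from the config seed, with per-epoch streams so that resuming from a
checkpoint at an epoch boundary reproduces the uninterrupted run exactly.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import engine as E
from . import losses as LO
from .engine import Tensor
from .errors import ConfigError, DivergenceError
from .evaluate import psnr
from .features import SmallConvFeatureExtractor
from .io import ImageStack, normalize, denormalize
from .networks import (GeneratorSpec, DiscriminatorSpec, UNetGenerator,
                       PatchDiscriminator)

__all__ = ["TrainConfig", "lr_at_epoch", "train_step", "fit", "translate"]


@dataclass
class TrainConfig:
    batch_size: int = 4
    lr0: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    lr_decay_base: float = 0.98
    epochs: int = 200
    loss: LO.LossConfig = field(
        default_factory=lambda: LO.make_loss_config("lsgan+l1"))
    seed: int = 0
    checkpoint_every: int = 0       # 0 → only final/best

    def validate(self) -> None:
        if self.lr0 <= 0:
            raise ConfigError("lr0 must be > 0")
        if not 0 < self.lr_decay_base <= 1:
            raise ConfigError("lr_decay_base must be in (0, 1]")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """lr0 · decay_base^epoch (epoch 0 = the initial learning rate)."""
    if epoch < 0:
        raise ConfigError(f"epoch must be >= 0, got {epoch}")
    return config.lr0 * config.lr_decay_base ** epoch


def _batch_tensors(batch):
    early = np.stack([s.early_slice for s in batch])[:, None, :, :]
    late = np.stack([s.late_slice for s in batch])[:, None, :, :]
    return (Tensor(early.astype(np.float32)), Tensor(late.astype(np.float32)))


def _finite(value: float, what: str, epoch: int, step: int) -> float:
    if not np.isfinite(value):
        raise DivergenceError(
            f"non-finite {what} ({value}) at epoch {epoch}, step {step}")
    return value


def train_step(G: UNetGenerator, D: PatchDiscriminator, batch,
               loss_config: LO.LossConfig, opt_g: E.Adam, opt_d: E.Adam,
               rng=None, extractor=None, epoch: int = 0,
               step: int = 0) -> dict:
    """One alternating update: D on a detached fake, then G with D fixed.

    Returns the scalar loss components of the step.
    """
    early, late = batch if isinstance(batch, tuple) else _batch_tensors(batch)
    w = loss_config.weights
    fake = G(early)

    # ---- discriminator ----
    opt_d.zero_grad()
    comps = {}
    if loss_config.adversarial == "wgan_gp":
        d_loss, gp_comps = LO.wgan_gp_loss_d(
            D, late, fake, lambda_gp=w.lambda_gp, rng=rng, cond=early)
        comps["gradient_penalty"] = gp_comps["gradient_penalty"].item()
    else:
        real_scores = D(early, late)
        fake_scores = D(early, fake.detach())
        if loss_config.adversarial == "gan":
            d_loss = LO.gan_loss_d(real_scores, fake_scores)
        elif loss_config.adversarial == "lsgan":
            d_loss = LO.lsgan_loss_d(real_scores, fake_scores)
        else:
            raise ConfigError(
                f"unknown adversarial loss {loss_config.adversarial!r}")
    d_loss.backward()
    opt_d.step()

    # ---- generator (discriminator fixed) ----
    opt_g.zero_grad()
    fake_scores_g = D(early, fake)
    if loss_config.adversarial == "gan":
        adv_g = LO.gan_loss_g(fake_scores_g,
                              saturating=loss_config.saturating_gan)
    elif loss_config.adversarial == "wgan_gp":
        adv_g = LO.wgan_loss_g(fake_scores_g)
    else:
        adv_g = LO.lsgan_loss_g(fake_scores_g)

    if loss_config.similarity == "l1":
        sim = LO.l1_loss(fake, late)
    else:
        if extractor is None:
            raise ConfigError("perceptual loss requires a feature extractor")
        sim = LO.perceptual_loss(fake, late, extractor,
                                 alpha=w.alpha, beta=w.beta,
                                 w_content=w.w_content, w_style=w.w_style)
    g_total = LO.total_generator_loss(loss_config, adv_g, sim)
    g_total.backward()
    opt_g.step()

    comps.update({
        "d_loss": _finite(d_loss.item(), "D loss", epoch, step),
        "g_adv": _finite(adv_g.item(), "G adversarial term", epoch, step),
        "g_sim": _finite(sim.item(), "G similarity term", epoch, step),
        "g_total": _finite(g_total.item(), "G total", epoch, step),
    })
    return comps


def _epoch_rng(seed: int, epoch: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(epoch, stream)))


def _val_psnr(G: UNetGenerator, val_samples, batch_size: int = 8) -> float:
    G.eval()
    vals = []
    with E.no_grad():
        for start in range(0, len(val_samples), batch_size):
            chunk = val_samples[start:start + batch_size]
            early, late = _batch_tensors(chunk)
            pred = G(early).data
            for i in range(pred.shape[0]):
                vals.append(psnr(pred[i, 0], late.data[i, 0]))
    G.train()
    return float(np.median(vals))


def fit(samples, config: TrainConfig,
        generator_spec: GeneratorSpec | None = None,
        discriminator_spec: DiscriminatorSpec | None = None,
        val_samples=None, checkpoint_dir: str | None = None,
        resume_from: str | None = None, verbose: bool = False):
    """Train a generator on a list of :class:`~petgan.io.PairedSample`.

    Returns (generator, history DataFrame).  With ``val_samples``, the
    weights with the best validation PSNR are restored at the end; otherwise
    the final weights are returned.
    """
    samples = list(samples)
    if not samples:
        raise ConfigError("empty training set")
    config.validate()
    h, w = samples[0].early_slice.shape
    if generator_spec is None:
        generator_spec = GeneratorSpec(rows=h, cols=w)
    if discriminator_spec is None:
        discriminator_spec = DiscriminatorSpec()
    if config.loss.adversarial == "wgan_gp":
        # per-sample gradient penalty is incompatible with cross-sample
        # batch statistics: build the critic without normalization
        discriminator_spec.norm_kind = "none"

    G = UNetGenerator(generator_spec,
                      rng=_epoch_rng(config.seed, 0, stream=10))
    D = PatchDiscriminator(discriminator_spec,
                           rng=_epoch_rng(config.seed, 0, stream=11))
    opt_g = E.Adam(G.parameters(), lr=config.lr0,
                   betas=(config.beta1, config.beta2))
    opt_d = E.Adam(D.parameters(), lr=config.lr0,
                   betas=(config.beta1, config.beta2))
    extractor = (SmallConvFeatureExtractor()
                 if config.loss.similarity == "perceptual" else None)

    history: list[dict] = []
    start_epoch = 0
    best = {"psnr": -np.inf, "state": None}
    if resume_from is not None:
        start_epoch, history, best = _load_training_state(
            resume_from, G, D, opt_g, opt_d)

    for epoch in range(start_epoch, config.epochs):
        lr = lr_at_epoch(config, epoch)
        opt_g.lr = lr
        opt_d.lr = lr
        shuffle_rng = _epoch_rng(config.seed, epoch, stream=0)
        gp_rng = _epoch_rng(config.seed, epoch, stream=1)
        order = shuffle_rng.permutation(len(samples))
        t0 = time.time()
        sums: dict[str, float] = {}
        n_steps = 0
        for start in range(0, len(samples), config.batch_size):
            batch = [samples[i] for i in order[start:start + config.batch_size]]
            comps = train_step(G, D, batch, config.loss, opt_g, opt_d,
                               rng=gp_rng, extractor=extractor,
                               epoch=epoch, step=n_steps)
            for k, v in comps.items():
                sums[k] = sums.get(k, 0.0) + v
            n_steps += 1
        record = {"epoch": epoch, "lr": lr, "n_steps": n_steps,
                  "wall_time_s": time.time() - t0}
        record.update({k: v / n_steps for k, v in sums.items()})
        if val_samples:
            vp = _val_psnr(G, val_samples)
            record["val_psnr"] = vp
            if vp > best["psnr"]:
                best = {"psnr": vp,
                        "state": {k: v.copy()
                                  for k, v in G.state_dict().items()}}
        history.append(record)
        if verbose:
            print(f"epoch {epoch}: " + ", ".join(
                f"{k}={v:.4g}" for k, v in record.items() if k != "epoch"))
        if checkpoint_dir and (
                (config.checkpoint_every
                 and (epoch + 1) % config.checkpoint_every == 0)
                or epoch + 1 == config.epochs):
            _save_training_state(
                os.path.join(checkpoint_dir, f"state_epoch{epoch + 1}.npz"),
                epoch + 1, G, D, opt_g, opt_d, history, best)

    if val_samples and best["state"] is not None:
        G.load_state_dict(best["state"])
    G.eval()
    return G, pd.DataFrame(history)


def _save_training_state(path, next_epoch, G, D, opt_g, opt_d, history,
                         best) -> None:
    arrays = {}
    for prefix, state in (("G.", G.state_dict()), ("D.", D.state_dict())):
        arrays.update({prefix + k: v for k, v in state.items()})
    for name, opt in (("og", opt_g), ("od", opt_d)):
        for i, (m, v) in enumerate(zip(opt.m, opt.v)):
            arrays[f"{name}.m.{i}"] = m
            arrays[f"{name}.v.{i}"] = v
    if best["state"] is not None:
        arrays.update({"best." + k: v for k, v in best["state"].items()})
    meta = {"next_epoch": next_epoch, "history": history,
            "gen_spec": asdict(G.spec), "disc_spec": asdict(D.spec),
            "opt_t": [opt_g.t, opt_d.t], "best_psnr": float(best["psnr"])}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(),
                                       dtype=np.uint8)
    np.savez(path, **arrays)


def _load_training_state(path, G, D, opt_g, opt_d):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        G.load_state_dict({k[2:]: data[k] for k in data.files
                           if k.startswith("G.")})
        D.load_state_dict({k[2:]: data[k] for k in data.files
                           if k.startswith("D.")})
        for name, opt in (("og", opt_g), ("od", opt_d)):
            opt.m = [np.array(data[f"{name}.m.{i}"])
                     for i in range(len(opt.params))]
            opt.v = [np.array(data[f"{name}.v.{i}"])
                     for i in range(len(opt.params))]
        opt_g.t, opt_d.t = meta["opt_t"]
        best_state = {k[5:]: np.array(data[k]) for k in data.files
                      if k.startswith("best.")}
    best = {"psnr": meta["best_psnr"], "state": best_state or None}
    return meta["next_epoch"], list(meta["history"]), best


def translate(G: UNetGenerator, early_stack: ImageStack, norm_params,
              batch_size: int = 8,
              time_post_injection: float | None = None) -> ImageStack:
    """Apply a trained generator slice-wise to an SUV stack.

    The stack is normalized with ``norm_params``, translated slice by slice,
    reassembled, and denormalized back to SUV units.
    """
    h, w = early_stack.voxels.shape[1:]
    if h % 2 ** G.spec.n_down or w % 2 ** G.spec.n_down:
        raise ConfigError(
            f"stack slices {h}x{w} incompatible with generator "
            f"(need divisibility by 2^{G.spec.n_down})")
    norm_stack, _ = normalize(early_stack, norm_params)
    G.eval()
    out = np.empty_like(norm_stack.voxels)
    with E.no_grad():
        for start in range(0, norm_stack.n_slices, batch_size):
            chunk = norm_stack.voxels[start:start + batch_size]
            pred = G(Tensor(chunk[:, None].astype(np.float32))).data
            out[start:start + chunk.shape[0]] = pred[:, 0].astype(np.float64)
    gen = ImageStack(voxels=out, spacing=early_stack.spacing,
                     subject_id=early_stack.subject_id,
                     time_post_injection=(
                         time_post_injection
                         if time_post_injection is not None
                         else early_stack.time_post_injection))
    return denormalize(gen, norm_params)
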